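# Methods

This note documents the models, numerical choices, and known limitations
behind `msfnc`, in the order the pipeline runs.

## Synthetic data: what it emulates and what it does not

The simulator's job is to give every downstream stage a ground truth, at
desk scale, under conditions where the methods are identifiable.

**Spatial model.**  Sources are flat-top ("plateau") blobs: balls of ones
with a Gaussian-smoothed edge, unit L2 norm.  Flat tops matter because
the pipeline variance-normalizes every voxel time course; that pointwise
monotone rescaling maps a plateau onto a plateau, whereas a sharply
peaked Gaussian blob is visibly flattened whenever the per-voxel SNR is
high.  Each of `n_coarse` parents owns `split_factor` children placed
around its center with low mutual overlap (within-scale pairwise spatial
correlation < 0.5 is enforced); the parent map is the smoothed union of
its children.  The construction guarantees, and the tests assert, the
multiscale premise: ≥ 80% of each child's mass lies inside the parent's
10%-of-peak support, ≥ 10% lies outside the parent's half-max contour,
and the parent-vs-union-of-children correlation sits in (0.5, 0.98) —
a coarse source is similar to, but not a simple split into, its children.

**Temporal model.**  Fine-source time courses are zero-mean multivariate
normal within each dwell segment of a first-order Markov chain (geometric
dwell, default mean 20 TRs); each state is a unit-diagonal covariance.
The coarse scale is not rendered separately: siblings share parent signal
through `hierarchical_covariance` (sibling correlation ρ, default 0.35).
Because spatial ICA treats maps as sources and time courses as mixing,
a low model order merges siblings into their parent-union pattern while a
high order resolves the fine maps — the multiscale phenomenon with exact
ground truth at both scales.  By default sources are additionally
low-passed at 0.1 Hz (zero-phase, variance restored), which leaves the
zero-lag covariance unchanged but gives back-reconstructed time courses
the low-frequency dominance the ICN spectral criterion screens for.

**Rendering.**  Subject data = amplitude × maps × time courses + white
Gaussian voxel noise + an optional per-site additive offset + a rank-1
motion term (a fixed central spatial pattern times the standardized first
translation parameter), with six motion parameters simulated as a random
walk.  Diagnosis × sex cells receive additive covariance offsets on named
source pairs (`EffectPair`), validated to keep every state positive
semidefinite.

**Default study conditions** (chosen once as the desk-scale regime in
which group spatial ICA is identifiable, and used throughout the tests):
26 × 26 × 10 voxel grid, 4 coarse × 2 fine sources of radius 2.2 voxels,
ρ = 0.35, source amplitude 1.0, noise σ = 0.05, 16 subjects (4 per
diagnosis × sex cell), 250 TRs at TR = 2 s.  Two regimes of the noise
trade-off bound these choices: with unit-norm maps the total voxel-noise
variance must stay below the per-source signal variance times T/V for the
PCA subspace to hold the sources, while the per-voxel SNR at the blob
plateau must stay moderate or variance normalization distorts map shapes.
The recovery experiments switch the temporal low-pass off (white
sources): with smoothed sources a model order of parents+1 stably
resolves one parent into its children (legitimate multiscale behavior,
but it changes which planted scale order 5 estimates).

**What passing tests do not show about real data:** no hemodynamic
convolution, no spatial autocorrelation of noise, no scanner drifts or
physiological rhythms, Gaussian states rather than heavy-tailed dynamics,
and far fewer voxels/subjects than a real study.  Recovery here means the
algorithms are implemented correctly, not that real ICNs are this easy.

## Decomposition

Subject spatial PCA whitens each subject to the dimensions holding
> 99.99% of variance (`var_retained`); the spatial mean is removed per
time point first, since voxels are the variables of spatial PCA (without
this, nonnegative sources leave a DC direction that measurably degrades
separation).  Group PCA takes the top-N directions of the concatenated
subject component images and whitens them for ICA.

Infomax is the natural-gradient algorithm; the default is the
sign-adaptive (extended) form, which estimates each component's source
kurtosis sign every pass and therefore separates sub- as well as
super-Gaussian sources (`extended=False` gives the classic logistic
update).  Hyperparameters: learning rate 0.01/ln(n), block size
clip(m/16, 64, 1024), tolerance 1e-6 on the relative weight-change norm,
max 512 passes.  The learning rate anneals by 0.90 only when the update
direction turns by more than 60° between passes; annealing on any
increase of the step norm collapses the rate under stochastic block noise
and freezes the weights before separation (this failure mode is easy to
mistake for convergence).  Non-convergence is flagged, not raised: an
unconverged run still enters ICASSO, where instability shows up in the
quality index instead of crashing the chain.

ICASSO pools components of all runs (distinct seeds; voxel bootstrap
optional, off by default), clusters them with average linkage on
1 − |spatial correlation| into model-order-many clusters, scores each
cluster with stability = mean intra − mean extra similarity, and keeps
the run whose components Hungarian-match the cluster centrotypes at the
smallest total distance.  Components are reported in descending stability
order with unit variance and positive peak.

Back-reconstruction is ordinary least squares of each subject volume on
all group maps jointly (spatial multiple regression): exact on noiseless
data, equal to plain projection for orthonormal maps.

## ICN selection and time-course cleaning

Selection is the conjunction: stability > 0.8, gray-matter overlap of
|Z| > 1.96 voxels ≥ 0.5, maximum |correlation| with artifact templates
≤ 0.5, low/high-frequency power ratio ≥ 2 (low band 0.01–0.10 Hz, high
band 0.15 Hz–Nyquist, Welch spectra).  Only the stability bar is
canonical; the other cutoffs encode common practice, are configurable,
and a report-only mode defers the decision to the analyst.  Domains are
assigned from user rules (explicit labels or template matching), not
derived — domain grouping is expert knowledge.

Cleaning order is fixed: polynomial detrend (cubic), regression of the
six motion parameters plus backward-difference derivatives (first row
zero), MAD despiking (threshold 4 robust sigmas, epsilon-floored MAD,
cubic-spline replacement from clean samples, abort above 50% flagged),
fifth-order Butterworth 0.01–0.15 Hz applied forward-backward (zero
phase), then cubic-spline resampling to the common TR when acquisitions
differ.  Each step preserves length; filtering is idempotent on passband
content.

## Windowed FNC and states

The taper is a rectangle (44 s → 22 samples at TR 2) convolved with a
±3σ-truncated, renormalized Gaussian (σ = 6 s → 3 samples), so weights
sum exactly to the rectangle length.  The window count convention is
W = T − rect_len: the rectangle start slides over T − 22 onsets, and the
Gaussian tails are truncated (weights renormalized) at the scan edges.
This reproduces the reference bookkeeping of 113 windows from 135 usable
TRs and 93,451 pooled windows over 827 subjects.  Weighted Pearson
correlation uses weights normalized to unit sum per window; zero-variance
windows are flagged invalid and skipped downstream.

k-means uses k-means++ seeding under the chosen metric, assignment by
city-block (default), Euclidean, or correlation distance, and the
matching centroid update (component-wise median for L1 — its within-
cluster optimizer — mean otherwise).  Empty clusters re-seed at the
farthest point; best of n_rep restarts by total assignment distance.
The elbow is found on the within/between cluster-variance ratio curve
(k = 1 is an infinite sentinel and excluded): the knee is the maximum
deviation below the endpoint chord of the *log* ratio curve.  The log
scale makes the transition to the flat regime dominate; on the raw curve
the largest absolute drop wins and lands one k early on planted data.
A knee sharpness (deviation / total log drop) below 0.5 flags a
structureless curve: the result falls back to k = 2, low-confidence.

Three state-fitting strategies are implemented and agree on planted
truth: exemplar two-stage (cluster per-subject variance-peak windows,
then one full pass initialized at those centroids), subject-then-group,
and direct.  Subject state means exist only for visited states (recorded
absent, never imputed); POC is the percentage of all windows per state.

## Group statistics

Framewise displacement is the literal six-term sum of absolute first
differences (rotations in native radians; an optional 50 mm conversion
flag exists).  The cohort GLM is vectorized OLS over features with
design [intercept, diagnosis, age, site dummies (reference = first
lexicographically), mean FD]; constant covariates are dropped with a log
note; t and two-sided p come from the usual normal-equations formulas
(cross-checked against statsmodels in the tests).  The sex-specific
statistic is t_male − t_female; its null permutes sex labels within CT
and within SZ separately (counts preserved and asserted every draw;
degenerate draws redrawn and logged), giving add-one two-sided p-values
with floor 1/(n_perm+1).  All p-values — both cohorts' parametric tests
and the permutation tests, over sFNC and every state — enter one pooled
Benjamini–Hochberg correction at q = 0.05.  Domain aggregation averages
FNC over (domain × order) block pairs, excluding the diagonal within
blocks (singleton blocks are NaN, never 1.0).  Symptom correlations
residualize both feature and score on the covariates before Pearson
correlation; the covariate set is age, site, and mean FD (the reference
analysis lists "mean functional domain", read here as mean framewise
displacement — it is the motion covariate everywhere else; configurable).
BPRS→PANSS conversion is monotone piecewise-linear lookup with clamped
extremes; the mapping table itself is supplied by the user.

## Problem sizes

The test suite and acceptance script run everything at desk scale: the
hierarchy-recovery experiment uses 16 subjects × 250 TRs on 6,760 voxels
with 10 ICASSO runs at orders 4 and 10; the state analysis 50 subjects ×
150 TRs × 12 sources; the type-I-error study 2,000 features × 20 seeds;
permutation checks 199–999 draws.  These sizes were chosen as the
smallest at which the planted-truth assertions are stable across seeds.

## Known limitations

ICASSO's best-run selection assumes the runs mostly agree; with very few
runs a single bad run can win a match by chance.  The elbow criterion is
a heuristic; `k` can always be fixed manually.  The GLM treats site as a
fixed effect (no harmonization or mixed models).  Windowed correlations
at 22-sample support are noisy (sd ≈ 0.2 per pair); state recovery needs
either many windows or well-separated states.  The simulator's effects
enter as covariance offsets, so "Cohen's d" calibrations on FNC features
are approximate.
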