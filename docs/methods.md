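# Methods

`cofluct` estimates how a task reshapes the brain's functional network,
and contrasts that with how it reshapes regional activation, using edge
(cofluctuation) time series. This note documents the models, the
estimation conventions, the synthetic cohort generator and its limits,
and the numerical choices a maintainer needs to know.

## Edge time series and the edge GLM

For parcel series x_i(t) (frames t = 1..T), each series is denoised,
z-scored over the whole run (denominator T − 1) and multiplied
pairwise:

    r_ij(t) = z_i(t) · z_j(t),   i < j.

Summing r_ij over frames and dividing by T − 1 gives exactly the
Pearson correlation of the parents, so an edge series decomposes a
static functional connection into frame-wise contributions. The T − 1
convention is deliberate: it makes this identity hold to machine
precision, and the package checks it as a core contract.

Each edge series is then the response variable of a GLM whose design is
an intercept plus, per task condition (congruent, incongruent), the
condition boxcar convolved with a canonical double-gamma HRF together
with its temporal and dispersion derivatives (7 columns for two
conditions). The intercept estimates the intrinsic (task-free)
correlation; the incongruent-minus-congruent contrast of the main HRF
betas is the task-dependent network change. Resting runs use an
intercept-only design, whose OLS solution is the edge-series mean —
(T − 1)/T times the static Pearson correlation, an identity the tests
verify exactly.

Whether the hemodynamic response applies to edge products at all is an
open question; the HRF regressors are used for symmetry with the node
analysis, and a raw-boxcar variant (`hrf_model="boxcar"`) is provided.

## Denoising

Parcel series are residualized in a single regression (sequential
filtering can reintroduce removed artifacts) on: 12 finite-impulse-
response lags per condition (24 task columns, spanning ~24 s at
TR = 2 s), the 24-parameter motion set (6 rigid-body parameters, their
backward-difference derivatives, and the squares of all twelve), mean
white-matter and CSF signals, the global (whole-brain mean) signal,
discrete-cosine drift terms for periods strictly above 187 s, and an
intercept — 57 columns with the defaults. FIR task removal prevents
evoked responses from inflating edge correlations; it is switchable
(`remove_task=False`) because the global-cofluctuation (RSS) analysis
deliberately keeps task effects in. Global-signal regression is a
contested step and is a first-class toggle (`gsr`).

Conventions: a frame belongs to a block iff its acquisition time
frame_index·TR falls in [onset, onset + duration); FIR columns are
lagged stimulus indicators truncated at the run end (no wrap-around);
convolution happens at frame resolution (an oversampling option exists,
but block durations ≫ TR make it immaterial); motion derivatives are
backward differences with 0 at the first frame; the cosine count uses a
strict inequality (280 frames at TR 2 s with a 187-s cutoff gives
exactly 5 terms).

### HRF constants

The double-gamma kernel is the SPM-style gamma difference: a response
gamma with shape 6 and unit scale minus 1/6 of an undershoot gamma with
shape 16 and unit scale, truncated at 32 s. The temporal derivative is
a finite difference in time (1-s step); the dispersion derivative a
finite difference in the response-gamma scale (step 0.01). The kernel
shape matches nilearn's SPM HRF to ρ > 0.999 at 0.1-s resolution (their
sampling convention is shifted by one bin).

## GLM estimation

All analyses share one mass-univariate estimator: OLS with optional
AR(1) prewhitening. The AR coefficient is the lag-1 autocorrelation of
each target's OLS residuals (Cochrane–Orcutt one step, clipped to
|ρ| < 0.999, estimated per target; a pooled option exists). Both the
response and the design are whitened: row 0 is scaled by √(1 − ρ²),
row t becomes row_t − ρ·row_{t−1}. Since ρ varies across targets, the
whitened design is target-specific and the normal equations are solved
in a batched pass.

Residual degrees of freedom are frames minus design rank; the extra
loss from estimating ρ is ignored, as is standard. Because per-target
autocorrelation makes subject-level dof vary across nodes and edges,
subject-level similarity analyses use β maps, not t maps.

Contrasts: effect = c'β, var = σ̂²·c'(X'X)⁻¹c, two-sided p from
Student's t. Degenerate targets (zero residual variance, which
synthetic fixtures can produce) yield a ±∞ t sentinel with p = 0 and a
warning rather than crashing the mass-univariate loop. Residual sums
below √ε-level rounding noise are treated as exactly zero.

A `standardize` toggle z-scores the response and non-constant design
columns inside the GLM (it changes β scales, not t statistics — a test
pins this down).

## Node activation GLM

The same estimator on the parcel series themselves, with a design
holding the HRF triplets plus the full nuisance set (including the
global signal, kept for symmetry with the edge analysis). The reported
map is the incongruent-vs-congruent contrast.

## Generalized psychophysiological interaction (gPPI)

For every ordered pair (seed j → target i), the raw target series is
regressed on an intercept, the raw seed series (background coupling),
the task block (HRF triplets of both conditions), one interaction term
per condition — the observed seed series times that condition's main
HRF regressor — and the nuisance covariates. No deconvolution is
applied (block designs make it unnecessary); derivative columns stay in
the task block but are not interacted. The pair's coupling change is
the incongruent-minus-congruent difference of the interaction betas;
the directed matrix is symmetrized by averaging its upper and lower
triangles. A rank-deficient pair is skipped and logged rather than
failing the run.

## Group statistics

Group maps are classical one-sample t tests of subject-level effects
against zero (dof = N − 1); paired maps are one-sample tests on
differences. Family-wise control uses Holm–Bonferroni; FDR control uses
Benjamini–Hochberg (both via statsmodels). Group t values convert to
correlations through r² = t²/(t² + N − 1) with the sign of t. All tests
are two-sided, since effects of both signs are of interest.

The top-fraction sign test selects the ⌊fraction·E⌋ edges with the
largest |t| per map (ties broken toward lower edge index), tabulates
positive/negative signs across the two maps and applies Fisher's exact
test; zero-t edges are excluded from the counts, and a zero cell
triggers the Haldane 0.5 continuity correction for the odds ratio (the
p-value stays exact). The default fraction is 0.01.

## Similarity battery

* Spearman ρ between unthresholded group t maps; Dice coefficient
  between significance masks (defined as 1 when both masks are empty).
  Dice masks encode significance only, not sign agreement (a signed
  variant exists but is not the default).
* Similarity as a function of group size: subjects are subsampled
  without replacement, group maps recomputed, and ρ plus Dice over an
  α grid reported as mean ± sd over repeats.
* Edge subsampling: the distribution of ρ over random k-edge subsets,
  to rule out feature-count effects.
* Region-wise similarity: each region's whole-brain profile (its row of
  the symmetric edge-statistic matrix, diagonal removed, length
  n_regions − 1) correlated between tasks.
* Subject-level similarity: per subject, Spearman ρ between the two
  tasks' β maps, separately for activation and network maps; the two
  similarity distributions are compared by a paired t test and paired
  Cohen's d (mean difference over the sample sd of differences,
  ddof = 1). The paired t runs on raw ρ values (a Fisher-z option
  exists), since mean ρ is the quantity of interest.
* Mantel test: Pearson r between the upper triangles of two
  subject-distance matrices (d_ij = 1 − ρ_ij), permutation p by joint
  row/column relabelling of one matrix (two-sided, add-one rule), and a
  confidence interval from the 2.5/97.5 percentiles of r over subject
  subsamples of size ⌈0.135·n⌉ drawn without replacement. The
  permutation count is a free parameter (only the CI procedure is
  fixed); scikit-bio's Mantel implementation serves as an independent
  cross-check in the tests.
* SNR filtering: an element's group SNR is mean(contrast)/sd(contrast)
  across subjects — a group-level Cohen's d; elements are retained when
  SNR exceeds the threshold in every supplied task. An activation
  filter on |d| > 0.8 supports the restricted-region robustness check.

## Synthetic cohort generator

The generator produces, per subject, two task runs (280 frames,
TR = 2 s) and a resting run (150 frames = 5 min), with full ground
truth. Schedules hold four congruent and four incongruent blocks of
52–60 s, each preceded by a 10–17-s fixation, alternating and starting
incongruent; durations are drawn by rejection sampling until the
schedule fits the run. A deterministic mode (`jitter_blocks=False`)
fixes blocks at 56 s and stretches fixations to tile the run exactly
(14 s here), making the schedule's block-alternation fundamental
(1/70 Hz) land exactly on the periodogram grid.

Signals follow x(t) ~ N(μ(t), Σ(t)), temporally coloured by AR(1)
(ρ = 0.4, innovations scaled by √(1 − ρ²) so the stationary covariance
equals Σ):

* μ(t): per-condition amplitude vectors times the HRF-convolved
  boxcars. Every region carries a weak background amplitude
  (N(0, 1.0) in noise-sd units, shared across tasks) and 10 regions add
  a strong response (U(0.5, 1.5) × 3.0); congruent amplitudes are half
  the incongruent ones. Widespread heterogeneous responses — rather
  than a few active regions in a silent brain — are what real conflict
  tasks evoke, and they are what makes global cofluctuation (RSS)
  task-locking physically detectable.
* Σ(t): a modular intrinsic correlation matrix (4 systems,
  within-system r = 0.3, between 0.05) plus condition-gated deltas:
  +0.3 on 30 planted incongruent edges and +0.1 on 30 disjoint
  congruent edges, gated by the raw condition boxcar (an HRF-gated
  option exists; whether edge cofluctuations follow the HRF is an open
  question, so the raw gate is the default). Non-PSD state covariances
  (possible for large deltas) are eigenvalue-clipped at 1e-6 with a
  warning.
* Per-subject variation: a multiplicative gain (1 + 0.2·z) shared by a
  subject's amplitudes and deltas across both tasks.
* Confounds: random-walk motion (6 parameters), AR(1) tissue signals,
  all leaking weakly (0.1) into the parcels through random loadings;
  the global-signal confound is the realized parcel mean plus noise.

**Dissociation mode** (default): tasks A and B share the amplitude
vectors exactly but their planted covariance edge sets are disjoint —
the ground-truth analogue of two tasks with near-identical activation
patterns and different network profiles.

What the generator does **not** emulate: spatially structured
(voxel-level) noise, hemodynamic nonlinearity and variability, subject-
specific intrinsic connectomes, behavioural coupling, or realistic
motion artifact spectra. Passing tests therefore demonstrate estimator
correctness and the internal consistency of the analysis logic, not
performance guarantees on real acquisitions.

The condition-covariance effect size (|Δ| = 0.3 on the correlation
scale) is chosen for test power at desk scale — real effect sizes for
condition-dependent covariance changes are unknown.

## Validation battery and problem sizes

Because the motivating dataset is not publicly deposited, validation
substitutes identities and recovery (see `cofluct.validation` and
`scripts/acceptance.py`):

* exact identities: 268 regions → 35,778 edges; 5 cosine terms at
  280 frames/TR 2/187 s; 24 FIR task columns; 267-entry region
  profiles; the Pearson decomposition to 1e-10; OLS vs explicit normal
  equations to 1e-9; the t→r identity to 1e-12;
* error control: Holm FWER and BH FDR over 1,000 simulations of 200
  elements;
* recovery: planted-edge AUC ≥ 0.9 at 20 subjects, 40 regions, 280
  frames, |Δ| = 0.3;
* dissociation: over 50 replicate cohorts, group activation similarity
  exceeds network similarity in ≥ 95% of replicates, and the
  subject-level paired t is significant;
* spectrum: the cohort-mean RSS periodogram (task effects kept) peaks
  at the schedule's block-alternation fundamental;
* comparator concordance: group gPPI and edge-GLM contrast maps
  correlate positively (Spearman, p < 0.01).

Desk-scale defaults (20 subjects × 40 regions) keep the whole battery
in the minutes range; the full-scale geometry (hundreds of subjects ×
268 regions) is reachable through `CohortConfig` but is not the
default.

## Known limitations

* AR(1) only; no higher-order or pooled-spatial noise models.
* The dof adjustment for prewhitening is the standard approximation.
* gPPI interacts only the main HRF regressors; including derivative
  interactions would change the comparator slightly.
* The FIR basis truncates at the run end; responses to events near the
  end are partially modelled.
* Voxel-level estimation, surface formats and BIDS-App orchestration
  are out of scope.
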