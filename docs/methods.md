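# Methods

`taskstates` implements a task-EEG microstate analysis chain on simulated
event-related-potential (ERP) cohorts: a generative model with planted
ground truth, preprocessing, polarity-invariant topographic clustering
with model selection, backfitting and parameter extraction, and the mixed
repeated-measures statistics of a three-group / two-treatment-arm study
design.  This note records the model, the defaults and why they were
chosen, and what the synthetic world does and does not establish.

## The microstate model

A microstate is a short (~60–120 ms) period during which the scalp
voltage topography is quasi-stable up to polarity and amplitude.  Let
`v_t ∈ R^C` be the average-referenced topography at sample `t` over `C`
channels.  The engine works with:

* **GFP** (global field power): the across-channel population standard
  deviation of `v_t`; with average-referenced data,
  `GFP(t) = ||v_t|| / sqrt(C)`.
* **Spatial correlation**: the Pearson correlation of two topographies
  across channels; taken in absolute value ("polarity invariant"), so a
  map and its negation denote the same state.
* **Modified k-means**: each sample is assigned to the prototype map
  `a_k` (zero-mean, unit-norm) maximizing the squared spatial
  correlation; each prototype is re-estimated as the dominant
  eigenvector of `Σ_{t∈k} v_t v_tᵀ` (the polarity-invariant centroid).
  Iteration stops when the relative GEV change falls below 1e-6 or after
  the iteration cap (default 1000); the best of `restarts` (default 50
  at the library surface, 20 in the pipeline) seeded initializations by
  GEV is kept.  An empty class is re-seeded from the currently
  worst-explained sample.
* **GEV** (global explained variance):
  `GEV = Σ_t [GFP(t)·corr(v_t, a_{l(t)})]² / Σ_t GFP(t)²`, the
  GFP-weighted share of topographic variance explained by a labeling
  `l`.  Per-class GEV restricts the numerator to that class's samples,
  so class GEVs sum exactly to the total.
* **CV criterion** (predictive residual variance):
  `CV = σ̂² · ((C−1)/(C−1−K))²` with
  `σ̂² = Σ_t (v_tᵀv_t − (a_{k(t)}ᵀv_t)²) / (T(C−1))`.
  Lower is better; the penalty term diverges at `K = C−1`, where the
  criterion is undefined and an error is raised.  Model selection fits
  every K in a range (default 2..8) and reports the full GEV/CV table;
  the returned `K*` minimizes CV, but the table supports the joint
  "larger GEV, smaller CV" judgment.
* **Backfitting**: a fixed map set labels each ERP sample by maximal
  absolute spatial correlation; ties break to the lowest class index,
  zero-variance samples get label 0 (unassigned).
* **Parameters** per class: coverage = labeled samples / assigned
  samples; duration = mean length of maximal runs in ms (edge-touching
  runs included); occurrence = number of runs per second of epoch.
  Under these conventions `occurrence × duration = coverage` holds
  exactly when every sample is assigned.  An alternative occurrence
  normalization per *assigned* second is available
  (`occurrence_denominator="assigned"`); published task-microstate
  occurrence values are ambiguous between the two, and the per-epoch
  convention is the default because it keeps the identity exact.

### Smoothing

`smooth_labels` re-assigns segments shorter than a minimum duration to
the better-correlated neighboring class, iterating to stability.  The
library default is off.  The *pipeline* default is 30 ms: the synthetic
GFP envelope passes through zero at every segment boundary, so boundary
samples are noise-dominated and fragment backfit runs to roughly half
the planted duration; 30 ms is the conventional microstate floor and
restores run structure without touching genuine segments.

## The synthetic world

`simulate_cohort` emulates a study with three groups (healthy controls
n=20, depressed n=52, depressed with nonsuicidal self-injury n=66), two
picture-cue conditions (150 neutral / 50 negative trials), 64-channel
epochs of −200..1000 ms at 500 Hz, and an optional longitudinal design
(medication n=31 vs medication+rTMS n=21, before/after).  Components:

* **Montage**: an idealized spherical 10-10 layout built from electrode
  arc geometry (rows Fp..O between the midline and the 10% temporal
  circle).  Only relative geometry matters (interpolation neighborhoods,
  smooth synthetic maps).  Custom layouts load from a `name x y z`
  sidecar.
* **Prototype maps**: random dipole patterns windowed by a Gaussian bump
  on the scalp, zero-meaned and normalized, rejected until all pairwise
  polarity-invariant correlations are ≤ 0.7.
* **Label sequences**: one sequence per subject × condition cell; every
  trial in the cell shares it (time-locked signal), so trial averaging
  raises effective SNR by √n_trials.  Sequences are *composed*: each
  class receives `round(coverage × T)` samples, split into segments with
  gamma-shaped (shape 4) length proportions, interleaved avoiding
  same-class adjacency.  The segment count per class uses
  expectation-matched stochastic rounding so realized mean durations are
  unbiased.  `simulate_epoch` (the single-trial generator) instead draws
  i.i.d. gamma dwell times.
* **Signal and noise**: within a segment every sample is the class map
  scaled by a positive half-sine envelope (peak 1); spatially and
  temporally white Gaussian noise is added so that mean signal GFP over
  mean noise GFP equals `snr` (default 5; `inf` disables noise).
* **Subject variability**: a per-subject lognormal duration scale
  (σ = 0.15, shared across that subject's cells, keeping conditions
  correlated within subject) and a per-cell Dirichlet draw of the
  coverage vector around the target (concentration 100, per-class SD
  ≈ 0.05, matching the order of published coverage SDs).  Realized
  per-cell duration additionally carries segment-count quantization: a
  ~200 ms class in a 1.2 s epoch has only 2–3 runs, so its per-cell mean
  duration is bimodal with SD 80–100 ms.  This is faithful to the
  measurement, and reproduces published duration SDs of 60–90 ms
  without any extra dial.
* **Scales**: HAMD (0–52), PHQ-9 (0–27), NSSI score and age (12–17) are
  truncated normals at per-cell means/SDs taken from the study's
  demographic and treatment tables; sex is Bernoulli at the group's male
  fraction.  Longitudinal draws share a per-subject level with pre/post
  correlation 0.5 — a conventional test-retest figure; the study reports
  none.

What a green test on this world does **not** establish: robustness to
ocular/muscle artifacts, volume-conduction realism, non-time-locked
(induced) activity, latency jitter across trials (a jitter parameter
exists, default 0, since no value is reported), or behavior-based trial
exclusion (correct-response filtering is a pass-through hook).

## Preprocessing

Polyphase resampling (anti-aliased), zero-phase Butterworth filtering as
a cascade of a high-pass (order 2) and a low-pass (order 4) — a single
band-pass design is numerically ill-conditioned when the edges differ by
orders of magnitude (0.1 vs 30 Hz) — half-open epoching (−200..1000 ms
at 500 Hz is exactly 600 samples), optional baseline subtraction,
peak-to-peak trial rejection (default 100 µV), inverse-distance-weighted
interpolation of bad channels from their k=6 nearest neighbors, common
average reference, and trial averaging.

Two pipeline defaults deliberately differ from the real-data settings,
because the synthetic signal is drift-free and time-locked into the
pre-stimulus window: baseline correction is off (subtracting a baseline
mean that contains genuine topography distorts every map; measured map
recovery drops from ≥0.997 to ~0.65) and the filter band is (0, 30) Hz
(a 0.1 Hz high-pass applied to a 1.2 s epoch reduces to per-channel mean
removal — the same distortion; the study filtered continuous recordings
before segmenting).  Both operations keep their conventional defaults at
the library surface for real-data use.

## Shared template and group tables

The pipeline clusters the *concatenated* samples of every subject ×
condition ERP and backfits the resulting single template to each cell,
so class indices are comparable across groups, cues, arms and times.
Concatenation rather than pointwise grand averaging is essential here:
averaging across subjects whose sequences are not strictly time-locked
cancels topographic structure.  Per-group-and-condition clustering with
post-hoc class matching is the main alternative; how the original
analysis matched classes across cells is not stated, so the shared
template is this package's choice.

## Statistics

* **Summary one-way ANOVA** reconstructs between/within sums of squares
  from per-group (mean, SD, n); with published inputs rounded to 2–3
  decimals, agreement with printed F values is limited to ~0.5% for
  large effects and ~2% for small ones.
* **Chi-square** is Pearson's test without continuity correction.
* **Mixed ANOVA** is a split-plot general linear model: one between
  factor (sum-to-zero coded), one or two within factors (orthonormal
  contrast strata), optional subject-constant covariates (mean-centered;
  two-level string covariates 0/1 coded).  Sums of squares are Type III
  by model comparison.  Covariates are carried in **every** stratum, the
  convention of the mainstream commercial GLM: with N subjects, g
  groups, c covariates and a two-level within factor, every error df is
  N − g − c (138 − 3 − 2 = 133 in the cross-sectional design — matching
  the study's printed denominators).  Greenhouse–Geisser ε is estimated
  from each stratum's residual covariance in contrast space
  (tr(S)²/(q·tr(S²))); two-level factors force ε = 1.  Corrected and
  uncorrected dfs are both reported; ε < 0.75 is flagged in the log.
  Subjects missing any within-subject cell are removed listwise with a
  logged count.
* **Simple effects** test the other factor of an interaction within each
  level of the slicing factor, with either the pooled omnibus error
  (default) or the slice's own error; pairwise follow-ups are
  Holm-adjusted within slice.
* **Holm** adjustment is the standard step-down procedure (monotone,
  capped at 1, input order restored).
* **Difference correlations** pair each subject's after-minus-before
  scale change with each parameter × class change, Pearson r with
  two-sided p, Holm-adjusted across all pairs.

Type-I error of the 2×3 design with covariates is verified by
Monte-Carlo (500 null replicates, empirical α within [0.03, 0.07]).

## Scaled-down designs and power

End-to-end runs default to a CI-scale design (n = 10/12/15 per group, 30
trials per condition; `paper_scale_design()` restores 138 subjects and
200 trials).  At n = 37 the study-scale cue × group differential on
class-3 duration is undetectable (analytic power ≈ 0.2 against the
generator's realization noise), so the scaled-down design plants a
larger "designed effect": ×4 on the duration differential (noncentral-F
power ≈ 0.9 at ground-truth level against the quantization-dominated
noise described above) and ×2 on coverage (quantization-free, power
≈ 1).  Because coverage sums to one, boosting class 3 re-balances
classes 1–2, which therefore also carry (compensating) cue × group
differences by construction.  Longitudinal scale effects need no boost:
the published treatment-arm means/SDs give ≈ 0.85 power for the HAMD
time × group interaction at n = 31/21 with pre/post correlation 0.5.

## Numerical choices

* Half-open, 0-based sample grid everywhere; baseline window −200..0 ms.
* k-means tolerance 1e-6 relative GEV change; map update eigendecomposes
  the C×C scatter of assigned samples.
* Ties in assignment and backfitting break to the lowest class index;
  all stochastic steps consume explicit seeds, and a run's master seed
  fans out to fixed per-stage child seeds (simulation, scales,
  clustering), so every stage and every written file reproduces
  byte-identically; outputs carry the config hash in a header comment.
* Sums of squares below 1e-12 of the response scale are clipped to zero
  so constant responses yield F = 0 rather than 0/0 noise.
* Classes absent from a labeling get coverage 0, occurrence 0 and an
  undefined (NaN) duration; ANOVAs on a class with too many missing
  cells are skipped with a logged warning, not fatal.

## Known limitations

* EDF I/O is not provided; all interchange uses delimited text with
  JSON/TSV sidecars.
* No ICA; real recordings must be cleaned upstream.
* No resting-state microstate syntax (transition matrices, Markov
  tests) and no source localization.
* The mixed ANOVA expects balanced within-subject cells after listwise
  removal; unbalanced within-cell replication is averaged per cell.
* Simple-effects error terms are a convention choice; both options are
  exposed because the original analysis does not state its own.
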