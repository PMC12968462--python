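# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `netreconf`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Windowed connectivity

Windows are specified in seconds and converted to samples by rounding
(`L = round(window_seconds / TR)`, `S = round(step_seconds / TR)`); at
TR = 1 s the defaults are exact (60 → 60 samples, 10 → 10). Window starts
are `0, S, 2S, …` and the count is `floor((N − L)/S) + 1`; trailing samples
that do not fill a window are dropped, never padded, so 300 samples give
exactly 25 windows at 60/10 and 26 at 44/10.

Edge weights are `|atanh(r)|` of the within-window Pearson correlation.
The correlation is clipped to ±(1 − 1e−7) before the transform so that a
perfectly correlated pair yields a large finite weight (≈ 8.4) rather than
infinity. The diagonal is forced to zero: self-connectivity plays no role
in community quality or reallocation. Each window's matrix is symmetrized
as `(Z + Zᵀ)/2` to remove float asymmetries of order 1e−16. A region with
zero variance inside any window is a hard error naming the region and the
window — constant signals are tolerated at read time (with a warning) and
rejected exactly where the mathematics breaks. Pearson correlation centres
each window implicitly; no additional per-window detrending is applied.

## Community detection

Each window is seeded independently from the canonical eight-network
assignment (seven cortical resting-state networks plus a deep grey matter
group; integer labels 1–8 in the order DMN, FPN, DAN, VAN, VN, SMN, LN,
DGM). Detection iterates:

1. score every region's assignment quality
   `q_i = mean(w_i→own community, self excluded) − max_{c≠own} mean(w_i→c)`;
2. select the region with the lowest quality (ties → lowest index);
3. reallocate it to the community with maximal mean connectivity (ties →
   keep the current label if tied, else lowest community index);
4. stop when the same region is selected in two consecutive iterations,
   when the proposed move is a no-op, or at `max_iterations` (default
   1000, a safety cap that is never reached in practice).

Design choices worth recording:

* **Quality and reallocation are two views of one quantity.** The quality
  score is the gap between own-community and best-other-community mean
  connectivity, so the region selected for reallocation is exactly the one
  whose reallocation target is most attractive. The score is pluggable
  (`quality_fn`) because other defensible definitions exist; this is the
  main fidelity risk relative to other implementations of the same
  procedure, and it is isolated behind a single interface.
* **Mean, not sum.** Connectivity to a community is the mean of edge
  weights to its members; a sum would systematically attract regions to
  the largest network.
* **Moving a region never lowers its own quality**: a region's row of
  community means excludes itself, so the move changes other regions'
  means but not the mover's, and the chosen target maximizes its own-mean.
  This monotonicity is asserted from the recorded `DetectionTrace`.
* **The two stop rules coincide at convergence.** A region selected twice
  in a row necessarily proposes a no-op the second time (its row of means
  is unchanged by its own move), which also makes detection a fixed point
  of itself: re-seeding with its own output returns the same labels.
* **Communities may empty.** If the last member leaves a community, the
  label simply goes unused in that window; K stays fixed at 8, which keeps
  the promiscuity denominator stable.
* Windows are detected independently; there is no temporal coupling or
  multilayer resolution parameter, and no randomness anywhere — identical
  inputs give identical assignment matrices.

## Reconfiguration metrics

For a regions × windows assignment matrix with T windows and K = 8
communities:

* **promiscuity** — distinct labels in the node's row / K. The initial
  label counts as visited; the denominator stays K even when some
  communities go unused (the denominator is a recorded configuration value,
  `promiscuity_denominator`, for sensitivity analyses).
* **flexibility** — label changes / (T − 1).
* **cohesion / disjointedness** — a switch at transition t is *cohesive*
  iff at least one other node switches at the same transition from the
  same source to the same destination, else *disjoint*; each fraction is
  the count / (T − 1). Requiring identical source AND destination makes
  the two classes partition the switch set, so
  flexibility = cohesion + disjointedness holds exactly per node (up to
  float rounding when the integer counts are divided). Cohesive partner
  sets are retained for export; the reported cohesion is the fraction of
  transitions, not a pairwise partner-count sum.

Aggregation is the unweighted node mean, globally and per network, where a
node's network is its *static* literature-based membership (a stable
grouping is needed for group statistics); a network with no members is
reported as missing, never as 0. All four metrics are invariant under any
permutation of community labels, and exhaustive enumeration against an
independent brute-force implementation (all shapes up to 4 nodes ×
4 windows × 3 communities with label spaces up to ~600k matrices, plus
50,000 random draws of the 43-million-matrix 4×4×3 shape, which is beyond
an exhaustive sweep at test time) confirms exact agreement.

## Surrogate nulls

Surrogates add random phases to every positive-frequency bin of each
region's real FFT; the DC bin is untouched and, for even-length series,
the Nyquist bin is multiplied by a random sign so the inverse transform is
real. Amplitude spectra are preserved exactly (validated to 1e−8
relative). Two phase modes:

* `multivariate_common_phase` (default): one phase vector shared by all
  regions. Cross-spectra, and therefore the full-series correlation
  matrix, are preserved exactly — the null keeps static connectivity and
  destroys only its temporal organisation, which is precisely the
  confound a time-varying analysis must rule out.
* `independent_phase`: independent phases per region; expected cross-
  correlations vanish.

The number of runs (default 50) and the averaging mode are mandatory
configuration: `average_series` averages the surrogate series elementwise
and runs the pipeline once (the literal reading of "the average was used
as surrogate data"); `average_metrics` runs the pipeline per surrogate and
averages the metrics. Both are implemented because averaging series
shrinks variance and is an unusual null; the mode is always logged, and
with one run the two coincide. Null metrics enter the group comparison as
a per-subject covariate; a constant null covariate is dropped so the model
reduces exactly to the unadjusted one.

Empirically (and asserted one-sided in the tests), phase randomization
*raises* flexibility on data with planted switches: a mobile region's
time-averaged, mixed correlation profile survives in the surrogate but its
visits are no longer localised in time, so its per-window assignment
becomes unstable.

## Group statistics

* **Correlations**: Pearson r with the two-sided t-transform p (n − 2 df),
  separately per group; Bonferroni with an explicit, caller-declared
  family size (default: the number of metric columns tested), echoed in
  every report. Zero-variance cells are flagged, not silently NaN.
* **ANCOVA**: OLS `metric ~ group + age + sex + education`; the group
  effect is the 1-df F = t² of the group indicator, identical to the
  classical ANCOVA F for a two-level factor. Collinear designs raise an
  error naming an offending column. Calibration: type-I error ≈ 0.044 at
  α = 0.05, n = 100 (measured in the acceptance suite over 500 null
  replicates).
* **Hierarchical ENTER regression**: ordered blocks demographics (age,
  sex, education) → clinical (EDSS, disease duration, DMT dummies with
  "none" as reference; absent categories are dropped rather than left as
  rank-deficient all-zero columns) → structural (normalized brain volume,
  T2 lesion load) → the reconfiguration predictor. Complete cases only,
  with the dropped count reported. The standardized β z-scores the
  response and all continuous predictors (binary indicators are left
  as-is). Note the standardized-β estimator carries a small positive
  finite-sample bias (≈ +0.01 at n = 155 with this covariate set) because
  the estimated sd of the response appears in the denominator; the
  acceptance suite checks 2-SE coverage of a planted β = 0.2 rather than
  exact unbiasedness.

## Synthetic data

The generator emulates a parcellated resting-state acquisition: 200
regions × 300 timepoints at TR = 1 s, eight networks of 25 regions, and
band-limited signals (white noise filtered to 0.01–0.1 Hz, matching a
standard high-pass preprocessing cut-off). Each community carries an
independent unit-variance latent; region i emits
`sqrt(ρ)·latent + sqrt(1−ρ)·noise` with coupling ρ (default 0.8), giving
within-community correlation ρ.

Planted switching is scheduled per mover unit (single regions for
disjoint events, groups of 2–3 sharing a source for cohesive events) as a
renewal process: consecutive switches are separated by at least 4 windows
(40 s) plus a Poisson extra dwell whose mean is drawn per unit, and
switches avoid the first and last transition. The minimum dwell is a
deliberate fidelity constraint: a 60-s sliding window can never see a
visit shorter than ~40 s in majority, so shorter planted visits would be
unrecoverable by construction, by any method operating on these windows.
In signal space a planted transition between windows w and w+1 takes
effect at the sample midway between the two windows' *centres*, which
makes every truth column the majority membership of its own (overlapping)
window; mapping it midway between the window *starts* would make the
edge window majority-new while its truth column says old.

The exact metrics of the planted assignment matrix (computed by the same
metric layer, and cross-checked against the brute-force oracle) serve as
ground truth. The recovery experiment fixes one planted template and
generates independent signal realizations: with ρ = 0.8, 20 realizations,
the pipeline recovers ≈ 93% of assignment entries, and replicate-averaged
node flexibility correlates with planted flexibility at r ≈ 0.99 (≈ 0.90
per single realization, pooled).

Cohorts draw switching intensity heterogeneously across subjects so the
planted metrics vary, then generate patient fatigue scales as
`μ + σ·(Σ_m e_m·z(metric_m) + sqrt(1 − Σe²)·ε)` at declared standardized
effects (defaults: disjointedness→fatigue 0.24/0.28/0.18 for
total/motor/cognitive), clipped to the instrument ranges (total ≤ 100,
subscales ≤ 50); controls get no metric dependence. Clipping mildly
attenuates the realized correlation; with the default means and SDs the
clip rate is ≈ 1% and the recovered planted-level correlation of a 0.24
effect averages 0.24 within sampling error (checked over seeds in the
tests). With several metrics mapped to one scale the declared effect is
exact only if the planted metrics were uncorrelated; the single-metric
default avoids the issue. Covariate distributions (age, sex, education,
EDSS, disease duration, nine-category DMT frequencies, brain volume,
lesion load) follow the clinical template of a 155-patient/48-control
fatigue study.

What the generator does *not* emulate: hemodynamic response convolution,
head motion, scanner drift and physiological noise, spatial autocorrelation
between neighbouring parcels, or heavy-tailed/asymmetric fatigue
distributions. Passing recovery tests therefore demonstrates the pipeline's
correctness and its behaviour under realistic band-limited noise and
window-resolvable dynamics — not robustness to preprocessing artefacts or
to dynamics faster than the window.

## Pipeline and reproducibility

The file-level pipeline is a pure function of (config, inputs): the
resolved JSON config is written beside the outputs, every output file is
checksummed into `manifest.json`, and reruns are byte-identical. Stage
subcommands (`connectivity`, `communities`, `metrics`, `nulls`, `stats`)
recompute deterministically from the raw inputs up to their stage rather
than parsing intermediate files back in; because outputs are pure in
(config, inputs), the result is identical to resuming from a predecessor's
files. Exit codes: 0 success, 2 validation error, 3 stage failure.
Detection iteration counts, convergence flags and full reassignment traces
are logged (`detection_traces.jsonl`) so the stopping behaviour is
auditable.

Problem sizes in the test and acceptance runs (12–20 subjects for
recovery, 300–500 replicates for calibration, 5,000–50,000 random matrices
at the largest oracle shape) are chosen to exercise every code path at
desk scale; all are parameters, not limits of the implementation.

## Known limitations

* The assignment-quality function matches the verbal description of the
  original procedure but the reference implementation's exact score is not
  published; results could differ in detail (pluggable `quality_fn`).
* Coverage fractions are taken as given; whether they were computed before
  or after lesion filling in any particular dataset is outside this
  package's scope.
* Sliding-window correlation cannot resolve dynamics faster than the
  window; the generator deliberately does not plant such dynamics.
* No tapered windows, DCC/GARCH, HMM state models, modularity-maximization
  or multilayer community detection, AAFT/IAAFT surrogates, or
  robust/mixed-effects statistics.
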