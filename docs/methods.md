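# Methods

## Analysis model

The pipeline operates on per-subject, per-session coherence values
(dimensionless, in [0, 1]) defined over pairs of source-space grid points,
for a set of frequency bands and post-stimulus time windows, in two task
conditions (picture naming and a visual baseline).  Its basic quantity is
the **task contrast**: naming − visual coherence per connection.  Working
on contrasts cancels spatial-leakage structure that is constant across
conditions, which is why the synthetic generator also only commits to the
distribution of contrasts, not of raw coherence.

### Connection selection (session 1 only)

Per band × window, a paired t-test over subjects is applied to every
grid-pair contrast in the first session; two-sidedness is used because
both increases and decreases are analyzed downstream.  Connections with
zero-variance differences are flagged degenerate and excluded.  Survivors
at the uncorrected threshold (selection A: 10⁻³, selection B: 10⁻⁴) are
additionally required to span ≥ 4 cm between endpoints; the limit is
inclusive (exactly 4 cm is retained).  Selection uses only session 1 so
that the session-2-involving reliability analysis is not circular.

**Bundles.**  The distance between two undirected connections
c₁ = (a₁, b₁) and c₂ = (a₂, b₂) is defined as

    d(c₁, c₂) = min over the two endpoint pairings of
                max(‖a₁ − a₂‖, ‖b₁ − b₂‖)   (resp. the crossed pairing),

i.e. two connections are close only when *both* endpoints can be matched
within the distance.  Bundles are the connected components (single
linkage) of the graph linking connections with d ≤ 1.3 cm; components
with fewer than 20 members are discarded.  This is the closest
brute-force-testable reading of a "maximum distance between connections"
criterion for undirected connections, and it is validated against a
transitive-closure oracle in the tests.

**Parcel mapping and aggregation.**  Each retained bundle member
contributes the unordered pair of its endpoint parcels; pairs touching
excluded (anterior) parcels and within-parcel pairs are dropped and
duplicates merged.  For each resulting parcel edge the contrast is summed
over *all* grid pairs between the two parcels present in the connection
index — not only the selected ones — separately per subject and session.
The modulation direction (increase/decrease) is the sign of the session-1
group mean of that summed contrast; an exact zero (a probability-zero
event under the generator) tie-breaks to "increase" with a warning.

**Power screen.**  Task power differences can masquerade as coherence
differences.  The screen computes r = |Pₙ − Pᵥ| / ((Pₙ + Pᵥ)/2) per
subject and parcel (r := 0 when both powers are zero) and flags entries
where r > 0.20 for at least five subjects ("more than four").  The
symmetric normalization by the condition mean avoids task-order
asymmetry, since no denominator convention is canonical.  Flags are
reported, not auto-excluded; an exclusion can be wired in by the caller.

### Reliability: ICC(3,1)

For each parcel edge the n × 2 subjects × sessions matrix of summed
contrasts is decomposed by a two-way ANOVA without replicates: BMS from
subject means, JMS from session means (computed and reported but unused),
EMS from the residual.  The consistency ICC is

    ICC(3,1) = (BMS − EMS) / (BMS + (k − 1)·EMS),  k = 2.

This form ranks subjects consistently across sessions and is insensitive
to additive session offsets and to positive rescaling (both properties
are asserted as invariants).  The 95% CI uses the Shrout–Fleiss F-based
construction: F = BMS/EMS with (n−1, (n−1)(k−1)) degrees of freedom,
bounds F/F₀.₉₇₅(n−1, df₂) and F·F₀.₉₇₅(df₂, n−1) mapped through
(x − 1)/(x + k − 1).  No CI method is canonical for this setting; the
F-based interval is the standard for this ICC form and, for k = 2, it
coincides with the parametric-bootstrap percentile interval (verified to
0.02 against a 2·10⁵-rep bootstrap in the tests).  Classification is
strict: consistent iff ICC > threshold, default 0.4 with 0.5 exposed as a
replication threshold.  Degenerate edges (BMS = EMS = 0) are labeled
inconsistent and logged rather than aborting a run.

### Properties of consistent vs. inconsistent edges

Edges are pooled over bands and windows; the edge identity is the
(parcel pair, band, window) triple throughout, so the same parcel pair
may appear in several band/window strata.

* **Behavior.**  Per edge, OLS of the per-subject mean-over-sessions
  contrast on the three language scores with intercept; overall F-test
  with (3, n−4) df; "fitted" means p < 0.05.  Deliberately *no*
  multiple-testing correction: the group comparison is of nominal fit
  *rates*, which are equally inflated in both groups.  This is a caveat
  for interpreting any individual edge's p-value.
* **Chi-square tests.**  Pearson independence tests with the Yates
  continuity correction applied automatically iff the table is 2×2.
  This convention is the only one consistent with both reference
  statistics the package reproduces (a 2×3 statistic computed without
  correction and a 2×2 one with); an override flag is provided.
* **Mann-Whitney.**  Two-sided throughout; exact enumeration when both
  groups have ≤ 20 observations and no ties, tie-corrected normal
  approximation otherwise.  Absolute mean strength applies the absolute
  value *after* averaging over subjects and sessions, so sign
  cancellation across subjects yields small strength by design.
* **Structural metrics.**  Streamline weights map to edge lengths by
  elementwise reciprocal (the standard strong-edge = short-length
  convention; a −log mapping is available).  Shortest path lengths use
  Dijkstra; edge betweenness uses Brandes' algorithm with fractional
  credit over tied shortest paths, reported as unnormalized counts over
  unordered node pairs (group comparisons are invariant to the common
  normalization constant, and zero betweenness for many edges is
  expected and meaningful).  Per-edge profiles average direct weight,
  path length, and that edge's betweenness across subjects; a subject in
  whom the pair is disconnected contributes ∞ to the path length, the
  profile mean is then reported as ∞ with the finite-subject count, and
  group comparisons drop non-finite values with a logged notice (real
  tractography graphs are near-complete, so this is a corner case).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the level the pipeline consumes.  It does **not** simulate MEG time
series, leadfields, spatial leakage, wavelet spectra, or streamline-level
tractography, so passing tests demonstrate correctness of the *analysis*
under its own model assumptions — not robustness to beamformer leakage,
artifact structure, head-position differences, or other properties of
real recordings.

* **Geometry.**  Grid points on two hemispheric shells (default radius
  50 mm with 2 mm radial jitter; hemisphere encoded by the sign of x,
  anterior by +y).  Parcels partition each hemisphere by
  nearest-seed-centroid assignment, seeds drawn from the points.  The
  most anterior parcels (default 10% per hemisphere) are flagged
  excluded, mirroring the anterior exclusion of the analysis.  The
  default desk scale is 400 points and 10 parcels per hemisphere: with a
  55-parcel/hemisphere scheme at desk-scale point counts, parcel pairs
  cannot hold the ≥ 20 connections a bundle requires, so the parcel count
  is scaled down with the grid while remaining configurable.
* **Connectivity.**  For grid pairs between a planted parcel pair in a
  given band × window, subject s draws a latent contrast
  δ ~ N(μ_c, σ_b²) per connection; each session observes δ + ε with
  ε ~ N(0, σ_e²) i.i.d. across sessions, subjects, connections, bands,
  and windows.  Non-planted connections have μ = σ_b = 0 (noise only).
  The population ICC of the parcel-summed series is σ_b²/(σ_b² + σ_e²)
  because both variance components scale with the number of summed
  pairs.  Coherence is realized as a per-connection baseline
  b_c ~ U(0.2, 0.5) for the visual task and b_c + contrast for naming,
  clipped to [0, 1]; a warning fires if clipping touches > 1% of values
  (an ill-scaled design).  σ_e = 0 is accepted for noiseless-session
  tests.  An optional additive session offset exists solely to exercise
  the offset-insensitivity of ICC(3,1).  No generative model for
  inter-subject coherence baselines exists in the literature this
  targets; the uniform mid-range baseline is a pragmatic choice and only
  differences reach the analysis.
* **Behavior.**  Three scores drawn independently per subject (letter
  fluency ~ N(15, 4²), category fluency ~ N(22, 5²), RAN/RAS mean ~
  N(30, 6²)); independence matches the observation that the predictors
  are uncorrelated.  Behavioral coupling adds β · (equal-weight
  combination of the standardized scores) to the subject latent of a
  planted edge, expressed in summed-contrast units (per-pair share β/m),
  so the regression outcome gains exactly β per unit score combination.
  Coupling acts on the latent (both sessions), matching the use of the
  mean-over-sessions contrast as the regression outcome.
* **Structural connectomes.**  Over included parcels, baseline weights
  are log-normal (σ = 1) around a distance-decaying expectation
  300·exp(−d/40 mm), emulating the heavy tail and strong distance
  dependence of streamline counts; matrices are symmetric, zero-diagonal,
  nonnegative.  Parcel pairs planted as reliable (population ICC > 0.4)
  are multiplied by the design's structural boost.
* **Presets.**  `null_design` (no planted effects, one band/window,
  10 011 connections) serves the false-positive calibrations.
  `strong_effect_design` is the documented end-to-end preset: 19
  subjects, 400 grid points, 8 parcels/hemisphere, 2 bands × 3 windows,
  session noise SD 0.01, and twelve planted edges in two tiers — six
  reliable (σ_b = 0.03, population ICC 0.9, per-pair contrast 0.06,
  behaviorally coupled with β = 1, structurally boosted 5×) and six
  unreliable (σ_b = 0.003, population ICC ≈ 0.08, contrast 0.04,
  uncoupled, unboosted).  Planted pairs are restricted to included
  parcels with ≥ 12 grid points and inter-centroid distance ≥ 60 mm, so
  a planted pair geometrically supports the 20-member bundle minimum and
  cannot be removed wholesale by the 4 cm filter; tiers alternate through
  the pairs sorted by grid-pair count, because the parcel-summed strength
  scales with that count and the planted per-pair strength difference —
  not parcel size — should separate the tiers.  Directions alternate so
  both modulation signs occur.  Everything is deterministic given the
  design seed, with independent reproducible streams per generator stage.

## Numerical and design choices

* Paired t, chi-square, Mann-Whitney, and OLS go through scipy/statsmodels;
  the ICC decomposition, its CI, the bundle distance/clustering rule, the
  weighted edge betweenness, and the count reconstruction are implemented
  here and each is validated against an independent oracle (R-frozen ANOVA
  mean squares, parametric bootstrap, transitive closure, Floyd–Warshall,
  brute-force path enumeration, exhaustive Mann-Whitney enumeration).
* Shortest-path tie detection in the betweenness routine uses an absolute
  tolerance of 10⁻¹², appropriate for the O(1)-magnitude reciprocal
  lengths the pipeline produces.
* Count reconstruction from printed percentages does an exhaustive
  integer search constrained to match every percentage at its printed
  precision and errors on ambiguity rather than guessing.
* Problem sizes in the test suite and acceptance study (400-point grids,
  10⁴-connection calibrations, 10⁵-rep Monte-Carlo oracles, ≤ 8-node
  enumeration fixtures) are chosen so the entire suite runs on a laptop
  in well under a minute while keeping every binomial/Monte-Carlo band
  tight enough to detect implementation errors; they are desk-scale
  stand-ins for the full measurement scale (thousands of grid points per
  hemisphere), which the implementation also supports.

## Known limitations

* The generator plants independent Gaussian contrasts; real coherence
  contrasts are bounded, skewed, and spatially autocorrelated through
  leakage.  Calibration results (e.g. the 0.1% null selection rate)
  therefore certify the statistics under exchangeable Gaussian noise
  only.
* Bundle clustering is defined on a specific reading of the
  inter-connection distance; other readings (e.g. mean endpoint distance)
  would change bundle membership at the margins.
* Subcortical nodes can participate in structural graphs if supplied, but
  the synthetic generator emits cortical parcels only.
* The per-edge behavioral screen is intentionally uncorrected for
  multiplicity; its per-edge p-values must not be read as significance
  claims.
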