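# Methods

## Zonation model

The analysis domain is the manually annotated viable-tumor region: one
simple outer polygon, optionally with holes marking necrotic or otherwise
non-viable areas. Holes are treated as outside for both area bookkeeping
and distance: their edges are tumor boundary.

The boundary-relative coordinate is the **depth field**: for each raster
pixel inside the region, the Euclidean distance from its center to the
nearest outside pixel center (exact distance transform,
`scipy.ndimage.distance_transform_edt`, sampled at the pixel size). A lone
inside pixel therefore has depth equal to one pixel size, and the depth of
any pixel adjacent to the outside is at most pixel_size·√2.

"Annular zones" are iso-depth bands. Equal area is enforced by taking the
k/K quantiles (k = 1..K−1) of the inside-pixel depth distribution as
thresholds, so each zone holds the same number of pixels up to quantile
granularity — *not* by equal depth spacing, which would give unequal areas
for any shape other than a perfect annulus. For a disk of radius R this
construction reproduces the closed-form equal-area annuli, with thresholds
R(1 − √(1 − k/K)); for irregular simply-connected shapes it is the natural
rotation-free generalization. An alternative reading of "radially
symmetric" — rays from the centroid — is coherent for star-convex shapes
only and is not implemented; the depth-field construction is the package's
documented choice.

Zone 1 is the shallowest band (periphery) and zone K the deepest (core).
Interval edges are right-closed: a depth exactly at threshold k belongs to
zone k, deterministically. Degenerate inputs fail loudly: fewer than 10·K
inside pixels, or non-increasing thresholds (massively tied depths, e.g. a
one-pixel-wide region), raise errors that name the remedy (finer pixels).

**Pixel size.** Default 4 µm — about half a nucleus diameter, fine enough
that zone areas deviate from equal by well under 2% on masks of ≥ 10⁴
pixels, while keeping a 1 cm² section under 10⁷ pixels. Zone membership at
the region level (periphery/intermediate/core) is stable under halving the
pixel size to well under 1% of random points; per-zone membership near the
nine internal iso-depth contours is pixel-limited and cannot be held to
that bound by any raster method.

## BioD score

Cells are assigned to zones by direct pixel lookup of their coordinates
(cells outside the mask are tallied and warned about above 5% — usually a
coordinate-frame mismatch). Zones are binned into three contiguous
regions; for K = 10 the default scheme is 3/4/3 (periphery = zones 1–3,
intermediate = 4–7, core = 8–10), chosen as the symmetric split that
respects the boundary-inward ordering; it is configurable.

Region density is **pooled**: summed counts over the region's zones
divided by summed areas. Under exactly equal zone areas this equals the
mean of zone densities; under pixel-granularity jitter it is the more
robust estimator. The zone-density-mean variant is available
(`pooled=False`).

The score is the ratio triple (C:P, C:I, I:P); when all densities are
positive, C:P = (C:I)·(I:P) by construction. Classification uses the
core:periphery ratio as the primary axis: > 1 `core_enriched`, < 0.5
`excluded`, the closed band [0.5, 1.0] `homogeneous`. Band edges are
assigned to `homogeneous` as the deterministic tie rule. A zero
denominator is never regularized: an empty periphery makes the label
`undefined` (ratio +∞ sentinel); an empty intermediate region flags
ratio_CI/ratio_IP as undefined but still allows the core:periphery label —
a strictly periphery-confined pattern is `excluded`, which is the
phenotype the score exists to detect.

## Synthetic data

The generators define the study conditions the tests exercise; all are
pure functions of their seed (numpy PCG64 streams, seed recorded in
provenance output).

* **Boundaries**: star-convex radial Fourier perturbation
  r(θ) = r0(1 + Σ a_k cos(kθ + φ_k)), harmonics from k = 2, total
  amplitude clamped at 0.8 so radii stay positive. Default r0 = 2 mm,
  amplitude 0.15 — the scale and waviness of a subcutaneous tumor section.
* **Cell patterns**: pixels sampled with weight ∝ exp(β·u),
  u = depth/max-depth ∈ [0, 1], uniform jitter within the pixel. β = 0 is
  uniform; β = 3 lands deep in the core-enriched band (C:P ≈ 5.5); β = −5
  deep in the excluded band (≈ 0.07); β = −1 sits mid-homogeneous
  (≈ 0.57). β = 0 has expected C:P of exactly 1.0 — the *edge* of the
  homogeneous band — so it is used to test calibration (ratio within
  ±0.05), not label recovery. An optional zone subset confines the
  pattern (zones 1–3 emulate strict margin exclusion).
* **Growth**: V(t) = V₀·e^{rate·t}·ε with ln ε ~ N(0, σ), V₀ uniform in
  the 75–150 mm³ enrollment window. The lognormal-error exponential model
  makes the log-volume ANCOVA exactly correctly specified, so its null
  behavior is analytically checkable. Defaults: control rate 0.23/day
  (≈ 3-day doubling, typical of untreated syngeneic models), σ = 0.10,
  10 animals/group, twice-weekly measurements to day 21. Length and width
  are back-derived from V at fixed aspect ratio L/W = 1.3, so (L·W²)/2
  reproduces V exactly.
* **Frequencies**: per-animal frequency = logit⁻¹(N(μ_group, σ)), the
  standard logistic-normal model for proportions; default σ = 0.5 logits,
  n = 8/group, matching typical flow-cytometry group sizes.

What the generators do *not* emulate: cell-detection errors and staining
artifacts, spatial clustering beyond the radial trend (real infiltrates
are patchy), non-exponential growth phases (initial lag, terminal
plateau), inter-animal rate heterogeneity, and attrition before the
reference day. Passing tests therefore demonstrate correctness of the
*computations* under the stated models, not robustness to every real-data
pathology.

## Statistical layer

* **Volume**: V = L·W²/2 (mm³), L the longest caliper dimension; W > L is
  rejected as a data error.
* **TGI**: 100·(1 − V̄_t/V̄_c) at the latest day every animal is still on
  study (minimizes welfare-attrition bias). Arithmetic group means by
  default; the geometric variant is selectable. The exact published
  convention (ratio of means vs mean of ratios vs baseline-delta) varies
  across labs; both implemented variants are reported with their name.
* **ANCOVA**: OLS of log V_ref on a treatment indicator and log V_baseline
  (baseline = earliest measured day, configurable). One-sided p from the
  t statistic of the treatment coefficient, alternative "treated <
  control"; wrong-direction effects give p > 0.5. A constant baseline
  column is dropped with a warning (the model degrades to a t-test);
  degenerate zero-residual designs yield p = NaN rather than a fabricated
  number.
* **Interaction ANOVA**: two-way OLS on log V_ref without baseline
  adjustment (so intrinsic genotype growth differences stay in the
  model), one-sided on the interaction contrast: the alternative is
  stronger treatment inhibition in the wildtype genotype.
* **Events**: first measured day with V ≥ 1500 mm³; otherwise censored at
  the last measured day. No interpolation between measurement days —
  caliper data are interval-observed, and interpolating would fabricate
  precision. A series that crosses and regresses keeps the first crossing.
* **Kaplan–Meier**: lifelines' product-limit estimator, simultaneous
  handling of ties.
* **Log-rank**: signed deviate Z = (O−E)/√V over the treated group;
  asymptotic one-sided p = Φ(Z) (Z² is the classical chi-square
  statistic). For ≤ 10 subjects total the p-value is computed by
  exhaustive group-label permutation, P(Z_perm ≤ Z_obs), because the
  normal approximation is unreliable there; the cutover is automatic and
  overridable.
* **4PL**: c(t) = bottom + (top − bottom)/(1 + (t/inflection)^(−slope)),
  the Hill form with the inflection on the time axis; the "slope" compared
  across arms is the Hill coefficient. Multi-start least squares (slopes
  ±{0.5, 2, 5}, inflection at the median time); fits that collapse top
  onto bottom are flagged non-converged and excluded from slope
  comparisons. Slope comparison is a one-sided Welch t-test (default
  alternative: treated slopes smaller, i.e. delayed growth). At n = 2
  replicates per arm the attainable p is bounded by the tiny degrees of
  freedom; it is reported as computed.
* **Two-tier comparison**: Shapiro–Wilk per group at α = 0.05 → if either
  fails, natural-log transform (base irrelevant to both SW and the t-test
  decision) and re-test → t-test (Welch default) on the passing scale,
  else Mann–Whitney on the original values (exact enumeration when both
  n ≤ 8 without ties, normal approximation with tie correction
  otherwise). Non-positive values skip the log branch and go
  nonparametric, flagged in the trace. The per-group (rather than pooled)
  pre-test is the default, pooled is a flag. Simulated type-I error under
  a normal null at n = 8/group is within [0.04, 0.06].
* **Spearman**: average-rank ties; large-sample p by default, exact
  permutation p available for n ≤ 9.
* **Stars**: strict inequalities at 0.05/0.01/0.001; p = 0.05 is `ns`.
  No multiple-comparison correction anywhere, by design; outputs are
  labelled raw.

## Problem sizes in tests and the acceptance script

The test suite exercises the spatial layer on a 1 mm disk fixture at 4 µm
(≈ 2×10⁵ pixels) with patterns of 2×10⁴–10⁵ cells and 30-seed label
recovery loops; the calibration script uses the 2 mm disk (≈ 8×10⁵ inside
pixels) with 10⁵-cell patterns. Simulation-based calibration checks use
10⁴ replicates for type-I error and 10²–10³ replicates for power and
null-uniformity — sizes at which the binomial noise on the checked
proportions is comfortably below the asserted margins.

## Known limitations

* The zonation is 2D and per-section; serial-section registration and 3D
  zonation are out of scope.
* Raster zone boundaries are pixel-quantized; per-zone assignment within
  ~1 pixel of an iso-depth contour is resolution-dependent (region-level
  assignment is stable).
* The score is single-marker; co-localization of multiple markers is not
  computed.
* Group-level comparison of BioD scores across animals is delegated to
  the two-tier comparison on exported scores; the scorer itself is
  per-section.
* Very sparse patterns (tens of cells) give noisy ratios; no variance
  estimate on the ratio is provided — bootstrap over cells if needed.
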