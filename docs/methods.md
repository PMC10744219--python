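# Methods

## Measure definition

Inward displacement (InD) is defined per tracked endocardial point as the
component of its ED→ES displacement vector along the unit vector from the ED
point toward the LV centre of contraction, normalised by the ED
point-to-centre distance and expressed in percent. The sign convention is
inward positive, stationary 0 %, outward negative; 100 % corresponds to the
point reaching the centreline. The normalisation denominator is the **ED**
point-to-centre distance: the axis and all centres are fitted from the ED
contour only and held fixed for ES, so InD measures motion toward a target
defined in the end-diastolic frame and 100 % coincides with the
shrink-to-centreline limit. (A time-varying denominator would decouple 100 %
from that limit, which is why it was not chosen.)

## Geometry

* **Axis.** Base midpoint = midpoint of the two mitral-annulus insertions
  (first and last polyline points); apex = contour point farthest from it.
  Parameter-free and correct for convex cavity shapes; a strongly concave
  aneurysmal contour could mislocate the apex, which is a known limitation.
* **Centre of contraction.** Located on the axis at fraction
  `g(f) = f_base + f · (f_apex − f_base)` of the axis length, where `f` is
  the point's longitudinal fraction (axis projection, clamped to [0, 1]) and
  the defaults are `f_base = 1/2`, `f_apex = 2/3`. A three-level discrete
  mode (`discrete3`: 1/2, 7/12, 2/3 for the basal/mid/apical thirds) is
  provided because the basal-to-apical variation could equally be read as
  per-region; continuous interpolation is the default since the variation is
  described as sliding with position. Both are config options.
* **Point correspondence.** When contours are not externally tracked, both
  contours are resampled at `n = 200` points at equal fractions of their own
  arc length and paired by index. This is exact for similarity motions and,
  on phantoms, keeps segment-mean error below 1 percentage point at 200
  points/view (the resampled-mode phantom measures exactly this error).
  Externally tracked pairs are accepted via the `paired` input flag and used
  verbatim.

## Bullseye mapping

Each view's polyline is split at the apex into two walls; each wall's
annulus-to-apex arc is divided at fractions 1/3 and 2/3 into basal / mid /
apical levels, and the trailing 10 % of each wall's arc (`cap_fraction`)
feeds the apical cap, segment 17. Wall-arc fractions (rather than
axis-projection thirds) are used because they remain well behaved around the
curved apex. The default view/wall→segment binding (4CH septal→3/9/14,
anterolateral→6/12/16; 2CH inferior→4/10/15, anterior→1/7/13; 3CH
anteroseptal→2/8/13, inferolateral→5/11/16; cap 17 from all views) follows
common vendor triplane conventions; it is a documented convention, not a
published fact, and is fully overridable in YAML. Shared segments (13, 16,
17) are averaged unweighted across contributing views, mirroring the
unweighted per-segment point averaging; point-count weighting is available
(`shared_segment_weighting: points`). Coverage of all 17 segments is
asserted when a map is constructed.

## Global metrics

* **Volumes.** Triplane method of disks: each view's axis is divided into
  `n_disks = 250` equal-length slabs, cavity half-widths are measured
  perpendicular to the axis at each slab midline in every view, and each disk
  contributes `π r̄² Δ` with `r̄` the mean of all half-widths at that level
  and `Δ` the mean axis length divided by `n_disks`. Volumes use each
  phase's own fitted axis. A slab a view does not cross contributes zero
  half-widths (one per expected wall) and a warning fires above 5 % missing
  cells. On a semi-ellipsoid the scheme converges to the closed form
  (2/3)πr²L to well under 1 % at 250 disks; doubling the disk count moves the
  result by < 0.2 %.
* **EF.** `100 (EDV − ESV)/EDV`; ESV > EDV is permitted but warned about.
* **GLS.** Per view, endocardial arc-length strain
  `100 (ℓ_ES − ℓ_ED)/ℓ_ED`, averaged over views; negative for shortening.
  Exact (100 (k−1)) for a k-scaled contour pair. This is a stated
  convention of this package, not a bit-match to any vendor implementation.
* **BSA.** Du Bois (`0.007184 w^0.425 h^0.725`) by default, Mosteller via
  config; volumes indexed as vol/BSA.

## Normal ranges and classification

The packaged per-segment normal ranges (mean, SD in %) come from a published
120-subject healthy-adult CMR cohort; the regional rows are checked at load
against the arithmetic means of the segment rows (one-decimal rounding
tolerance 0.05). Z-scores flag |z| > 1.96 (the 95 % band). Wall-motion
classes use the published anchors (negative = dyskinetic, 0 % = akinetic)
plus two package conventions: an akinesis band of [0, 2 %) and a hypokinesis
threshold of z < −1.96; both configurable, since no published cut-offs exist
for them.

## Statistics

Pearson correlation via `scipy.stats.pearsonr` (two-sided t-based p);
Bland–Altman bias and limits of agreement `bias ± 1.96 · SD(diff)` with the
sample SD (ddof 1); adjusted linear regression via `statsmodels` OLS with
t-based 95 % CIs (normal-theory intervals throughout, matching common
clinical-statistics defaults). Cohort tables report, per age decile (and
optionally per sex), n, mean, SD, the 95 % CI of the mean
(mean ± 1.96 SD/√n) and the 95 % reference interval (mean ± 1.96 SD) — both
interval types are reported because normative tables are used both ways.

## Phantom

The synthetic subject is an axisymmetric half-ellipse cavity (ED equatorial
radius 22 mm, base-to-apex length 90 mm — mid-normal adult dimensions
consistent with an EDV near 90 mL per long-axis view) rendered identically in
all three views. Each ED point's ES position is the ED point moved fraction
`s` of the way toward its own centre of contraction, where `s` is the
contraction fraction of the point's AHA segment (default uniform 0.33, the
normal overall mean), blended linearly across segment boundaries over a 5 %
arc band so the ES contour is continuous. Optional annular descent adds
`d (1 − f)` mm of apex-directed motion; optional isotropic Gaussian noise
perturbs emitted ES points. All stochastic paths are seeded and the seed is
recorded in the output.

Ground truth is computed from the noise-free construction: per-point InD from
the applied motion, averaged per segment and fused across views exactly as
the pipeline fuses them; EF and GLS from a dense (1501-point) noise-free
construction with a 1000-disk stack. Consequences worth knowing:

* In paired mode with zero noise the pipeline must reproduce the truth to
  machine precision — this is the analytic oracle (uniform `s` gives every
  segment exactly `100 s`).
* Because of boundary smoothing, a segment whose `s` differs from its
  neighbours has a construction-truth mean slightly interpolated toward them
  (e.g. `s = 0.484` amid `0.30` yields ≈ 47.8 %, not 48.4 %); the pipeline
  recovers the construction truth exactly, and the truth is the honest
  target.
* Uniform contraction toward the sliding centre is an affine map
  (`x → (1−s)x`, `y → ((1−s) + s(f_apex − f_base)) y + const`), so the true
  volume ratio is `(1−s)²((1−s) + s/6)` — the closed form used to validate
  phantom EF.

What the phantom does **not** emulate: myocardial torsion, through-plane
motion, view foreshortening or misangulation, papillary/trabecular
irregularity, regionally varying wall curvature, or realistic image noise
statistics. Passing phantom tests therefore demonstrates geometric and
numerical correctness of the pipeline, not robustness to real acquisition
artefacts; the interobserver simulation (1 mm isotropic contour jitter)
emulates only the contour-correction component of observer variability.

## Problem sizes and numerics

Default analyses use 200 points/view and 250 disks, where phantom
discretisation error is ≲ 1 pp per segment and < 0.5 % in volume. The
statistics validation uses 1,000 OLS replicates at n = 120 (the cohort size)
and a 500-subject single-recovery check; the synthetic-cohort check draws 120
subjects from the packaged ranges and verifies cell means within
3 SD/√120 of the generating values — a per-cell 3σ bound, so across 17
segments a small share of seeds will exceed it by chance. Degenerate inputs
(coincident points, a point on the centreline, constant series, rank-
deficient designs, empty strata) raise informative errors rather than
producing silent zeros.

## Known limitations

ED/ES only (no full-cycle curves); no 16/18-segment variants; apex
identification assumes convexity; arc-length correspondence is a tracking
surrogate, biased for strongly non-similar regional motion (quantified by
resampled-mode phantoms); volumes and GLS are package conventions and should
not be compared across software without cross-calibration.
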