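# Methods

## The scores

`misalign` quantifies how coherently cells are oriented in a segmented
tissue section. Cell orientation is *axial*: a long axis has no head or
tail, so angles live on a 180°-periodic circle and every comparison uses
the smallest axial difference

    d(a, b) = min(|a − b| mod 180, 180 − |a − b| mod 180)  ∈ [0°, 90°].

**Global Orientation Angle (GOA).** Per cell, `d(θ, axis)` between the
cell's major-axis angle θ and the proximal–distal axis of its bone element,
in [0°, 90°]: 0 means parallel to the axis, 90 perpendicular. GOA is not an
alignment strength by itself; the *distribution* over a population carries
the signal (narrow = strongly aligned, broad = weakly aligned).

**Local Misalignment Score (LMS).** Per cell, the mean axial difference to
every neighbor whose centroid lies within a radius r (default 30 μm,
centroid-to-centroid, boundary inclusive), remapped by

    LMS = 45 − |45 − mean_diff|  (equivalently min(mean_diff, 90 − mean_diff)).

Because the axial difference of two independent uniformly random
orientations is Uniform[0°, 90°] with mean 45°, a neighborhood with
completely random orientations scores 45° in expectation — the theoretical
LMS maximum — while locally coherent neighborhoods score near 0. The remap
is applied to the *per-cell mean*, not per pair: that is the only order of
operations under which random neighborhoods average 45° *and* every value
lies in [0, 45] (a per-pair remap would give uniform values on [0, 45] with
mean 22.5). The unfolded mean (range [0, 90]) remains available as
`fold_mode="raw"` for sensitivity analyses; note that folding maps mean
differences above 45° back toward 0, which matters only for adversarially
bimodal neighborhoods (e.g. half parallel, half perpendicular).

LMS needs no tissue axis — any common reference gives identical scores —
and is exactly invariant to global rotation, reflection, and reference-axis
choice. Cells with fewer than `min_neighbors` (default 1) neighbors get an
*undefined* LMS (never 0 or 45) and are excluded from summaries, with
counts logged. When a class subset is selected (e.g. chondrocytes only),
the neighbor graph is rebuilt on that subset so other cell types never
contaminate the score.

### Finite-neighborhood bias of the folded mean

For k neighbors with uniform orientations, the per-cell mean difference has
standard deviation (90/√12)/√k ≈ 26°/√k, and folding gives

    E[LMS] = 45 − E|mean − 45| ≈ 45 − 20.75/√k  degrees.

So a field of ~12 neighbors per cell averages ≈ 39°, not 45°; the 45°
calibration is reached asymptotically. Wherever this package checks the 45°
law to ±1°, the neighborhood radius is sized from this bound so every cell
has k ≳ 480 (for 5,000 cells on a 2,000×2,000 μm jittered grid that means
r = 700 μm). This is a property of the estimator worth keeping in mind when
comparing absolute LMS levels across datasets with different cell
densities; *differences* between genotypes at matched density are
unaffected.

## Geometry

Orientation is the angle of the maximum Feret (caliper) diameter of the
cell polygon's convex hull — the longest chord — reduced mod 180. Ties
between equally long chords (a rectangle's two diagonals) are combined by
their axial mean, which recovers the intuitive long-side direction; a fully
symmetric tie (a square) falls back to the smallest qualifying angle and
the orientation is flagged unreliable. Cells whose caliper aspect ratio
(max/min Feret) is below 1.1 are likewise flagged low-anisotropy; flagged
cells are still scored but can be excluded in sensitivity analyses. An
ellipse-moment orientation (`orientation_from_moments`) is exposed for
cross-checking; the two agree within 1° on elongated convex shapes.

All coordinates are converted to micrometres at read time
(`PixelCalibration`), so radii, distance windows and areas are physical
quantities regardless of magnification. Self-intersecting polygons are
repaired by the zero-buffer convention; unrepairable ones are skipped with
a warning. Label-mask contours are smoothed with a short circular moving
average before the Feret computation, because the raw pixel staircase
perturbs the longest chord by several degrees; with ≥200 px² cells at
aspect ratio 3 the round-trip orientation error stays below 2°.

## Classification and zoning

Cells are classified by centroid membership in marker regions with fixed
precedence: Col2⁺∩ColX⁺ → chondro-hyper, else Col2⁺ → chondrocyte, else
Muscle⁺ → myocyte, else other. Centroid containment (boundary inclusive)
was chosen over partial-overlap rules for determinism. Chondrocytes whose
straight-line distance to the nearest hypertrophic-zone polygon falls in
the half-open window [0, 400) μm are relabeled chondro-PZ; chondro-hyper
cells are never relabeled, and the operation is idempotent. Distance is
measured to the HZ annotation polygon (0 inside it), matching an
annotation-based workflow, rather than to the nearest hypertrophic cell,
and as straight-line rather than along-axis distance. Optional filters drop
cells whose centroid lies within a margin of the cartilage boundary (edge
cells have truncated neighborhoods) and cells outside an area window;
every exclusion is counted by reason.

## Group comparison

The biological replicate is the embryo. Per-embryo score distributions are
compared with the first-order 1-D Wasserstein distance (scipy's
quantile-integral implementation), and two groups are contrasted by

    T = mean{ D(i,j) : embryos i, j in different groups }
      / mean{ D(i,j) : embryos i, j in the same group },

the within-group mean being Gini's mean difference over the pooled
same-group pairs (pooling and per-group averaging coincide for balanced
designs with equal spread). T ≈ 1 under exchangeability; T ≫ 1 when the
groups' distributions differ — in location or dispersion — more than
embryos within a group do, analogously to an F statistic but without
distributional assumptions.

Significance comes from permuting group labels over embryos; per-cell
permutation is deliberately not offered (pseudoreplication). When the
number of distinct assignments is ≤ B the null is enumerated exhaustively
and p = #{T_perm ≥ T_obs}/#assignments (observed included); otherwise B
seeded random relabelings with the add-one convention
p = (1 + #{≥})/(B + 1), so p > 0 always. Ties count as exceedances
(conservative). Two discreteness facts matter at small n: T is invariant
to swapping the two labels wholesale, so the observed assignment always
ties its complement and the smallest attainable p for a 4+4 design is
2/70 = 1/35; consequently the exact type-I rate at nominal α = 0.05 is
1/35 ≈ 0.029 — conservative, never anti-conservative.

For mixed-effects modeling (done downstream in standard software, not
here) the pipeline exports the median score per embryo × location, the
dependent-variable shape such models consume. Marker intensities (e.g.
SOX9) are reported relative to the mean of a designated reference
population, so the reference group maps to 1.

## Synthetic data

The generator emulates a growth-plate-like section: elliptical cells
(default 120 μm², aspect ratio 3 — flattened proliferative chondrocytes)
on a jittered grid (lattice + bounded jitter; spacing √(area/n) guarantees
the dense-neighborhood regime without pairwise rejection) or
uniform-random placement with bounded rejection at a minimum centroid
separation. Orientation models: constant; axial wrapped-normal(σ) built on
the doubled-angle circle (the standard axial treatment); or uniform.
Rectangular blocks can override the local regime to create spatially
graded severity. Each field emits matching annotations — the whole domain
cartilage/Col2⁺, a 150 μm ColX⁺ HZ strip at one edge — so classification
and zoning are exercisable end to end. Cohorts derive per-(embryo,
element) sub-seeds from the master seed by counter-based `SeedSequence`
splits, so any file regenerates identically in isolation.

What the generator does **not** emulate: real segmentation error, intensity
noise and marker bleed-through, curved bone geometry and non-rectangular
zones, cell-size gradients along the growth plate, and spatial correlation
of orientation noise. Passing tests therefore establish the correctness and
calibration of the *scoring machinery*, not the biological effect sizes
recoverable from any particular imaging dataset.

## Numerical choices and test scales

Angle arithmetic is in degrees end to end, with mod-180 reduction at input
boundaries. Neighbor search uses a kd-tree whose inclusive-boundary output
is test-verified against the brute-force all-pairs rule; LMS on ≤300-cell
instances matches a double-loop oracle to 1e-9°. "Exact" invariances are
asserted at 1e-9° (floating-point addition before the mod costs up to an
ulp). Equidistant nucleus-to-cell pairings break to the lowest cell id;
undefined scores are written as empty CSV fields, never 0. Heatmaps use
fixed color limits ([0,45] LMS, [0,90] GOA) so images are comparable across
samples.

Test problem sizes: calibration fields of 5,000 cells; range laws on 10⁶
vectorized neighborhoods; permutation calibration over 1,000 null cohorts
(2×4 embryos, 200 cells each, B = 999) plus 300 power replicates at a +15°
σ shift; noise-recovery sweeps of 20 seeds × 5 σ levels at 250 cells.

## Known limitations

LMS carries no directional (clockwise/counterclockwise) information and no
vector polarity — it cannot distinguish a coherent field rotated off-axis
from one aligned with it (that is GOA's job), nor detect polarity reversals
at matched axial orientation. Orientation is meaningless for near-round
cells (flagged, not removed). The Wasserstein-ratio test needs at least two
embryos in some group; with few embryos its p-values are coarsely discrete
(see above). The folded-mean bias makes absolute LMS levels density-
dependent at small neighborhood sizes.
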