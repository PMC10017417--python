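# Methods

This note documents the models and procedures implemented in `podskel`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmark does and does not establish. Units are millimetres
throughout; the gravity axis is +z.

## Problem setting

A mature oilseed-rape plant is a sparse 3D structure: a few woody stems
and branches (≈8 mm diameter) carrying tens to hundreds of siliques —
flat, elongate seed pods, typically ≈3 mm wide, ≈1.5 mm thick and
40–80 mm long, attached at 20–70° to their parent branch. The input is
a single-plant surface point cloud from a laser scan; the outputs are
the silique number (SN), the total silique length (SL) and the total
silique volume (SV), plus per-silique records and a labelled cloud.

## Preprocessing

Statistical outlier removal keeps a point when its mean distance to its
`k = 20` nearest neighbours is at most the cloud-wide mean of that
statistic plus `std_ratio = 2` standard deviations. Note two inherent
properties of this classic filter: boundary points of any finite
surface have slightly inflated statistics (a homogeneous cloud
therefore loses a small hull fraction), and the filter is only
approximately idempotent, because each pass re-tightens the threshold.

A pot approximates an inverted cone frustum. Starting at the lowest
point, each z-slab of thickness `delta_d = 10` is projected to the
ground plane and an algebraic (Kasa) least-squares circle is fitted.
Scanning stops at the first slab whose radius fails to exceed the
previous slab's by more than 2% — a plateau (cylinder) or a decrease
both stop the scan, so a plant without a pot yields pot height `h = 0`
and nothing is removed. With growth, the largest-radius slab defines
`r_max`/`O_max`, and `h` runs from the lowest point to that slab's
upper boundary, so removal covers the whole pot. Points with
`z ≤ z_min + h` inside their slab's circle (+2 mm radial margin, which
covers sensor noise plus the within-slab radius change of a sloped
wall) are removed. Stem points passing through the pot interior below
`z_min + h` are removed with it; this collateral loss is intentional
and small.

## Skeleton extraction

The skeleton is a contracted point set: candidates seeded as a random
subsample of the (voxel down-sampled) cloud move iteratively to local
L1-medians. One update is

```
x ← Σ_j p_j α_j / Σ_j α_j + τ·λ · Σ_i (x − x_i) β_i / Σ_i β_i
α_j = θ(‖x − p_j‖)/‖x − p_j‖        (attraction, source neighbours J)
β_i = θ(‖x − x_i‖)/‖x − x_i‖²       (repulsion, candidate neighbours I)
```

with Gaussian kernel `θ(d) = exp(−(d/bw)²)` and directionality
`λ = σ₁/(σ₁+σ₂+σ₃)` from the weighted covariance of J (1 on a line,
≈1/2 on a disk, ≈1/3 isotropic). A distance floor of 1e−8 guards the
denominators. Repulsion (balance `τ = 0.35`) spreads candidates evenly
along organ axes; with `τ = 0` all candidates in one neighbourhood
collapse to the same weighted median.

**Radius schedule.** `r₀` defaults to twice the mean nearest-neighbour
spacing of the working cloud. The working cloud is voxel-filtered at a
fixed 1 mm resolution so that `r₀` (and every radius derived from it)
is stable across acquisition densities. The radius grows by `0.5·r₀`
per level up to `r_cap_factor·r₀` (default 6, ≈14 mm). Per level, the
neighbourhoods and constraint planes are fixed and up to `inner_iters =
3` update steps converge the positions; this per-level convergence is
essential — a single step per radius level leaves candidates stuck on
the surface. The cap is an organ-scale parameter: contraction of a
round organ requires a radius of roughly twice its diameter, so the
default suits ≈8 mm stems, while a fixture of isolated 4 mm tubes does
better with `r_cap_factor ≈ 4`.

**Plane constraint.** Because a silique is flat, its local geometry is
a plane. For each candidate, RANSAC (24 three-point samples,
least-squares refinement on the consensus set, refitted every second
level and reused between) fits a plane to the neighbourhood truncated
at `r_flat_factor·r₀`; only points within `T_d = 1.5` of the plane are
used. Three safeguards make this robust:

* *anchoring* — only planes passing within `T_d` of the candidate
  compete, and consensus is weighted by proximity to the candidate, so
  a parallel neighbouring organ cannot outvote the local surface;
* *the gap gate* — the constraint only applies when the band
  `[T_d, 2·T_d)` from the plane is nearly empty (<10% of the
  neighbourhood). The constraint is meant to sever an empty gap between
  organs; a populated band means the plane cuts a continuous curved
  surface (a stem), where constraining would pin candidates to a
  tangent plane forever;
* *in-plane severing* — when a plane slices two parallel organs at
  once, the constrained set splits into runs along its second principal
  axis separated by an empty gap; only the candidate's own run is kept.

Constrained (flat) neighbourhoods use the narrow kernel bandwidth
(`0.5·r`, prevents clumping along the pod), curved ones the wide
bandwidth (`1.5·r`, lets a thick stem's far side attract).

The per-candidate update and weighted covariance are JIT-compiled with
numba over CSR neighbour lists; a pure-numpy reference implementation
remains and is used automatically when numba is unavailable.

## Connection

DBSCAN (`eps` = 3× the skeleton's median point spacing, `min_pts = 3`)
groups skeleton points roughly; noise points are set aside. Within a
class, polylines grow greedily from both ends toward the nearest
unvisited point whose direction has positive cosine with the end
tangent (backward edges are inadmissible — the direction correction
that prevents hairpin shortcuts). `connect_class` returns a single
path visiting every class point. The pipeline instead grows *strands*:
growth stops when no admissible point lies within `max_edge_factor`
(default 4) × the median spacing, and a new strand is seeded from the
remaining points. A plant-scale DBSCAN class is never a single curve,
and forcing one Hamiltonian path through it produces zigzag that the
split rule then shreds. Strands of fewer than 3 points are dropped as
connection debris. Each strand receives two passes of end-preserving
Laplacian smoothing: residual perpendicular contraction jitter
otherwise corrupts interior angles and inflates polyline lengths.

## Optimization

Two repair rules run in sequence, split first:

* **split** at every interior point whose angle is ≤ 165°; the pipeline
  measures the angle between chords over ±2 points (`angle_window`),
  which resists jitter while leaving genuine corners sharp;
* **merge** two sub-skeletons when their nearest end pair is closer
  than `5 × d̄_sk` (mean connected-point distance, computed once after
  splitting) and both outward end tangents (chords over 3 end edges)
  make < 15° with the connecting line. Merging is greedy
  smallest-gap-first over an endpoint KD-tree, and a merge whose
  junction the split rule would immediately re-cut is refused — this
  keeps the output consistent with both rules at once and makes the
  operation idempotent.

The multiset of skeleton points is conserved exactly.

## Trait extraction

Sub-skeletons longer than 200 mm are branches. The remaining candidates
pass through four stages:

1. **end completion** — contraction truncates a silique skeleton where
   its parent branch interferes (≈10 mm at the base) and slightly at
   the tip. Each candidate polyline is extended along its outward end
   tangents for as long as the cloud supplies surface points inside a
   2.5 mm tube, in contiguous 2 mm bins (up to 20 mm per end); the walk
   stops naturally at the branch surface or at free space. Without
   this, total SL is biased ≈25% low.
2. **duplicate absorption** — a candidate lying mostly (≥50% of its
   points) within 3 mm of a longer candidate's polyline is a second
   fragment of the same silique; it is absorbed, the keeper extended
   over its arc overhang, so each silique is counted once.
3. **width check** — the source points assigned to each candidate
   (nearest sub-skeleton within 3 mm, and within `T_d` of the local
   least-squares plane; assignments are disjoint) are projected slab by
   slab; a candidate whose median cross-section extent exceeds 4 mm is
   a piece of stem or branch surface and is reclassified as branch
   debris *before* the length statistics.
4. **the effective-silique filter** — with candidate lengths sorted, μ
   is the mean of ranks `int(0.2·m)..int(0.8·m)` (half-open; the middle
   60%, robust against leftover stem fragments), σ is the sample SD
   (ddof = 1) of all candidates, and candidates within
   `[max(15, μ − 1.96σ), μ + 1.96σ]` are effective. The printed source
   gives the same expression for both interval bounds, an evident typo;
   the upper bound is `μ + 1.96σ`. The interval is a population band,
   not a standard-error band — a standard-error band would reject
   nearly every pod.

Per-silique volume accumulates `V_A = L·W·(d₁+d₂)/2` over skeleton
points, where `L ≥ W` are robust (1st–99th percentile) principal-axis
extents of the assigned points in the slab `[A − d₁/2, A + d₂/2]`
(arc-length coordinates along the polyline, so curvature is handled);
end points use their single neighbour distance on the existing side
only, and slabs with fewer than 3 points contribute 0.

## Synthetic plants

The generator emulates the three mature-plant architectures — FBBS
(few-branch broom: 1 main stem, ~4 second-order branches), MBBS
(multibranch broom: 1/6/4) and MBCS (multibranch cylinder: 4/14/6,
stems splayed from the base) — with curved-tube stems (radius 4 mm,
height ≈500 mm; second/third orders at 0.6×/0.4× radius) and siliques
as straight box-section pods (3 × 1.5 mm section, lengths N(60, 8²) mm,
pedicel angle U(20°, 70°), stratified along the upper half of each
branch). Defaults: 80 siliques per plant, surface density 1.2 pts/mm²,
Gaussian sensor noise SD 0.05 mm, and a 120° angular sector dropped per
organ (a handheld scan covers ≈240° horizontally). A pot frustum
(r 40→60 mm, height 100 mm) is optional and off by default. All
randomness derives from one seed; clouds are byte-identical per seed.

The box cross-section is a deliberate modelling choice: the volume
estimator assumes a rectangular projected distribution, and a box makes
the generator's analytic truth (area × length) exact, so the volume
test has a closed-form anchor. Real pods are lens-shaped; on real data
the rectangle model overestimates the enclosed volume by up to ≈4/π and
SV should be read as a rectangular-hull volume. The generator also
omits leaves (mature plants are defoliated), petioles/pedicel stalks,
soil in the pot, and multi-plant interference; passing tests therefore
demonstrate the geometric machinery, not robustness to those factors.

## Benchmark scale and expectations

The synthetic benchmark runs 10 plants per architecture at generator
defaults (≈55–120k points per plant; roughly 10–20 s per plant on one
CPU). Under these conditions the pipeline reaches a mean silique-count
recall around 0.95–1.05 (over-segmentation can push individual plants
above 1), pooled total-SL within about ±10% and pooled total-SV within
about ±15% of truth; recall degrades monotonically as extra sensor
noise is added. The residual SL bias is negative (base truncation not
fully recovered); the residual SV bias is positive (rectangular hulls
and stray near-branch points).

## Numerical choices and degenerate inputs

* Strict inequalities follow the stated rules: branch cutoff (`> 200`),
  plane constraint (`< T_d`), merge (`< 15°`, `< 5·d̄_sk`); the split
  keeps a vertex interior only if its angle is `> 165°`; the effective
  interval is closed.
* Ties break deterministically: equal distances go to the lowest point
  index, equidistant source points to the lower sub-skeleton id.
* Collinear inputs raise degenerate-geometry errors in circle and plane
  fits; empty clouds raise insufficient-data errors; a cloud with no
  silique candidates yields zero traits rather than an error.
* Determinism: every stochastic step (candidate seeding, RANSAC
  samples, generator geometry) is driven by explicit integer seeds;
  pipelines re-run bit-identically. Skeleton extraction is equivariant
  under rigid rotation when the (grid-aligned) voxel filter is
  disabled.

## Known limitations

* Siliques attached nearly parallel to their branch can merge with the
  branch skeleton and be lost or truncated.
* Two pods touching tip-to-tip at a shallow angle can survive both
  repair rules as one candidate; the length filter then rejects the
  double-length candidate and both pods are lost.
* The branch/silique cutoff is a hard length threshold; branch
  fragments in the silique length range are suppressed only by the
  width check.
* The count recall `SN_E/SN` is not capped at 1; over-segmentation on
  dense canopies can raise it above 1 while the totals stay accurate.
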