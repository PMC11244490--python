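# Methods

This note documents the models, parameter choices and numerical decisions
behind `bamboostand`, and what the synthetic validation does and does not
show about real scans.

## Synthetic stands

The simulator is the package's source of labelled validation data.  It
emulates a square sample plot (default 10 m × 10 m; presets A1/A2/A3 carry
37/45/52 plants, i.e. 3700–5200 culms·hm⁻²) on hilly terrain and renders it
through two scanner models.

**Terrain.** An inclined plane (default slope 10°, typical of the hilly
bamboo country the workflow targets) plus smooth sinusoidal bumps of 0.05 m
amplitude.  The surface is analytic, so the terrain under any point is known
exactly for oracle checks.

**Plants.** Culm bases are placed by rejection sampling with a minimum
spacing (default 1.0 m).  DBH is truncated-normal (mean 0.10 m, sd 0.015 m,
floor 0.04 m).  Height follows the allometry `H = a·DBH^b · ε` with
`a = 45`, `b = 0.55` and lognormal scatter `σ = 0.05`, giving 11–15 m plants
for 7–13 cm culms — typical moso dimensions.  Culms are tapered cylinders:
constant radius DBH/2 below breast height (1.3 m), linear to zero at the
apex, so the measurement slice sits on a near-constant-radius section.
Culms arch: the axis leans up to 3.5° in a random direction, displacing the
apex up to ~0.8 m from the base.  This matters for evaluation realism:
location-based matching of crown apexes against surveyed stem positions is
exactly where airborne-only height errors arise, because a displaced apex
can match a neighbouring plant.

**Crowns.** A pointed-dome shell `r(w) = R_c (1 − w)^{0.75}` (apex at
`w = 1`) occupying the top 35 % of the plant, its apex coinciding with the
culm apex.  Shell directions are sampled with the matching area weight, so
foliage density vanishes toward the thin leader — a blunt, densely sampled
cap would make airborne apex estimates centimetre-perfect, which real
scanners of arching bamboo crowns are not.  35 % of crown returns come from
interior foliage, which keeps every crown path-connected to its own culm.
Crowns exhibit shyness: each plant's crown radius shrinks so neighbouring
crowns keep a ≥ 0.25 m air gap (cap 0.9 m, floor 0.3 m).  Inter-crown gaps
are the premise both segmentation methods rely on.

**Scanners.** Point retention is a logistic in normalized height
`h/H`, oriented oppositely for the two modes:

| parameter | ALS | TLS |
|---|---|---|
| density (pts·m⁻²) | 600 | 6000 |
| coordinate noise sd (m) | 0.02 | 0.005 |
| ground-return fraction | 0.22 | 0.12 |
| retention profile | rises with height (floor 0.02) | falls with height |
| crown-top hard cutoff | none | per plant, U(0.85 H, 1.0 H) |
| culm azimuth occlusion | none | 120° sector per plant |
| ground shadowing | none | returns removed ≤ 0.6 m from culm bases |

The TLS cloud is emitted in a local frame (the inverse image of the
projected frame under a known 7-parameter transform) with the four corner
targets' projected coordinates perturbed by GNSS-like noise (sd 0.05 m) —
fixed RTK solutions are rarely available under a dense canopy.

**What the simulator does not model:** multi-station TLS acquisition and
co-registration (a single merged TLS cloud is emitted), radiometry,
multi-return waveforms, understory vegetation, wind movement, and field
reference error (the truth is exact, so absolute accuracy numbers are
optimistic relative to field studies; cross-source *orderings* are the
meaningful comparison).

## Registration

The Helmert estimate solves the linearized model (exact up to `m·θ`
cross-terms) in one least-squares solve, then polishes with Gauss–Newton on
the exact small-angle form; noise-free control pairs are recovered to
~1e-14.  Degenerate (collinear) control geometry is detected by rank.

ICP is point-to-point: nearest-neighbour correspondences, closed-form SVD
update, iterating until the RMS correspondence distance improves by less
than 1e-6 m (max 50 iterations).  Correspondence rejection is adaptive: the
radius starts at 1.0 m and shrinks toward 3× the current RMS (floor
0.05 m).  Without this, TLS culm points — which have no airborne
counterpart — dominate the correspondence set and stall the fit.  Scale is
not re-estimated in ICP; it is fixed by the Helmert step, so a scale error
from noisy controls (±4·10⁻³ at 0.05 m control noise on a 10 m plot) is the
accuracy floor of the fine alignment.  Both clouds are voxel-subsampled to
0.05 m for ICP; the final transform is applied at full resolution.

## Terrain

Classical progressive TIN densification: per-cell minima on a 2 m seed grid,
then iterative acceptance of points with vertical facet distance ≤ 0.3 m
and point-to-vertex angles ≤ 8° to the facet plane.  Two implementation
details matter in dense terrestrial clouds: (i) facets steeper than 45° are
not treated as terrain — otherwise near-vertical sliver facets formed by
noisy, horizontally near-coincident culm returns let the TIN climb the
culms; (ii) points outside the TIN hull are accepted only if vertically
within the distance threshold of the nearest classified ground point.
The DEM is the per-cell mean of ground elevations at 0.5 m, voids filled
from the nearest filled cell; height normalization subtracts the containing
cell's value (nearest-cell, no interpolation), so it is exactly invertible
given the DEM.

## Segmentation

**PCS** (airborne): points at ≥ 1 m height are processed in descending
height; each point joins the segment of its horizontally nearest
already-assigned point unless that distance exceeds *d*, in which case it
seeds a new plant.  *d* defaults to the plot's average spacing
`sqrt(area/n)`; the processing order is quantized in 0.2 m slabs.  Segments
under 50 points are discarded.  On interlocked canopies PCS under-segments
by design intent — that is the documented weakness of airborne-only data.

**CSP** (terrestrial/merged): DBSCAN on the horizontal coordinates of the
0.5–2.0 m band (minPts 500, radius 0.2 m) finds culms; remaining points are
assigned by multi-source Dijkstra over a 10-NN graph on a 0.05 m
voxel-subsampled cloud.  Edges longer than 0.15 m are pruned so the air gap
between shy crowns actually disconnects them — without pruning, a shortest
path happily hops a 0.25 m gap and overhanging foliage of a taller
neighbour is claimed by the plant below it.  Unreachable points fall back
to the horizontally nearest culm.  The second pass re-detects culms within
each first-pass segment at half the radius (0.1 m) and splits segments
containing ≥ 2 culms; re-running the identical clustering could never split
anything, so the finer radius is what gives the second pass its purpose.
Ties everywhere go to the lowest culm/segment id; node order is fixed by
sorted voxel keys, making the assignment independent of input point order.

## Traits

The breast-height slice is the segment's points with normalized height in
[1.2, 1.4) m; fewer than 10 points flags the plant as "DBH not estimable"
(the usual fate of airborne-only culms).  The cylinder fit minimizes the
sum of squared point-to-surface distances over five parameters: axis
direction `(ax, ay, 1)/‖·‖` (non-degenerate for near-vertical culms), two
axis offsets in the plane normal to the axis, and the radius; it is
initialized from the centroid, a vertical axis and an algebraic (Kasa)
circle fit of the horizontal projection.  One trimming pass drops residuals
beyond 3×MAD and refits, tolerating scattered leaf/twig returns near the
stem.  The fitted radius is Rician-debiased by `s²/(2r)` (s = residual
RMS): noisy surface points lie at mean distance `r + σ²/2r` from the axis,
so the raw geometric fit overestimates; noise-free fits are unaffected.
Exact-surface recovery is at 1e-6 m for radii 0.03–0.08 m and any axis
within 30° of vertical; with 3 mm noise the DBH RMSE over 50 replicates is
≤ 0.5 mm.

## Evaluation

Greedy globally-nearest-first one-to-one matching within a distance
threshold (default: the average spacing `sqrt(area/n)`), which is
deterministic and order-independent; `Nt + No = n` references and
`Nt + Nc =` detections hold by construction.  R² is the squared Pearson
correlation of estimated vs measured values (the "linear regression"
reading); RMSE is about the 1:1 line.  Percentages and F are reported at
2 d.p.

## Known limitations

* The fine-alignment RMS (~0.08 m on synthetic plots) is dominated by the
  Helmert scale error from four noisy corner targets; rigid ICP cannot
  correct scale.
* Merged-vs-terrestrial DBH is a near-tie by construction: the merged
  slice is a superset of the terrestrial slice, airborne data contribute
  ~0.2 culm points per plant there, and the remaining geometry is shared.
  The merged advantage observed in field studies rests on multi-station
  culm completeness, which the single-cloud simulator does not represent.
* Synthetic accuracy numbers are optimistic in absolute terms (no field
  reference error, no wind, no understory); cross-source orderings — not
  absolute RMSEs — are the validated claims.
* The workflow assumes plot-scale extents (tens of metres); the ground
  filter and the CSP graph are built in memory.
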