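# bamboostand

Individual-plant inventory of moso bamboo (*Phyllostachys edulis*) from
fused airborne (ALS) and terrestrial (TLS) LiDAR point clouds.

Airborne and terrestrial scans of the same bamboo plot are complementary:
the drone sees the canopy but almost nothing of the culms (stems); the
ground scanner sees the culms in detail but loses the crown tops.  This
package implements the full fusion workflow at sample-plot scale —
registration, terrain normalization, individual-plant segmentation and
trait extraction — together with a labelled synthetic-stand simulator so
that every stage can be validated against known ground truth.

**Who it is for:** forest-inventory and plant-phenotyping researchers who
work with plot-scale LiDAR and want a tested, scriptable reference
implementation of the culm-level measurement chain.

## The method

1. **Coarse registration.** The TLS cloud lives in a local scanner frame.
   A 7-parameter similarity (Helmert) transform

   `X = T + (1 + m) · R(θx, θy, θz) · X₀`,

   with `R` in the small-angle form, is estimated by least squares from the
   four surveyed plot-corner targets and applied to the whole TLS cloud.
2. **Fine registration.** Point-to-point ICP (nearest-neighbour
   correspondences with adaptive rejection, closed-form SVD updates)
   minimizes `f(R,T) = (1/n) Σᵢ ‖R·Pᵢ + T − Pᵢ′‖²` and refines the TLS
   cloud onto the ALS cloud; the two are then merged with per-point source
   tags.
3. **Normalization.** Ground points are classified by progressive TIN
   densification, gridded into a 0.5 m DEM, and all heights become
   height-above-ground.
4. **Segmentation.** Airborne-only clouds use PCS — top-down region growing
   seeded at the highest unassigned point with a horizontal spacing
   threshold *d*.  Terrestrial and merged clouds use CSP — culms are
   detected by DBSCAN (minPts 500, radius 0.2 m) in a low slice band, and
   every point joins the culm with the shortest graph path; a second pass
   re-detects culms inside each segment and splits under-segmentations.
5. **Traits.** Height is the maximum normalized height per segment.  DBH
   comes from a least-squares cylinder fit of the 1.2–1.4 m culm slice:
   the distance of point *p* to the cylinder (axis *a*, axis point *c*,
   reciprocal radius *k*) is `d(p) = ‖(p−c) − ((p−c)·a)a‖ − 1/k`, and
   `DBH = 2/k`.
6. **Evaluation.** Detections are matched one-to-one to the reference
   inventory within the plot's average spacing; recall `r = Nt/(Nt+No)`,
   precision `p = Nt/(Nt+Nc)` and `F = 2rp/(r+p)` summarize detection, and
   RMSE / R² summarize trait accuracy over the correctly segmented plants.

The simulator (`bamboostand.synthetic`) generates 10 m × 10 m stands
(presets A1/A2/A3 with 37/45/52 plants) on hilly terrain, with tapered
arching culms, pointed-dome crowns, and the characteristic sampling biases
of each scanner; every rendered point carries its ground-truth plant label.

## Worked example

```python
from bamboostand.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig.preset("A1", seed=1))
a = report["alignment"]
print(f"fine alignment RMS: {a['icp_final_rms_m']:.3f} m ({a['icp_iterations']} ICP iterations)")
for row in report["rows"]:
    print(f"{row['source']:>6}: recall {row['r_pct']:.2f}%  precision {row['p_pct']:.2f}%  "
          f"F {row['f']:.2f}  height RMSE {row.get('height_rmse_m', float('nan')):.2f} m  "
          + (f"DBH RMSE {row['dbh_rmse_m']*1000:.1f} mm" if "dbh_rmse_m" in row else "DBH n/a"))
```

prints

```
fine alignment RMS: 0.076 m (16 ICP iterations)
   als: recall 32.43%  precision 100.00%  F 0.49  height RMSE 0.06 m  DBH n/a
   tls: recall 100.00%  precision 100.00%  F 1.00  height RMSE 1.07 m  DBH RMSE 1.3 mm
merged: recall 100.00%  precision 100.00%  F 1.00  height RMSE 0.09 m  DBH RMSE 1.2 mm
```

Reading this: on a simulated 37-plant plot, top-down region growing on the
airborne cloud alone under-segments the interlocked canopy (recall 32%),
while culm-based segmentation of the terrestrial and merged clouds finds
every plant.  Terrestrial-only heights are ~1 m short because the scanner
cannot see the crown tops; the merged cloud restores them.  DBH is
millimetre-accurate wherever the culm slice is densely sampled (the
airborne cloud alone has too few culm returns to attempt it).

A command-line interface mirrors the library
(`bamboostand simulate/convert/validate/align/normalize/segment/traits/evaluate/run`);
run `bamboostand --help` for the subcommands.

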