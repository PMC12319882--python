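# safsheet

Post-processing and validation tooling for **short association fibres (SAF)**
— the U/V-shaped white-matter connections lying directly beneath the cortex —
at the interface of the primary (V1) and secondary (V2) visual areas.

SAF at the V1–V2 border are expected to form a *topographic sheet*: a thin
layer of parallel fibres hugging the grey/white boundary, whose terminations
inherit the retinotopic order of the overlying cortex (eccentricity along the
gyrus, polar angle across it). `safsheet` turns that claim into computable,
testable quantities. Given a tractogram, white/pial surfaces, V1/V2 labels
and phase-encoded retinotopic maps, it:

1. **Conditions the functional maps** — per-vertex SNR at the stimulus
   frequency (|spectrum at the stimulus bin| / sd of the non-DC magnitude
   spectrum), reliability masking at SNR ≥ 5, and 4 iterations of 1-ring
   neighbourhood-mean smoothing on the mesh (circular means for polar angle);
   V1/V2 voxel-label overlaps are resolved by a V1 probability map.
2. **Selects the SAF** — streamlines traversing both V1 and V2, lengths
   restricted to 3–120 mm (in vivo preset) or 3–30 mm (post mortem), removal
   of streamlines diving > 2 mm below the white surface and of streamlines
   with > 80 % intracortical arc length.
3. **Measures per-streamline geometry** — arc length and the **bending
   angle**: the angle subtended at the streamline's apex (point of highest
   discrete curvature after uniform arc-length resampling) by the two
   vectors joining the apex to the endpoints. Smaller angles = more U-shaped,
   larger = more V-shaped; a straight line scores 180°.
4. **Characterises the sheet** — "sizes" are the variances (mm²) of the
   pooled streamline coordinates along three orthonormal axes (principal
   axes by default), a quadratic 2D height surface is fitted over the two
   largest axes, and size ratios classify the population as *sheet*
   (two wide axes, one thin) vs *bundle* (one long axis, tight cross-section).
5. **Projects retinotopy and quantifies topography** — each endpoint is
   anchored to the three vertices of its closest surface triangle, the mean
   of their eccentricity/polar-angle values gives four retinotopy values per
   streamline, the V1-end values are carried along the whole streamline,
   streamlines are clustered into 6 eccentricity / 15 polar-angle bands
   drawn below the V1 border, and a Spearman **topographic order index**
   in [−1, 1] scores how well the carried values follow position.

Because real study data of this kind are not publicly deposited, the package
ships a first-class **phantom generator**: a single folded gyrus (two
cortical banks joined by a circular crown) extruded along the
anterior–posterior axis, with sub-cortical fibres that follow the fold at a
fixed depth. Every generated fibre has an *analytically* known arc length
and apex angle, every vertex a known retinotopic value and fMRI phase, so
each pipeline stage can be tested against exact ground truth.

## Worked example

```python
from safsheet import AnalysisParams, run_pipeline
from safsheet.synthetic_data import SceneConfig, make_scene

scene = make_scene(SceneConfig(seed=1))          # 200-fibre folded-gyrus phantom
result = run_pipeline(
    scene.tractogram, scene.white, scene.pial,
    scene.eccentricity, scene.polar_angle, scene.v1, scene.v2,
    AnalysisParams(), timeseries=scene.timeseries,
)
m, s = result.summary["bending_angle_deg"]
print(f"{result.summary['n_selected']} SAF;"
      f" bending angle {m:.1f} +/- {s:.1f} deg;"
      f" sizes {[round(x, 2) for x in result.summary['sheet_sizes_mm2']]} mm^2;"
      f" {result.summary['sheet_classification']};"
      f" ecc order {result.summary['order_index_eccentricity']:.4f}")
```

prints

```
200 SAF; bending angle 140.2 +/- 0.3 deg; sizes [16.44, 11.57, 0.44] mm^2; sheet; ecc order 0.9996
```

meaning: all 200 planted fibres survive selection; the measured bending
angle recovers the phantom's configured 140° apex; the pooled-coordinate
variances are widest along the sheet extent (A–P) and fibre length and two
orders of magnitude smaller across the sheet thickness, so the population
classifies as a sheet; and the projected eccentricities are almost perfectly
rank-ordered along the gyrus (order index ≈ 1).

The same stages are available from the shell:

```bash
safsheet simulate --seed 7 --out scene/        # phantom as TCK + OFF + TSV
safsheet metrics scene/fibres.tck --out metrics.tsv
safsheet sheet scene/fibres.tck --out sheet.json
safsheet run --seed 7 --out report/            # full pipeline + reports
```

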