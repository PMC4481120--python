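# landmarkerr

Landmark precision and linear-distance reliability for replicated 3D
morphometric data.

When the same anatomical landmarks are digitized repeatedly on the same
specimens with more than one instrument — a 3D digitizer arm on real
skulls, micro-CT image stacks at different resolutions or scanning
filters — two questions decide whether the data are usable for
morphometrics: **how precisely does each method place each landmark**,
and **how reliable and mutually consistent are the linear distances
extracted from them**. `landmarkerr` implements the full analysis for a
replicated individual × method × replicate study design, together with
a synthetic-data generator with known ground truth so every stage can
be validated end to end.

## What it computes

**Leave-one-landmark-out precision.** Configurations are superimposed
by Generalized Procrustes Analysis (centring, scaling to unit centroid
size CS(X) = √Σᵢ‖xᵢ − x̄‖², least-squares proper rotations onto an
iterated mean shape). A plain GPA, however, spreads a variable
landmark's variation across the others; so each landmark k is excluded
from the superimposition, every configuration's fitted similarity
transform is applied to the held-out landmark, and the landmark's
deviation is its distance from the mean of the transformed held-out
points. Reported per landmark in shape-space units and in mm (× mean
centroid size).

**Distance repeatability.** For every inter-landmark distance
(bilateral pairs averaged), a one-way ANOVA with individuals as groups
gives the repeatability

r = s²_A / (s² + s²_A),  s² = MS_within,  s²_A = (MS_among − MS_within)/k₀,

within a single method (k = 2 replicates) and for two methods joined
(k = 4), where any systematic between-method disagreement inflates the
residual and depresses r.

**Difference reports.** Mean raw (signed), absolute, and percentage
(100 × mean |Δ| / distance mean) differences between replicates and
between methods, plus the Pearson correlation of per-distance
repeatability against mean distance length (the proportional error of
a fixed mm-scale disagreement is larger for shorter distances).

**Quality control.** Replicate pairs differing by more than 0.5 mm
(0.3 mm for distances with method-wise mean < 3.0 mm) are flagged as
gross errors for manual re-measurement.

The bundled protocol is a 20-landmark toad-skull scheme (5 midline, 15
bilateral → 35 points) with 24 named inter-landmark distances; CT
coordinates in voxel units are converted to mm with the scan's
mm-per-pixel factor (0.01742 at medium, 0.00871 at high resolution).

## Worked example

```python
import landmarkerr as le

# a replicated study: 20 individuals x 3 methods x 2 replicates
params = le.SimulationParams(seed=1)
dataset, truth = le.simulate_dataset(params)
dataset = le.convert_units(dataset, "MED", 0.01742)
dataset = le.convert_units(dataset, "HIGH", 0.00871)

res = le.LandmarkPrecision(dataset, "DIG").fit()
print(res.summary())            # per-landmark precision, mm

table = le.distance_table(dataset)
rep = le.DistanceRepeatability(table, ("MED", "DIG")).fit()
print(f"mean r = {rep.mean_r:.3f} +- {rep.sd_r:.3f}")
```

prints (abridged):

```
Leave-one-landmark-out precision — method DIG
  configurations: 40   landmarks: 20 (midline_and_left)
  mean centroid size: 32.700 mm
  deviation range: 0.385 to 0.497 mm
...
mean r = 0.714 +- 0.164
```

The deviation range says DIG places landmarks within roughly 0.4–0.5 mm
of the sample mean shape. The joined MED + DIG repeatability (0.71)
falls between its members' within-method values (DIG 0.61, MED 0.86 on
this synthetic draw): with no systematic bias between the methods the
joined value is set by the noisier member. A real method bias pushes it
*below* both within-method values — the degradation signature the
acceptance script measures.

The same pipeline runs from the shell:

```sh
landmarkerr simulate --seed 1 --n-individuals 20 --out study.csv
landmarkerr qc study.csv
landmarkerr full --input study.csv --out reports/
```

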