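# mnvquant

Quantitative vascular morphometry of macular neovascularization (MNV)
from en-face OCT angiography, with a robust weighted-regression
analysis of long-term anti-VEGF treatment demand.

In neovascular age-related macular degeneration (nAMD), the number of
intravitreal anti-VEGF injections (IVIs) a patient will need varies
widely and is hard to predict at diagnosis. OCTA renders the new
vessel network of the MNV directly, so its geometry can be measured at
baseline. This package implements the full measurement-and-analysis
chain for the four standard en-face parameters and relates them to the
3-year injection count and visual-acuity change:

- **area** (mm²) — two-dimensional extent of the membrane,
  `area = |pixels| · s²` for pixel scale `s` (default 6 mm / 500 px);
- **sumL** (mm) — total vascular length: the binarized flow mask is
  thinned to one-pixel centerlines, decomposed into a graph of
  endpoint/bifurcation nodes and vessel-segment edges, and edge chain
  lengths are summed (axial step `s`, diagonal step `√2·s`);
- **FD** — box-counting fractal dimension of the centerline network:
  the slope of `log N(b)` versus `log(1/b)` over a geometric ladder of
  box sizes `b`;
- **flow density** (%) — `100 · |flow pixels| / |ROI pixels|` within
  the delineated MNV region.

Because clinical OCTA cohorts of this kind are not public, the package
ships a first-class synthetic-data module: a stochastic branching
generator for MNV-like networks (known ground-truth length and mask,
rasterized onto the 500×500 en-face grid and degraded with
multiplicative speckle), and a cohort sampler calibrated to the
published moments of a 68-eye nAMD cohort (area 1.106 ± 1.181 mm²,
sumL 12.95 ± 14.24 mm, FD 1.263 ± 0.145, flow density 41.19 ± 5.87 %,
19.8 ± 8.5 IVIs over three years, MNV type proportions 31:19:18), with
an overdispersed negative-binomial injection model.

The association analysis downweights far outliers instead of removing
them: for each numeric variable, percentile fences
`t_low = p10 − 1.5·(p90 − p10)`, `t_high = p90 + 1.5·(p90 − p10)` give
each observation the Gaussian-kernel weight

```
w(x) = exp(−0.5 · (max(0, t_low − x, x − t_high) / (0.5·(t_high − t_low)))²)
```

and a model's per-observation weight is the geometric mean of the
weights of its variables. Models are weighted linear regressions (a
weighted logistic branch exists for dichotomous outcomes); the
visual-acuity models include baseline acuity as a confounder, and MNV
type enters as two indicators with a joint F test.

## Worked example

```python
import mnvquant as m
from skimage.morphology import dilation, disk

# one synthetic eye with known ground truth
net  = m.generate_vessel_tree(0)                      # 28 segments, 8.65 mm total
mask = m.rasterize_network(net)                       # 500x500 binary vessel mask
roi  = m.MnvRoi(dilation(mask, disk(4)))              # delineation around the lesion
img  = m.synthesize_angiogram(mask, seed=100)         # speckled angiogram

metrics = m.quantify(img, roi)
# area=0.936 mm2  sumL=8.38 mm  FD=0.974  flow=33.4%
# sumL recovers the 8.65 mm ground truth within ~3%; this small,
# sparsely branched lesion has a near-curve skeleton, hence FD near 1.

# a calibrated 68-eye cohort and the association battery
cohort = m.generate_cohort(seed=1)
report = m.analyze_cohort(cohort)
for mod in report.models:
    print(f"{mod.name:35s} p={mod.pvalue:.4f}")
```

which prints (seed 1):

```
area_mm2~ivi_count_3y               p=0.1077
suml_mm~ivi_count_3y                p=0.0072
fd~ivi_count_3y                     p=0.0000
flow_density_pct~ivi_count_3y       p=0.4382
area_mm2~va_change                  p=0.4020
suml_mm~va_change                   p=0.3443
fd~va_change                        p=0.5968
flow_density_pct~va_change          p=0.3617
mnv_type~ivi_count_3y               p=0.5196
mnv_type~va_change                  p=0.1485
```

Size and complexity parameters drive the injection count (any single
cohort can miss one of them — power is ≈0.9 per test, here area at
p=0.11), flow density and MNV type do not, and no vascular parameter
relates to visual-acuity change — the embedded association pattern.

The same chain is available from the shell:

```
mnvquant simulate --seed 1 --out runs/demo --n-eyes 68
mnvquant analyze  --out runs/demo
mnvquant quantify --image eye.tif --roi eye_roi.png --pixel-scale 0.012 --out metrics.json
```

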