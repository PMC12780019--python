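# endoquant

Quantitative evaluation of in-situ colorectal tumour therapy from
endoscopic segmentation masks and companion wet-lab read-outs.

In orthotopic colorectal cancer models (AOM/DSS-induced mice), treatment
response is scored endoscopically: how many tumour globules remain, and how
large they are. `endoquant` takes binary lesion masks produced by any
segmenter (e.g. SAM — segmentation itself is out of scope here) and turns
them into per-tumour measurements, then converts pixels to millimetres
through a standard curve fitted on tumours whose true size was measured
after dissection. Around this core it implements the photothermal and
plate-assay arithmetic such a therapy study reports.

## What it computes

**Morphometry.** An image mask is split into 8-connected instances; each
instance's boundary pixels are traced (Moore neighbourhood, clockwise); the
convex hull is built by the monotone-chain method and the maximum Feret
diameter

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>max</sub> = max<sub>p,q ∈ region</sub> ‖p − q‖

is found on hull vertices by rotating calipers (by convexity the maximum
over all region pixels is attained there). Counts and diameters per group
and timepoint form the therapy report.

**Calibration.** Ordinary least squares y = a·x + b maps pixel distance to
physical distance (or assay signal to concentration), with an invertible
model serialized to JSON.

**Photothermal fitting.** For a cooling trace, θ = (T − T<sub>surr</sub>) /
(T<sub>max</sub> − T<sub>surr</sub>) and t = τ·(−ln θ), so τ is a regression
slope. The conversion efficiency follows the lumped energy balance

&nbsp;&nbsp;&nbsp;&nbsp;η = [hs·(T<sub>max</sub> − T<sub>surr</sub>) − Q<sub>dis</sub>] / [I·(1 − 10<sup>−A₈₀₈</sup>)],&nbsp;&nbsp; hs = m·c/τ.

First-order decays (blood clearance) are fitted log-linearly, giving
t<sub>1/2</sub> = τ·ln 2.

**Assay statistics.** Haemolysis rate, cell viability, organ/tumour index,
mass fractions, H₂S quantification through a standard curve, and reduction
rates (C<sub>control</sub> − C<sub>treated</sub>)/C<sub>control</sub> × 100 —
all as exact closed forms.

**Synthetic data.** Every input above can be generated with known ground
truth (shape masks with continuous-geometry diameters, noisy calibration
pairs, exponential cooling/decay curves, plate tables), which is how the
estimation code is validated.

## Worked example

```python
import endoquant as eq

# a synthetic lesion: ellipse with semi-axes 20 and 10 px, rotated 25 deg
spec = eq.ShapeSpec("ellipse", (32, 32), {"a": 20, "b": 10, "rotation_deg": 25.0})
mask, truth = eq.make_mask(64, 64, [spec], seed=4)

cal = eq.fit_linear(eq.make_calibration_pairs(seed=0))   # 38-pair standard curve
rec = eq.measure_mask(mask, min_area_px=5, calibration=cal)[0]
print(f"true diameter {truth.diameters[0]:.1f} px, "
      f"measured {rec.max_diameter_px:.2f} px = {rec.max_diameter_phys:.2f} mm")
```

prints

```
true diameter 40.0 px, measured 39.45 px = 5.04 mm
```

— the measured diameter sits within the ≤1.5 px rasterization bound of the
continuous truth, and the calibrated size applies the fitted mm/px curve
(slope ≈ 0.120). The same pipeline is available from the shell:

```
endoquant simulate --out fixtures --seed 1
endoquant measure --mask-dir fixtures/masks --out measured
endoquant calibrate --pairs fixtures/calibration_pairs.csv --out model.json
```

The numbered scripts under `analysis/` run the whole study on synthetic
data: `01_simulate.py` writes all inputs, `02`–`05` fit the calibration,
measure the masks, fit τ/η/half-life, and evaluate the assay statistics,
printing each recovered value against its generating truth.

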