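# Methods

## Morphometry model

A lesion mask is a rectangular boolean grid. Tumour instances are its
8-connected foreground components (background taken 4-connected, the
standard complementary pair for blob labelling); components smaller than
`min_area_px` (default 5) are discarded as segmentation speckle. Coordinates
are 0-based `(row, col)` and all distances are Euclidean between pixel
centres, in pixel units.

The *boundary* of an instance is the set of its pixels with at least one
4-neighbour that is background or off-image. Its ordering is a clockwise
Moore-neighbourhood trace of the outer contour starting at the raster-first
boundary pixel; if the instance contains holes, each interior contour is
traced afterwards in scan order, so the ordered sequence always covers the
full 4-boundary set (this set-equality is asserted against an exhaustive
neighbour-scan oracle).

The size statistic is the maximum Feret diameter: the largest Euclidean
distance between any two region points. It is computed on the convex hull
of the boundary pixels (monotone chain, strict turns — collinear non-extreme
points are dropped so vertex sets are deterministic) by rotating calipers
over antipodal vertex pairs; by convexity this equals the maximum over all
region pixels, which the tests assert directly. Ties between equal-distance
pairs resolve to the lexicographically smallest endpoint pair for
reproducibility.

With a calibration of slope *a* (mm/px) and intercept *b*, lengths map as
`a·d + b`, areas as `a²·area_px` (the intercept is a length offset and is
not applied to areas), and the estimated volume is a sphere of the
calibrated diameter, `(π/6)·d³`. The sphere rule is this package's own
assumption for converting a single diameter to a volume; output rows carry a
`volume_model` column flagging it. When several images show one tumour from
different angles, the default report is per image; tumour-level aggregation
(keeping the maximum diameter across angles) is available via a
tumour-id mapping.

## Calibration

Standard curves are plain OLS with a free intercept — the conventional form
for instrument calibration; no weighting is applied, and a through-origin
variant exists for curves known to pass through zero. `r_squared` is
reported but nothing is gated on it. Exactly collinear data recover their
parameters to machine precision with `r_squared = 1`; a numerically
constant response with negligible residuals is also reported as 1 (the
0/0 limit is taken as a perfect fit). The model inverts analytically,
`x = (y − b)/a`, failing only for zero slope.

## Photothermal fitting

Cooling after laser switch-off follows Newtonian relaxation
`T(t) = T_surr + (T_max − T_surr)·e^(−t/τ)`. With
`θ = (T − T_surr)/(T_max − T_surr)` this linearizes to `t = τ·(−ln θ)`;
time is re-zeroed at the cooling start (θ = 1) and τ is the through-origin
regression slope (a free-intercept variant exists). Samples with
`θ ≤ θ_min` (default 0.05) are excluded — near ambient the logarithm
amplifies noise without adding information; samples with θ ≤ 0 are flagged,
never silently dropped, and a θ increase above 0.05 between consecutive
samples triggers a warning (reheating or sensor glitch).

The conversion efficiency is the lumped energy balance
`η = [hs(T_max − T_surr) − Q_dis] / [I(1 − 10^(−A₈₀₈))]` with
`hs = m·c/τ` whenever not supplied directly; h and s are never separated —
only their product is dimensionally meaningful here. Units: I in mW (a flag
accepts W), hs in mW/°C (m·c/τ in W/°C is converted), temperatures in °C.
`Q_dis` defaults to 0 when no solvent-blank run is available; with a blank
run it is `hs_blank·(T_max,blank − T_surr)`. η is reported even outside
[0, 1] with a warning flag rather than clipped. The tests pin η to an
independently hand-computed value (e.g. m = 0.3 g, c = 1.96 J/g/°C,
τ = 120 s gives hs = 4.9 mW/°C) and assert its limits and monotonicities
numerically.

First-order decays (blood clearance) are fitted log-linearly:
`ln(v − baseline)` on t, `τ = −1/slope`, `t_1/2 = τ·ln 2`. Non-positive
baseline-subtracted samples are excluded; fewer than three remaining is an
error. A one-compartment model is assumed throughout; multi-exponential
pharmacokinetics are out of scope.

## Assay statistics

All assay quantities are exact closed forms (haemolysis and viability as
normalized OD differences, indices as weight ratios, reduction rates
relative to a control group, apoptosis totals as a sum of fractions), so
testing is by independently coded one-line oracles over random inputs plus
the affine/antitone structure of each formula. H₂S quantification inverts a
fluorescence standard curve per group; negative inversions are floored at 0
(a concentration cannot be negative) with a warning. Percentages keep full
precision internally; display rounding is 3 significant figures, 4 where
the source style uses them (mass fractions).

## Synthetic data

Generators are pure functions of (parameters, seed) and their defaults are
the study conditions: 38 calibration pairs at σ = 0.05 mm around
y = 0.12x + 0.3 over 20–200 px (plausible mm-per-pixel scale for close-range
endoscopy); cooling between T_surr = 26.1 °C and T_max = 53.5 °C with
τ = 120 s (a laboratory cuvette relaxes on the order of minutes), sampled
at 1 s for 600 s; blood decay with half-life 3.16 h sampled every 2 h for
24 h at 5 % relative noise; the fixed H₂S group table
{PBS 2.8, NIR 2.5, MCC 1.27, MCC+NIR 0.98, PfCC+NIR 0.676} mM.

Masks rasterize a continuous shape by the pixel-centre rule (foreground iff
the centre lies inside or on the shape), which bounds the discretized
diameter of a shape of continuous diameter D to [D − 2, D] — hence the
1.5 px recovery tolerance used in tests at the generated sizes. Blobs are
star-convex radial perturbations of a circle (harmonics 2–4, bounded
amplitude), so their true diameter is computable by dense angular sampling
of the continuous boundary. Speckle is isolated single pixels kept ≥2 px
from shapes; holes are knocked only out of interior pixels so hull and
diameter are unaffected. Shapes must be ≥2 px apart or generation fails —
touching shapes would merge under 8-connectivity.

What the generators do *not* emulate: real endoscopic masks have soft,
operator- and model-dependent edges, motion blur, specular highlights and
non-elliptical lesions; plate data can be heteroscedastic and drift.
Passing the recovery tests therefore demonstrates correctness of the
estimation code under the stated noise models, not segmentation quality or
instrument behaviour on real data.

## Apoptosis fixture

Only the 20 µg/mL condition has a published early/late/necrosis split
(27.0/14.5/23.0 %); the 40 µg/mL split in the synthetic table is an
invented placement consistent with its known 68.9 % total and is synthetic
by construction (the 80 µg/mL early fraction is likewise derived from its
total minus the published late/necrosis values).

## Problem sizes and numerical choices

Test and driver problem sizes — 64–128 px images, ≤300-point hull oracle
sweeps, 20–50 seed Monte-Carlo recoveries — were chosen as the smallest
scales at which the discretization and sampling bounds above are
informative. Hull comparisons use exact arithmetic agreement (same float
operations on both routes); stochastic recoveries compare medians across
seeds against generator truth. Degenerate inputs (single-pixel instances,
collinear point sets, constant traces, all-baseline decays, zero-slope
curves) are all defined behaviours or explicit errors, covered in the
suite.
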