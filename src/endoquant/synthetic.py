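"""Ground-truth generators for every pipeline input.

Each generator is a pure function of its parameters and a seed, and its
defaults encode the study conditions the measurements emulate: a 38-point
pixel-to-millimetre calibration (38 tumours photographed endoscopically and
measured after dissection), Newtonian cooling between an ambient of 26.1 degC
and a plateau of 53.5 degC with a ~2-minute time constant, a blood-clearance
half-life of 3.16 h, and the H2S group-concentration table
{2.8, 2.5, 1.27, 0.98, 0.676} mM.

Rasterization rule: a pixel is foreground iff its centre lies inside (or on)
the continuous shape.  This makes the discretized max diameter of a shape of
continuous diameter D fall in [D - 2, D], i.e. within the 1.5 px bound used
by the recovery tests for the sizes generated here.  Blobs are star-convex
radial perturbations of a circle, so their true diameter is computable by
dense angular sampling of the continuous boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull as _SciHull

from .calibration import CalibrationPair
from .photothermal import TemperatureTrace

__all__ = [
    "ShapeSpec", "SyntheticTruth",
    "make_mask", "make_calibration_pairs", "make_cooling_curve",
    "make_decay_curve", "make_assay_tables",
    "H2S_GROUP_CONCENTRATIONS_MM",
]

#: Intratumoural H2S concentrations by treatment group (mM) used as the
#: fixed fixture for reduction-rate reports.
H2S_GROUP_CONCENTRATIONS_MM = {
    "PBS": 2.8,
    "NIR": 2.5,
    "MCC": 1.27,
    "MCC+NIR": 0.98,
    "PfCC+NIR": 0.676,
}


@dataclass
class ShapeSpec:
    """A continuous shape to rasterize.

    kind "ellipse": params {"a": semi-axis px, "b": semi-axis px,
    "rotation_deg": float}; kind "convex-polygon": params {"vertices":
    [(row, col), ...]}; kind "blob": params {"radius": px, "jitter_amp":
    relative amplitude of the radial perturbation (star-convex for
    jitter_amp < ~0.3)}.
    """
    kind: str
    center: tuple
    params: dict
    label: int = 1


@dataclass
class SyntheticTruth:
    count: int
    diameters: list = field(default_factory=list)   # continuous-geometry px
    areas: list = field(default_factory=list)       # continuous px^2
    labels: list = field(default_factory=list)


def _blob_radius(spec: ShapeSpec, seed: int):
    """Radius function R(phi) of a star-convex blob, seeded per label."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, spec.label, 7]))
    coeffs = rng.normal(size=(3, 2))   # harmonics k = 2, 3, 4
    r0 = float(spec.params["radius"])
    amp = float(spec.params.get("jitter_amp", 0.1))
    norm = np.abs(coeffs).sum() or 1.0

    def radius(phi):
        pert = np.zeros_like(phi, dtype=float)
        for i, k in enumerate((2, 3, 4)):
            pert = pert + coeffs[i, 0] * np.cos(k * phi) + coeffs[i, 1] * np.sin(k * phi)
        return r0 * (1.0 + amp * pert / norm)

    return radius


def _rasterize(spec: ShapeSpec, height: int, width: int, seed: int):
    """(mask, true_diameter, true_area) for one shape."""
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    r0, c0 = spec.center
    if spec.kind == "ellipse":
        a = float(spec.params["a"])
        b = float(spec.params["b"])
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        phi = math.radians(float(spec.params.get("rotation_deg", 0.0)))
        dr = rr - r0
        dc = cc - c0
        u = dr * math.cos(phi) + dc * math.sin(phi)
        v = -dr * math.sin(phi) + dc * math.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        diam = 2.0 * max(a, b)
        area = math.pi * a * b
        extent = max(a, b)
        if r0 - extent < 0 or r0 + extent > height - 1 or \
           c0 - extent < 0 or c0 + extent > width - 1:
            raise ValueError("shape does not fit inside the image")
    elif spec.kind == "convex-polygon":
        verts = [(float(r), float(c)) for r, c in spec.params["vertices"]]
        poly = shapely.Polygon(verts)
        inside = shapely.contains_xy(poly, rr.ravel(), cc.ravel()).reshape(rr.shape)
        inside |= shapely.intersects_xy(poly.boundary, rr.ravel(),
                                        cc.ravel()).reshape(rr.shape)
        diam = max(math.dist(p, q) for p in verts for q in verts)
        area = poly.area
        rs = [v[0] for v in verts]
        cs = [v[1] for v in verts]
        if min(rs) < 0 or max(rs) > height - 1 or min(cs) < 0 or max(cs) > width - 1:
            raise ValueError("shape does not fit inside the image")
    elif spec.kind == "blob":
        radius = _blob_radius(spec, seed)
        dr = rr - r0
        dc = cc - c0
        phi = np.arctan2(dc, dr)
        inside = np.hypot(dr, dc) <= radius(phi)
        # dense boundary sampling; the diameter of a star-convex region is
        # attained between boundary points, found via their convex hull
        ang = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
        rad = radius(ang)
        if np.any(rad <= 0):
            raise ValueError("blob jitter too large (radius goes non-positive)")
        pts = np.column_stack([r0 + rad * np.cos(ang), c0 + rad * np.sin(ang)])
        hv = pts[_SciHull(pts).vertices]
        diff = hv[:, None, :] - hv[None, :, :]
        diam = float(np.sqrt((diff ** 2).sum(axis=2)).max())
        area = float(0.5 * np.sum(rad ** 2) * (2.0 * math.pi / ang.size))
        if pts[:, 0].min() < 0 or pts[:, 0].max() > height - 1 or \
           pts[:, 1].min() < 0 or pts[:, 1].max() > width - 1:
            raise ValueError("shape does not fit inside the image")
    else:
        raise ValueError(f"unknown shape kind {spec.kind!r}")
    return inside, float(diam), float(area)


def make_mask(height: int, width: int, shapes: Sequence[ShapeSpec],
              speckle_density: float = 0.0, hole_density: float = 0.0,
              seed: int = 0):
    """Rasterize *shapes* plus optional speckle and holes.

    Returns (mask, SyntheticTruth).  Shapes must be pairwise separated by at
    least 2 px (checked on the rasterized footprints) so instance labelling
    cannot merge them.  Speckle adds isolated single foreground pixels away
    from the shapes; holes knock out interior pixels (never boundary pixels,
    so hull and diameter are unaffected).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    masks = []
    truth = SyntheticTruth(count=0)
    for spec in shapes:
        m, diam, area = _rasterize(spec, height, width, seed)
        masks.append(m)
        truth.diameters.append(diam)
        truth.areas.append(area)
        truth.labels.append(spec.label)
    truth.count = len(masks)

    combined = np.zeros((height, width), dtype=bool)
    for i, m in enumerate(masks):
        grown = ndimage.binary_dilation(m, structure=np.ones((3, 3), bool),
                                        iterations=2)
        if (grown & combined).any():
            raise ValueError("shapes overlap (or closer than 2 px)")
        combined |= m

    mask = combined.copy()
    if hole_density > 0:
        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
        cand = np.flatnonzero(interior.ravel())
        n_holes = int(round(hole_density * cand.size))
        if n_holes:
            drop = rng.choice(cand, size=min(n_holes, cand.size), replace=False)
            mask.ravel()[drop] = False

    if speckle_density > 0:
        keepout = ndimage.binary_dilation(combined, np.ones((3, 3), bool),
                                          iterations=2)
        cand = np.flatnonzero(~keepout.ravel())
        n_spk = int(round(speckle_density * cand.size))
        if n_spk:
            chosen = rng.choice(cand, size=min(n_spk, cand.size), replace=False)
            placed: list = []
            for flat in chosen:
                r, c = divmod(int(flat), width)
                if all(max(abs(r - pr), abs(c - pc)) > 1 for pr, pc in placed):
                    mask[r, c] = True
                    placed.append((r, c))
    return mask, truth


def make_calibration_pairs(slope: float = 0.12, intercept: float = 0.3,
                           sigma: float = 0.05, n: int = 38,
                           x_range: tuple = (20.0, 200.0), seed: int = 0
                           ) -> list[CalibrationPair]:
    """Noisy points on y = slope * x + intercept, x uniform in *x_range*.

    Defaults mimic the 38-tumour endoscopy calibration at mm-scale noise.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = slope * x + intercept + rng.normal(0.0, sigma, size=n)
    return [CalibrationPair(float(a), float(b)) for a, b in zip(x, y)]


def make_cooling_curve(T_surr: float = 26.1, T_max: float = 53.5,
                       tau_s: float = 120.0, dt: float = 1.0,
                       duration: float = 600.0, sigma: float = 0.0,
                       seed: int = 0) -> TemperatureTrace:
    """Single-exponential cooling T(t) = T_surr + (T_max - T_surr) e^(-t/tau).

    Gaussian measurement noise of std *sigma* degC is added pointwise.
    """
    if tau_s <= 0 or dt <= 0 or duration < 3 * dt or sigma < 0 or T_max <= T_surr:
        raise ValueError("invalid cooling-curve parameters")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    temp = T_surr + (T_max - T_surr) * np.exp(-t / tau_s)
    temp = temp + rng.normal(0.0, sigma, size=t.size)
    return TemperatureTrace(time_s=t, temp_C=temp, phase=["cooling"] * t.size)


def make_decay_curve(amplitude: float = 100.0, half_life: float = 3.16,
                     baseline: float = 0.0, rel_sigma: float = 0.05,
                     times: Optional[np.ndarray] = None, seed: int = 0):
    """First-order decay samples, e.g. blood concentration after injection.

    v(t) = baseline + amplitude * exp(-t ln2 / half_life), with multiplicative
    Gaussian noise of relative std *rel_sigma* on the decaying part.  Default
    half-life and sampling span mirror a probe cleared from blood over a day.
    Returns a list of (time, value).
    """
    if half_life <= 0 or amplitude <= 0 or rel_sigma < 0:
        raise ValueError("invalid decay parameters")
    if times is None:
        times = np.arange(0.0, 24.1, 2.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    tau = half_life / math.log(2.0)
    clean = amplitude * np.exp(-times / tau)
    noisy = clean * (1.0 + rng.normal(0.0, rel_sigma, size=times.size))
    return list(zip(times.tolist(), (baseline + noisy).tolist()))


def make_assay_tables(seed: int = 0, hemolysis_pct: float = 50.0,
                      viability_pct: float = 87.8,
                      od_negative: float = 0.1, od_positive: float = 1.1,
                      sigma_od: float = 0.0,
                      curve_slope: float = 100.0, curve_intercept: float = 50.0,
                      curve_sigma: float = 0.0) -> dict:
    """CSV-ready assay tables with known truth.

    Returns a dict of DataFrames:

    * ``hemolysis_plate`` / ``viability_plate``: (well, role, od) with the
      sample od placed so the true rate is *hemolysis_pct* / *viability_pct*
      before noise.
    * ``h2s_standard_curve``: (concentration_mM, fluorescence) on a line of
      slope *curve_slope* AU/mM and intercept *curve_intercept* AU.
    * ``h2s_groups``: (group, concentration_mM, fluorescence) embedding the
      fixed group-concentration fixture, signals via the same curve.
    * ``apoptosis``: (condition, early_pct, late_pct, necrosis_pct).  The
      20 ug/mL row carries the measured split; the other splits are synthetic
      placements consistent with their known totals.
    """
    rng = np.random.default_rng(seed)

    def plate(rate):
        od_s = od_negative + rate / 100.0 * (od_positive - od_negative)
        ods = np.array([od_s, od_negative, od_positive])
        ods = ods + rng.normal(0.0, sigma_od, size=3)
        return pd.DataFrame({
            "well": ["A1", "A2", "A3"],
            "role": ["sample", "negative", "positive"],
            "od": ods,
        })

    conc = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    signal = curve_slope * conc + curve_intercept \
        + rng.normal(0.0, curve_sigma, size=conc.size)
    std_curve = pd.DataFrame({"concentration_mM": conc, "fluorescence": signal})

    groups = pd.DataFrame({
        "group": list(H2S_GROUP_CONCENTRATIONS_MM),
        "concentration_mM": list(H2S_GROUP_CONCENTRATIONS_MM.values()),
    })
    groups["fluorescence"] = curve_slope * groups["concentration_mM"] + curve_intercept

    apoptosis = pd.DataFrame({
        "condition": ["H2S 20 ug/mL", "H2S 40 ug/mL", "H2S 80 ug/mL"],
        "early_pct": [27.0, 23.9, 19.4],
        "late_pct": [14.5, 21.4, 27.1],
        "necrosis_pct": [23.0, 23.6, 27.6],
    })

    return {
        "hemolysis_plate": plate(hemolysis_pct),
        "viability_plate": plate(viability_pct),
        "h2s_standard_curve": std_curve,
        "h2s_groups": groups,
        "apoptosis": apoptosis,
    }
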