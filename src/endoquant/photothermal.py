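"""Photothermal time-constant fitting and conversion efficiency.

A laser-heated sample relaxes toward ambient as Newtonian cooling,
``T(t) = T_surr + (T_max - T_surr) exp(-t/tau)``.  With the dimensionless
driving force ``theta = (T - T_surr)/(T_max - T_surr)`` the cooling branch
satisfies ``t = tau * (-ln theta)``, so tau is the slope of elapsed cooling
time regressed on -ln(theta) through the origin.

The photothermal conversion efficiency of an absorber irradiated at 808 nm
follows the Roper energy balance,

    eta = [ hs (T_max - T_surr) - Q_dis ] / [ I (1 - 10**(-A_808)) ]

with the lumped heat-transfer term ``hs = m c / tau`` (mass * specific heat
/ time constant, converted to mW/degC so it matches a laser power quoted in
mW), ``Q_dis`` the baseline heat input absorbed by solvent and container,
and ``A_808`` the absorbance at the laser wavelength.  The same log-linear
machinery fits first-order decays generally, e.g. the blood-clearance
half-life of a circulating probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TemperatureTrace", "PhotothermalParams", "EfficiencyResult",
    "normalize_theta", "fit_time_constant", "conversion_efficiency",
    "fit_exponential_decay", "delta_T",
]

#: Samples with theta at or below this are excluded from the log fit by
#: default: near ambient the logarithm blows up and noise dominates.
DEFAULT_THETA_MIN = 0.05


@dataclass
class TemperatureTrace:
    """Time-temperature samples; *phase* optionally labels heating/cooling."""
    time_s: np.ndarray
    temp_C: np.ndarray
    phase: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.time_s.size != self.temp_C.size or self.time_s.size < 3:
            raise ValueError("trace needs >= 3 equal-length time/temp samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class PhotothermalParams:
    """Symbols of the efficiency formula; supply either tau_s (with m, c) or hs.

    Units: temperatures degC, I in mW (set power_in_watts=True for W),
    m in g, c in J/(g degC), tau_s in s, hs in mW/degC, Q_dis in mW.
    """
    T_max: float
    T_surr: float
    A_808: float
    I: float
    m: Optional[float] = None
    c: Optional[float] = None
    tau_s: Optional[float] = None
    hs: Optional[float] = None
    Q_dis: float = 0.0
    power_in_watts: bool = False


@dataclass
class EfficiencyResult:
    eta: float
    tau_s: Optional[float]
    hs: float
    theta_fit_r2: Optional[float] = None
    n_points_used: Optional[int] = None
    warnings: list = field(default_factory=list)


def normalize_theta(trace: TemperatureTrace, T_surr: float, T_max: float):
    """Return (time_s, theta, flagged) with theta = (T - T_surr)/(T_max - T_surr).

    *flagged* marks samples with theta <= 0 (at or below ambient); they are
    reported, not dropped.
    """
    if T_max <= T_surr:
        raise ValueError("invalid temperature bounds (T_max must exceed T_surr)")
    theta = (trace.temp_C - T_surr) / (T_max - T_surr)
    return trace.time_s.copy(), theta, theta <= 0


def fit_time_constant(cooling: TemperatureTrace, T_surr: float, T_max: float,
                      theta_min: float = DEFAULT_THETA_MIN,
                      through_origin: bool = True):
    """Fit tau from a cooling trace: t regressed on -ln(theta).

    Time is re-zeroed at the first sample (cooling start, theta = 1).
    Returns (tau_s, r2, n_used, warnings).  Raises if fewer than three
    samples fall in (theta_min, 1].
    """
    t, theta, _ = normalize_theta(cooling, T_surr, T_max)
    t = t - t[0]
    usable = (theta > theta_min) & (theta <= 1.0)
    warnings = []
    jumps = np.diff(theta)
    if np.any(jumps > 0.05):
        warnings.append("theta increases by > 0.05 between consecutive samples")
    if usable.sum() < 3:
        raise ValueError("insufficient cooling data (need >= 3 usable samples)")
    x = -np.log(theta[usable])
    y = t[usable]
    if through_origin:
        tau = float(np.dot(x, y) / np.dot(x, x))
        resid = y - tau * x
    else:
        res = stats.linregress(x, y)
        tau = float(res.slope)
        resid = y - (res.slope * x + res.intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    return tau, r2, int(usable.sum()), warnings


def _lumped_hs(p: PhotothermalParams) -> float:
    if p.hs is not None:
        return float(p.hs)
    if p.m is None or p.c is None or p.tau_s is None:
        raise ValueError("supply hs directly or all of (m, c, tau_s)")
    # m*c/tau is in W/degC; the mW convention matches I quoted in mW
    return float(p.m * p.c / p.tau_s * 1000.0)


def conversion_efficiency(p: PhotothermalParams) -> EfficiencyResult:
    """Photothermal conversion efficiency from the lumped energy balance.

    eta is reported even outside [0, 1], with a warning flag, since noisy
    inputs can push the estimate out of the physical range.
    """
    if p.I <= 0 or p.A_808 <= 0:
        raise ValueError("invalid optical parameters (I and A_808 must be > 0)")
    if p.T_max < p.T_surr:
        raise ValueError("invalid temperature bounds (T_max below T_surr)")
    if p.Q_dis < 0:
        raise ValueError("Q_dis must be non-negative")
    hs = _lumped_hs(p)
    power_mw = p.I * 1000.0 if p.power_in_watts else p.I
    eta = (hs * (p.T_max - p.T_surr) - p.Q_dis) / (power_mw * (1.0 - 10.0 ** (-p.A_808)))
    warnings = []
    if not 0.0 <= eta <= 1.0:
        warnings.append("eta outside [0, 1]")
    return EfficiencyResult(eta=float(eta), tau_s=p.tau_s, hs=hs,
                            warnings=warnings)


def fit_exponential_decay(samples, baseline: float = 0.0):
    """Fit v(t) = baseline + a * exp(-t/tau) by log-linear least squares.

    *samples* is a sequence of (time, value).  Samples at or below baseline
    are excluded; fewer than three remaining raises.  Returns
    (tau, half_life, r2) with half_life = tau * ln 2.
    """
    arr = np.asarray([(s[0], s[1]) for s in samples], dtype=float)
    keep = arr[:, 1] > baseline
    if keep.sum() < 3:
        raise ValueError("insufficient decay data (need >= 3 samples above baseline)")
    t = arr[keep, 0]
    lv = np.log(arr[keep, 1] - baseline)
    res = stats.linregress(t, lv)
    if res.slope >= 0:
        raise ValueError("samples do not decay (non-negative log-slope)")
    tau = -1.0 / float(res.slope)
    return tau, tau * math.log(2.0), float(res.rvalue ** 2)


def delta_T(trace: TemperatureTrace, at_time_s: float) -> float:
    """Temperature rise at *at_time_s* relative to the trace start.

    Linear interpolation between samples; times outside the trace span raise.
    """
    if not (trace.time_s[0] <= at_time_s <= trace.time_s[-1]):
        raise ValueError("time outside trace")
    temp = float(np.interp(at_time_s, trace.time_s, trace.temp_C))
    return temp - float(trace.temp_C[0])
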