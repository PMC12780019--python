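"""Closed-form plate-assay and gross-burden statistics.

Each function is the exact formula the corresponding wet-lab assay reports:

* haemolysis rate     (OD_sample - OD_PBS) / (OD_water - OD_PBS) * 100
* cell viability      (OD_exp - OD_blank) / (OD_ctrl - OD_blank) * 100
* mass fraction       component / total * 100
* reduction rate      (C_control - C_treated) / C_control * 100
* organ/tumour index  weight / body weight * 100
* apoptosis total     early + late + necrosis

plus standard-curve H2S quantification (WSP-1 fluorescence inverted through
a linear calibration).  Percentages are kept at full precision internally;
``round_sig`` applies the display convention (3 significant figures for
rates, 4 where the source style demands it, e.g. mass fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .calibration import CalibrationModel, invert_calibration

__all__ = [
    "ODReading", "GroupConcentration", "ApoptosisFractions",
    "hemolysis_rate", "cell_viability", "mass_fraction", "reduction_rate",
    "organ_index", "tumour_index", "apoptosis_total", "quantify_h2s",
    "round_sig",
]


def round_sig(value: float, sig: int = 3) -> float:
    """Round to *sig* significant figures (display convention)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - int(math.floor(math.log10(abs(value)))))


@dataclass(frozen=True)
class ODReading:
    """Absorbances of a well plus its negative and positive controls.

    For haemolysis the negative control is PBS and the positive is ultrapure
    water; for viability the negative is the cell-free blank and the positive
    the untreated control.
    """
    od_sample: float
    od_negative: float
    od_positive: float


@dataclass(frozen=True)
class GroupConcentration:
    group: str
    concentration: float        # mM (or any unit shared across groups)

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class ApoptosisFractions:
    early_pct: float
    late_pct: float
    necrosis_pct: float

    def __post_init__(self):
        for v in (self.early_pct, self.late_pct, self.necrosis_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("fractions must lie in [0, 100]")
        if self.early_pct + self.late_pct + self.necrosis_pct > 100.5:
            raise ValueError("fractions sum above 100% beyond rounding slack")


def _normalized(r: ODReading) -> float:
    if r.od_positive == r.od_negative:
        raise ValueError("degenerate controls (positive equals negative)")
    return (r.od_sample - r.od_negative) / (r.od_positive - r.od_negative) * 100.0


def hemolysis_rate(r: ODReading) -> float:
    """Erythrocyte lysis relative to the PBS/water control pair, percent.

    Measurement noise can push the value outside [0, 100]; it is returned
    unclipped so the caller sees the raw statistic.
    """
    return _normalized(r)


def cell_viability(r: ODReading) -> float:
    """Viability relative to the blank/untreated control pair, percent."""
    return _normalized(r)


def mass_fraction(component_mass: float, total_mass: float) -> float:
    """Component share of the total formulation mass, percent."""
    if total_mass <= 0:
        raise ValueError("invalid total (must be positive)")
    if component_mass < 0:
        raise ValueError("component mass must be non-negative")
    return component_mass / total_mass * 100.0


def reduction_rate(control: GroupConcentration, treated: GroupConcentration) -> float:
    """Relative depletion of the treated group versus the control, percent.

    Used both for intratumoural H2S depletion and for the metabolic
    elimination of cobalt from organs over time.
    """
    if control.concentration == 0:
        raise ValueError("zero control concentration")
    return (control.concentration - treated.concentration) / control.concentration * 100.0


def organ_index(organ_weight: float, body_weight: float) -> float:
    """Organ weight as a percentage of body weight (gross-toxicity metric)."""
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    if organ_weight < 0:
        raise ValueError("organ weight must be non-negative")
    return organ_weight / body_weight * 100.0


def tumour_index(tumour_weight: float, body_weight: float) -> float:
    """Tumour weight as a percentage of body weight (burden metric)."""
    return organ_index(tumour_weight, body_weight)


def apoptosis_total(f: ApoptosisFractions) -> float:
    """Total affected fraction: early + late apoptosis + necrosis, percent."""
    return f.early_pct + f.late_pct + f.necrosis_pct


def quantify_h2s(signals: Sequence, curve: CalibrationModel):
    """Convert per-group fluorescence to concentration via a standard curve.

    *signals* is a sequence of (group, fluorescence).  Inversions below zero
    (signal under the curve intercept) are floored at 0 — a negative
    concentration is unphysical — and reported in the warnings list.
    Returns (list of GroupConcentration, warnings).
    """
    out = []
    warnings = []
    for group, signal in signals:
        conc = invert_calibration(curve, signal)
        if conc < 0:
            warnings.append(f"group {group!r}: inverted concentration "
                            f"{conc:.4g} floored at 0")
            conc = 0.0
        out.append(GroupConcentration(group=str(group), concentration=conc))
    return out, warnings
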