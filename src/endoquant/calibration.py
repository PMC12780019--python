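"""Linear standard curves.

Two uses share one model: the endoscopy calibration mapping pixel distance
to physical distance (fitted from photographed tumours whose true size was
measured after dissection), and generic assay curves mapping a signal
(fluorescence, absorbance) to a concentration.

The fit is ordinary least squares with a free intercept — the conventional
form for standard curves; a through-origin variant is available.  No
weighting is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CalibrationPair", "CalibrationModel", "fit_linear",
           "apply_calibration", "invert_calibration"]


@dataclass(frozen=True)
class CalibrationPair:
    """One observation (x = pixel distance or signal, y = mm or concentration)."""
    x: float
    y: float


@dataclass
class CalibrationModel:
    slope: float                # y-units per x-unit
    intercept: float            # y-units
    r_squared: float
    n: int
    x_units: str = "px"
    y_units: str = "mm"

    def apply(self, x: float) -> float:
        """Predict y = slope * x + intercept."""
        return self.slope * x + self.intercept

    def invert(self, y: float) -> float:
        """Solve slope * x + intercept = y for x."""
        if self.slope == 0:
            raise ValueError("non-invertible curve (slope is zero)")
        return (y - self.intercept) / self.slope

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
            else str(source)
        return cls(**json.loads(text))


def _as_xy(pairs: Sequence) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray([p.x if isinstance(p, CalibrationPair) else p[0] for p in pairs],
                   dtype=float)
    y = np.asarray([p.y if isinstance(p, CalibrationPair) else p[1] for p in pairs],
                   dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("calibration pairs must be finite")
    return x, y


def fit_linear(pairs: Sequence, *, through_origin: bool = False,
               x_units: str = "px", y_units: str = "mm") -> CalibrationModel:
    """Fit y = slope * x + intercept by ordinary least squares.

    Raises on fewer than two pairs or an all-equal x design.  When the data
    lie exactly on a line (zero total and residual sum of squares) the fit
    reports r_squared = 1 by convention.
    """
    x, y = _as_xy(pairs)
    if x.size < 2:
        raise ValueError("insufficient pairs (need at least 2)")
    if np.all(x == x[0]):
        raise ValueError("degenerate design (all x values identical)")

    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum(resid ** 2))
        r2 = 1.0 if sst == 0 and sse == 0 else (1.0 - sse / sst if sst > 0 else 0.0)
        r2 = float(min(max(r2, 0.0), 1.0))
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        sse = float(np.sum((y - (slope * x + intercept)) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        noise = 1e-20 * max(1.0, float(np.sum(y * y)))
        if sst <= noise:
            # constant response: perfect fit unless residuals are non-trivial
            r2 = 1.0 if sse <= noise else 0.0
        else:
            r2 = float(res.rvalue ** 2)
    return CalibrationModel(slope=slope, intercept=intercept, r_squared=r2,
                            n=int(x.size), x_units=x_units, y_units=y_units)


def apply_calibration(model: CalibrationModel, x: float) -> float:
    return model.apply(x)


def invert_calibration(model: CalibrationModel, y: float) -> float:
    return model.invert(y)


def read_pairs_csv(path) -> list[CalibrationPair]:
    """Read a 2-column CSV with an (x, y) header row."""
    import pandas as pd
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a 2-column CSV with header (x, y)")
    return [CalibrationPair(float(a), float(b))
            for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
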