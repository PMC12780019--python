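"""Readers and writers for the formats the pipeline exchanges.

Masks are PNG/TIFF images: any nonzero pixel is foreground, or a greyscale
image may be binarized with an explicit threshold.  Tables are comma
separated with a header row, UTF-8, "." decimal.  Reports are JSON with 12
significant digits of float precision so a write/read round trip is
lossless at serialization precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import MorphometryRecord
from .photothermal import TemperatureTrace

__all__ = [
    "read_mask", "write_mask", "records_to_frame", "write_records_csv",
    "write_records_json", "read_trace_csv", "write_trace_csv", "write_json",
]


def read_mask(path, threshold: Optional[float] = None) -> np.ndarray:
    """Load a PNG/TIFF as a boolean mask.

    Multichannel images are reduced by "any channel nonzero".  With
    *threshold*, greyscale values strictly above it are foreground.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img.max(axis=2)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image")
    if threshold is not None:
        return img > threshold
    return img != 0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def records_to_frame(records: Sequence[MorphometryRecord],
                     image_id: str = "") -> pd.DataFrame:
    rows = [dict(image_id=image_id, **r.to_dict()) for r in records]
    cols = ["image_id", "instance_id", "area_px", "max_diameter_px",
            "endpoint1_row", "endpoint1_col", "endpoint2_row", "endpoint2_col",
            "max_diameter_phys", "area_phys", "est_volume_phys", "volume_model"]
    return pd.DataFrame(rows, columns=cols)


def write_records_csv(path, records, image_id: str = "") -> None:
    records_to_frame(records, image_id).to_csv(path, index=False,
                                               float_format="%.12g")


def write_records_json(path, records, image_id: str = "") -> None:
    payload = {"image_id": image_id,
               "tumour_count": len(records),
               "instances": [r.to_dict() for r in records]}
    write_json(path, payload)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_json(path, payload: dict) -> None:
    """JSON with floats at 12 significant digits (round-trip precision)."""
    Path(path).write_text(json.dumps(_round_floats(payload), indent=2) + "\n")


def read_trace_csv(path) -> TemperatureTrace:
    """Read a 2-3 column (time_s, temp_C[, phase]) temperature trace."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs columns time_s, temp_C[, phase]")
    phase = df.iloc[:, 2].tolist() if df.shape[1] >= 3 else None
    return TemperatureTrace(time_s=df.iloc[:, 0].to_numpy(float),
                            temp_C=df.iloc[:, 1].to_numpy(float),
                            phase=phase)


def write_trace_csv(path, trace: TemperatureTrace) -> None:
    data = {"time_s": trace.time_s, "temp_C": trace.temp_C}
    if trace.phase is not None:
        data["phase"] = list(trace.phase)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
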