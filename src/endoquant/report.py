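"""Group-level therapy reports.

Endoscopic evaluation compares treatment groups by tumour count and size
per timepoint.  ``build_group_report`` aggregates per-image morphometry
records into one row per (group, timepoint).

Multi-angle caveat: several images may show the same tumour from different
angles.  The default aggregates per image (each image's instances counted);
with ``key="tumour"`` records sharing a tumour id keep only the maximum
diameter across angles, which is the better size estimate when angles of
one lesion are known.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

__all__ = ["build_group_report"]


def build_group_report(frames: Sequence[pd.DataFrame],
                       meta: pd.DataFrame,
                       key: str = "image") -> pd.DataFrame:
    """Aggregate morphometry frames into a per-(group, timepoint) report.

    *frames* are ``records_to_frame`` outputs (one per image); *meta* maps
    image_id -> group, timepoint and, for key="tumour", a tumour_id column.
    Returns columns: group, timepoint, tumour_count, mean_diameter,
    max_diameter, total_volume (physical units when calibrated, else px).
    """
    if key not in {"image", "tumour"}:
        raise ValueError("key must be 'image' or 'tumour'")
    records = pd.concat([f for f in frames], ignore_index=True) if frames \
        else pd.DataFrame(columns=["image_id"])
    if records.empty:
        return pd.DataFrame(columns=["group", "timepoint", "tumour_count",
                                     "mean_diameter", "max_diameter",
                                     "total_volume"])
    merged = records.merge(meta, on="image_id", how="left")
    diam = merged["max_diameter_phys"].where(
        merged["max_diameter_phys"].notna(), merged["max_diameter_px"])
    merged = merged.assign(_diam=diam)

    if key == "tumour":
        if "tumour_id" not in merged.columns:
            raise ValueError("tumour-level aggregation needs a tumour_id column")
        idx = merged.groupby(["group", "timepoint", "tumour_id"])["_diam"].idxmax()
        merged = merged.loc[idx]

    def summarize(g: pd.DataFrame) -> pd.Series:
        vol = g["est_volume_phys"].dropna()
        return pd.Series({
            "tumour_count": int(len(g)),
            "mean_diameter": float(g["_diam"].mean()),
            "max_diameter": float(g["_diam"].max()),
            "total_volume": float(vol.sum()) if len(vol) else float("nan"),
        })

    out = (merged.groupby(["group", "timepoint"])
           .apply(summarize, include_groups=False)
           .reset_index())
    out["tumour_count"] = out["tumour_count"].astype(int)
    return out
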