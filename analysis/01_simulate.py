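#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes endoscopy-style lesion masks (PNG, under scratch/ since they are
binary), the 38-point pixel/mm calibration table, a noisy cooling trace, a
blood-clearance decay series, and the assay tables, under results/ and
scratch/fixtures/.  Everything is deterministic for the seed below.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from endoquant import io, synthetic

SEED = 0
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIXTURES = ROOT / "scratch" / "fixtures"


def main():
    (FIXTURES / "masks").mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    truth_rows = []
    for i in range(8):
        a = float(rng.uniform(8, 22))
        b = float(rng.uniform(6, a))
        margin = a + 2
        spec = synthetic.ShapeSpec(
            "ellipse",
            (float(rng.uniform(margin, 127 - margin)),
             float(rng.uniform(margin, 127 - margin))),
            {"a": a, "b": b, "rotation_deg": float(rng.uniform(0, 180))})
        mask, truth = synthetic.make_mask(128, 128, [spec],
                                          speckle_density=0.002,
                                          seed=int(rng.integers(2 ** 31)))
        name = f"mask_{i:03d}"
        io.write_mask(FIXTURES / "masks" / f"{name}.png", mask)
        truth_rows.append({"image_id": name, "count": truth.count,
                           "true_diameter_px": truth.diameters[0]})
    pd.DataFrame(truth_rows).to_csv(RESULTS / "mask_truth.csv", index=False,
                                    float_format="%.12g")

    pairs = synthetic.make_calibration_pairs(seed=SEED)     # 38-tumour analogue
    pd.DataFrame([(p.x, p.y) for p in pairs], columns=["x", "y"]).to_csv(
        RESULTS / "calibration_pairs.csv", index=False, float_format="%.12g")

    io.write_trace_csv(RESULTS / "cooling_trace.csv",
                       synthetic.make_cooling_curve(sigma=0.2, seed=SEED))

    decay = synthetic.make_decay_curve(half_life=3.16, rel_sigma=0.05,
                                       seed=SEED)
    pd.DataFrame(decay, columns=["time_h", "signal"]).to_csv(
        RESULTS / "blood_decay.csv", index=False, float_format="%.12g")

    for name, df in synthetic.make_assay_tables(seed=SEED).items():
        df.to_csv(RESULTS / f"{name}.csv", index=False, float_format="%.12g")

    print(f"wrote {len(truth_rows)} masks to {FIXTURES / 'masks'}")
    print(f"wrote calibration, cooling, decay and assay tables to {RESULTS}")


if __name__ == "__main__":
    main()
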