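#!/usr/bin/env python
"""Evaluate the closed-form assay statistics on their published inputs.

Computes the formulation mass fractions, the per-group intratumoural H2S
reduction rates relative to the PBS control (from the fixed group table
written by 01_simulate.py), the apoptosis totals, and the haemolysis /
viability rates recovered from the simulated plates.
"""

from pathlib import Path

import pandas as pd

from endoquant import io
from endoquant.assays import (ApoptosisFractions, GroupConcentration,
                              ODReading, apoptosis_total, cell_viability,
                              hemolysis_rate, mass_fraction, reduction_rate,
                              round_sig)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    total_mg = 4.75
    co = round_sig(mass_fraction(0.8076, total_mg), 4)
    pep = round_sig(mass_fraction(0.152, total_mg), 3)
    print(f"formulation: cobalt {co}%  antimicrobial peptide {pep}%")

    groups = pd.read_csv(RESULTS / "h2s_groups.csv")
    conc = dict(zip(groups["group"], groups["concentration_mM"]))
    pbs = GroupConcentration("PBS", conc["PBS"])
    reductions = {}
    for name, c in conc.items():
        if name == "PBS":
            continue
        reductions[name] = round_sig(
            reduction_rate(pbs, GroupConcentration(name, c)), 3)
        print(f"H2S reduction {name} vs PBS: {reductions[name]}%")

    apop = pd.read_csv(RESULTS / "apoptosis.csv")
    totals = {}
    for _, row in apop.iterrows():
        t = apoptosis_total(ApoptosisFractions(row["early_pct"],
                                               row["late_pct"],
                                               row["necrosis_pct"]))
        totals[row["condition"]] = round_sig(t, 3)
        print(f"apoptosis total, {row['condition']}: {totals[row['condition']]}%")

    hemo = pd.read_csv(RESULTS / "hemolysis_plate.csv").set_index("role")["od"]
    via = pd.read_csv(RESULTS / "viability_plate.csv").set_index("role")["od"]
    h = hemolysis_rate(ODReading(hemo["sample"], hemo["negative"],
                                 hemo["positive"]))
    v = cell_viability(ODReading(via["sample"], via["negative"],
                                 via["positive"]))
    print(f"plate recovery: haemolysis {h:.1f}%  viability {v:.1f}%")

    io.write_json(RESULTS / "assay_statistics.json", {
        "cobalt_mass_fraction_pct": co,
        "peptide_mass_fraction_pct": pep,
        "h2s_reduction_pct": reductions,
        "apoptosis_total_pct": totals,
        "hemolysis_pct": h,
        "viability_pct": v,
    })


if __name__ == "__main__":
    main()
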