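#!/usr/bin/env python
"""Descriptive tables for the generated panels: item moments per wave,
scale totals, internal consistency (Cronbach's alpha with Feldt CI),
cut-off prevalence, and the attrition comparison.

Reads results/data/<group>.csv (run 01_simulate.py first); writes
results/descriptives/<group>_moments.csv and prints the summary block.
"""

from pathlib import Path

from panelgvar.descriptives import (
    attrition_comparison,
    cronbach_alpha,
    cutoff_prevalence,
    item_moments,
    scale_total,
)
from panelgvar.panel_data import ItemSchema, read_panel

ROOT = Path(__file__).resolve().parent.parent / "results"
CUTOFFS = {"mothers": 11, "fathers": 10}


def main() -> None:
    out = ROOT / "descriptives"
    out.mkdir(parents=True, exist_ok=True)
    schema = ItemSchema(tuple(f"EPDS{i}" for i in range(1, 11)), 4, ("T1", "T2", "T3"))
    for group, cutoff in CUTOFFS.items():
        ds = read_panel(ROOT / "data" / f"{group}.csv", schema, group=group)
        moments = item_moments(ds)
        moments.round(3).to_csv(out / f"{group}_moments.csv", index=False)
        print(f"== {group} (n={ds.n_persons}) ==")
        for t, lab in enumerate(schema.wave_labels):
            tot = scale_total(ds, t)
            a = cronbach_alpha(ds, t)
            count, pct = cutoff_prevalence(ds, t, cutoff)
            print(f"  {lab}: total {tot.mean:.2f} (SD {tot.sd:.2f}), "
                  f"alpha {a.alpha:.2f} [{a.ci_low:.2f}, {a.ci_high:.2f}], "
                  f">= {cutoff}: {count} ({pct:.2f}%)")
        tt = attrition_comparison(ds, 0, 2)
        print(f"  dropouts scored higher at T1: t({tt.df}) = {tt.t:.2f}, p = {tt.p:.3f}\n")


if __name__ == "__main__":
    main()
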