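#!/usr/bin/env python
"""Clinical performance of the reference screening year from published counts.

Pure arithmetic (no simulation): confusion-table metrics with Wilson CIs for
the SCID and T-cell-lymphopenia outcome definitions, stratified referral
rates, the exact-method SCID incidence interval, and the post hoc referral
cut-off sweep over the reconstructed referred-children table.

Writes results/reference_performance.json and results/reference_sweep.csv.
"""

import json
from pathlib import Path

import pandas as pd

from trecscreen.pipeline import reference_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = reference_report()
    OUT.mkdir(exist_ok=True)
    (OUT / "reference_performance.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame(report["cutoff_sweep"]).to_csv(OUT / "reference_sweep.csv", index=False)

    scid = report["confusion"]["SCID"]
    lym = report["confusion"]["T_cell_lymphopenia"]
    inc = report["incidence"]
    print("=== outcome: SCID ===")
    print(f"  PPV  {scid['ppv']['percent'][0]}% (95% CI {scid['ppv']['percent'][1]}-{scid['ppv']['percent'][2]})")
    print(f"  sensitivity {scid['sensitivity']['percent'][0]}% "
          f"(95% CI {scid['sensitivity']['percent'][1]}-{scid['sensitivity']['percent'][2]})")
    print(f"  NPV  {scid['npv']['percent'][0]}%")
    print("=== outcome: T cell lymphopenia ===")
    print(f"  PPV  {lym['ppv']['percent'][0]}% (95% CI {lym['ppv']['percent'][1]}-{lym['ppv']['percent'][2]})")
    print("=== referral rates ===")
    for name, r in report["referral_rates"].items():
        print(f"  {name:18s} {r['k']:>3d} / {r['n']:>7,d} = {100 * r['rate']:.3f}%")
    print("=== SCID incidence ===")
    print(f"  {inc['cases']} / {inc['denominator']:,} newborns = "
          f"1 in {inc['one_in']:,.0f} (95% CI 1 in {inc['one_in_lower']:,.0f} "
          f"to 1 in {inc['one_in_upper']:,.0f})")
    row4 = next(r for r in report["cutoff_sweep"] if r["cutoff"] == 4.0)
    print("=== cut-off 4.0 copies/well (post hoc) ===")
    print(f"  referred {row4['referred_total']} "
          f"({row4['referred_preterm']} preterm, {row4['referred_term']} term); "
          f"lymphopenia PPV {100 * row4['ppv_lymphopenia']:.1f}% "
          f"(95% CI {100 * row4['ppv_lymphopenia_lo']:.1f}-{100 * row4['ppv_lymphopenia_hi']:.1f}); "
          f"SCID sensitivity {100 * row4['sensitivity_scid']:.0f}%")


if __name__ == "__main__":
    main()
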