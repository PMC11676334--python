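#!/usr/bin/env python
"""Biodiesel fuel descriptors of the Dunaliella isolate from its FAME profile.

Computes the seven empirical descriptors from the packaged 11-component
composition (0.5 M NaCl), checks them against the EN14214 and ASTM D6751-02
standards, and cross-checks the published descriptor table for internal
consistency with the stated equations.

Writes results/biodiesel_properties.csv and results/biodiesel_compliance.csv.
"""

from pathlib import Path

import pandas as pd

from algatrait.biodiesel import (
    STANDARDS,
    check_compliance,
    evaluate_properties,
    flag_inconsistent_row,
)
from algatrait.datasets import (
    load_biodiesel_reference_table,
    load_reference_fame_profile,
)
from algatrait.fame import class_totals

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    profile = load_reference_fame_profile()
    totals = class_totals(profile)
    props = evaluate_properties(profile)

    print(f"Profile: {profile.label} ({len(profile)} components, "
          f"total {profile.total_percent:.2f}%)")
    print(f"  SFA {totals.sfa_percent:.2f}%  MUFA {totals.mufa_percent:.2f}%  "
          f"PUFA {totals.pufa_percent:.2f}%")
    for name, value in props.as_dict().items():
        print(f"  {name:>14}: {value:.2f}" if value is not None
              else f"  {name:>14}: not computable")

    row = {"source": profile.label, "sfa_percent": totals.sfa_percent,
           **props.as_dict()}
    pd.DataFrame([row]).round(2).to_csv(
        RESULTS / "biodiesel_properties.csv", index=False
    )

    rows = []
    for key, limits in STANDARDS.items():
        report = check_compliance(props, limits)
        for crit in report.criteria:
            rows.append(
                {"standard": crit.standard, "criterion": crit.criterion,
                 "value": crit.value, "bound": crit.bound,
                 "passed": crit.passed}
            )
            print(f"  {crit.standard:>14} {crit.criterion:>5} "
                  f"{'PASS' if crit.passed else 'FAIL'} "
                  f"({crit.value if crit.value is None else round(crit.value, 2)} "
                  f"vs {crit.bound})")
    pd.DataFrame(rows).to_csv(RESULTS / "biodiesel_compliance.csv", index=False)

    # internal-consistency audit of the published descriptor table
    table = load_biodiesel_reference_table()
    for source in ("Dunaliella salina DSTA20",
                   "Asterarcys quadricellulare AQYS21"):
        r = table.loc[source]
        flags = flag_inconsistent_row(
            {"sv": r["sv"], "iv": r["iv"], "cn": r["cn"],
             "lcsf": r["lcsf"], "cfpp": r["cfpp"]}
        )
        print(f"  published row {source}: {flags}")


if __name__ == "__main__":
    main()
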