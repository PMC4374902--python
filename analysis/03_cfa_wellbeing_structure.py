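#!/usr/bin/env python
"""Factor structure of the 14 MHC-SF items: 1- vs 2- vs 3-factor CFA.

Fits the three nested maximum-likelihood CFA models and runs the chi-square
difference tests that ask (a) whether hedonic and eudaimonic well-being carry
reliable unique variance (2 vs 1 factors) and (b) whether psychological and
social well-being separate within eudaimonia (3 vs 2 factors).
"""
from pathlib import Path

import pandas as pd

from ctra_wellbeing import io as cio
from ctra_wellbeing.cfa import fit_cfa_ml, mhcsf_cfa_specs, nested_chisq_test

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "study_data" / "confirmation"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    items = cio.read_items(DATA / "items.xlsx", instrument="MHC-SF")
    data = items.responses[list(items.item_map)].dropna()
    fits = {name: fit_cfa_ml(spec, data=data, seed=0)
            for name, spec in mhcsf_cfa_specs().items()}

    rows = [{"model": name, "T": f.statistic, "df": f.df, "loglik": f.loglik,
             "converged": f.converged, "heywood": f.heywood}
            for name, f in fits.items()]
    d21 = nested_chisq_test(fits["1-factor"], fits["2-factor"])
    d32 = nested_chisq_test(fits["2-factor"], fits["3-factor"])
    table = pd.DataFrame(rows).set_index("model").round(3)

    TABLES.mkdir(parents=True, exist_ok=True)
    table.to_csv(TABLES / "cfa_model_fits.csv")
    tests = pd.DataFrame(
        [{"comparison": "2-factor vs 1-factor", "delta_chisq": d21[0],
          "delta_df": d21[1], "p": d21[2]},
         {"comparison": "3-factor vs 2-factor", "delta_chisq": d32[0],
          "delta_df": d32[1], "p": d32[2]}]
    ).round(4)
    tests.to_csv(TABLES / "cfa_nested_tests.csv", index=False)

    print(table.to_string())
    print()
    print(tests.to_string(index=False))
    verdict = "supports" if d21[2] < 0.05 else "does not support"
    print(f"\nThe 2-factor model {verdict} distinct hedonic/eudaimonic factors "
          f"(dX2({d21[1]}) = {d21[0]:.2f}, p = {d21[2]:.2g}).")


if __name__ == "__main__":
    main()
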