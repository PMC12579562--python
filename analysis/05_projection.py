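#!/usr/bin/env python
"""Counterfactual organ-utilization projection.

How many additional grafts would survive at 5 years if the 184 dual
transplants of 2023 had each been performed as two single transplants?
Computed once from the published inputs (2023 volumes, matched-cohort
death-censored HR 0.73 with CI 0.58-0.93, single-graft survival
log-interpolated at 5 years), and optionally from this run's own fitted
survival tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from dualkidney import reference
from dualkidney.counterfactual_projection import (ProjectionInputs,
                                                  interpolate_survival,
                                                  project_dual_to_single)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cox", type=Path, default=Path("results/table5_cox.csv"),
                    help="this run's Cox table (used with --own-fit)")
    ap.add_argument("--survival-table", type=Path,
                    default=Path("results/table4_death_censored_graft.csv"))
    ap.add_argument("--own-fit", action="store_true",
                    help="also project from this run's fitted HR and survival")
    ap.add_argument("--out", type=Path, default=Path("results/projection.csv"))
    args = ap.parse_args()

    rows = []
    inputs = reference.reference_projection_inputs(horizon_years=5.0)
    res = project_dual_to_single(inputs)
    rows.append({"inputs": "published", **res.to_frame().iloc[0].to_dict()})
    print(f"published inputs: +{res.additional_transplants:.1f} "
          f"({res.additional_ci95[0]:.1f}-{res.additional_ci95[1]:.1f}) grafts "
          f"surviving at 5 years = {res.percent_increase:.2f}% "
          f"({res.percent_ci95[0]:.2f}-{res.percent_ci95[1]:.2f}) more "
          "successful transplants")

    if args.own_fit:
        cox = pd.read_csv(args.cox)
        row = cox[(cox.endpoint == "death_censored_graft")
                  & (cox.model == "multivariable")].iloc[0]
        tab = pd.read_csv(args.survival_table)
        table = dict(zip(tab["year"], tab["single_pct"] / 100.0))
        own = ProjectionInputs(
            n_single=reference.TRANSPLANT_VOLUMES_2023["single"],
            n_dual=reference.TRANSPLANT_VOLUMES_2023["dual"],
            hr_dual_vs_single=float(row["hr"]),
            hr_ci95=(float(row["ci_low"]), float(row["ci_high"])),
            horizon_years=5.0,
            single_survival_at_horizon=interpolate_survival(table, 5.0))
        res_own = project_dual_to_single(own)
        rows.append({"inputs": "own_fit", **res_own.to_frame().iloc[0].to_dict()})
        print(f"own fitted inputs (HR {own.hr_dual_vs_single:.3f}, "
              f"S(5) {own.single_survival_at_horizon:.3f}): "
              f"+{res_own.additional_transplants:.1f} grafts = "
              f"{res_own.percent_increase:.2f}%")

    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
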