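#!/usr/bin/env python
"""Survival differences across discovered and predicted subgroups.

Kaplan-Meier five-year survival per subgroup with a log-rank test in the
discovery cohort; a Cox model with the poor subgroup and dichotomised age at
diagnosis as covariates; and the same KM/log-rank validation on the
validation cohort's predicted subgroups (time origin: diagnosis).
"""

import argparse
from pathlib import Path

import pandas as pd

from endopheno import io as eio
from endopheno.survival import SurvivalData, cox_fit, km_estimate, logrank_test

FIVE_YEARS = 5 * 365.25


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out

    surv = eio.read_survival(out / "data" / "survival.csv")
    part = eio.read_partition(out / "partition.tsv")
    surv.data = surv.data.loc[part.labels.index]
    surv.data["group"] = part.labels
    stat, p = logrank_test(surv)
    print("discovery cohort (time from sampling):")
    rows = []
    for sg in sorted(part.labels.unique()):
        km = km_estimate(surv, sg)
        s5 = km.at(FIVE_YEARS)
        rows.append({"subgroup": sg, "n": int((part.labels == sg).sum()), "five_year_survival": round(s5, 3)})
        print(f"  subgroup {sg}: 5-year survival {100*s5:.1f}%")
    print(f"  log-rank chi2 = {stat:.1f}, p = {p:.2e}")
    pd.DataFrame(rows).to_csv(out / "km_five_year.tsv", sep="\t", index=False)

    clin = eio.read_clinical(out / "data" / "clinical.csv", out / "data" / "clinical_dictionary.json")
    age = clin.values.loc[part.labels.index, "age_diagnosis"].astype(float)
    cov = surv.data.copy()
    cov["poor_subgroup"] = (part.labels == 1).astype(int)
    cov["age_above_median"] = (age > age.median()).fillna(False).astype(int)
    fit = cox_fit(SurvivalData(cov[["time", "event", "poor_subgroup", "age_above_median"]]),
                  ["poor_subgroup", "age_above_median"])
    print("Cox model (poor subgroup + age>median):")
    print(fit.summary[["hr", "ci_lower", "ci_upper", "p"]].round(3).to_string())
    fit.summary.to_csv(out / "cox_summary.tsv", sep="\t")

    pred_path = out / "validation_predicted.tsv"
    if pred_path.exists():
        pred = pd.read_csv(pred_path, sep="\t", index_col=0)["predicted_subgroup"]
        vsurv = eio.read_survival(out / "data" / "validation_survival.csv")
        vsurv.data = vsurv.data.loc[pred.index]
        vsurv.data["group"] = pred
        vstat, vp = logrank_test(vsurv)
        print(f"validation cohort (predicted subgroups, time from {vsurv.time_origin}):")
        for sg in sorted(pred.unique()):
            km = km_estimate(vsurv, sg)
            print(f"  subgroup {sg}: 5-year survival {100*km.at(FIVE_YEARS):.1f}%")
        print(f"  log-rank chi2 = {vstat:.1f}, p = {vp:.2e}")


if __name__ == "__main__":
    main()
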