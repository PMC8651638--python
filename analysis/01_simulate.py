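#!/usr/bin/env python
"""Generate the synthetic discovery and validation cohorts.

Writes the expression matrix, gene annotation, clinical tables, survival and
genotype records, plus the planted ground truth, under results/data/.  The
discovery cohort has 330 patients in proportions 129:89:112
(poor:moderate:good prognosis); the validation cohort has 197 patients with
clinical and survival data only.
"""

import argparse
from pathlib import Path

from endopheno import CohortSpec, generate_cohort, generate_validation_cohort
from endopheno import io as eio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(seed=args.seed)
    expr, clin, surv, geno, truth, ann = generate_cohort(spec)
    eio.write_expression(expr, out / "expression.tsv")
    eio.write_annotation(ann, out / "annotation.tsv")
    eio.write_clinical(clin, out / "clinical.csv", out / "clinical_dictionary.json")
    eio.write_survival(surv, out / "survival.csv")
    eio.write_genotype(geno, out / "genotype.csv")
    eio.write_json(
        {
            "labels": truth.labels.to_dict(),
            "marker_genes": truth.marker_genes,
            "planted_hazards": truth.planted_hazards,
            "planted_genotype_freqs": truth.planted_genotype_freqs,
        },
        out / "truth.json",
    )
    vclin, vsurv, vtruth = generate_validation_cohort(spec, truth)
    eio.write_clinical(vclin, out / "validation_clinical.csv")
    eio.write_survival(vsurv, out / "validation_survival.csv")
    eio.write_json({"labels": vtruth.labels.to_dict()}, out / "validation_truth.json")

    sizes = truth.labels.value_counts().sort_index()
    print(f"discovery cohort: {expr.n_genes} genes x {expr.n_samples} patients")
    print(f"planted subgroup sizes (poor/moderate/good): {list(sizes)}")
    print(f"validation cohort: {len(vtruth.labels)} patients (clinical + survival only)")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
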