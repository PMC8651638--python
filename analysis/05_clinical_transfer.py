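#!/usr/bin/env python
"""Clinical signatures and transfer classification of the validation cohort.

Cleans the clinical table (5% missingness rule), imputes by chained
equations, searches per-subgroup clinical signatures (ensemble feature
selection, sizes s=1..s_max over SVM/RF/LR/kNN), pools them into a composite
multi-class classifier, and predicts subgroup membership for the independent
validation cohort.
"""

import argparse
import warnings
from pathlib import Path

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

from endopheno import io as eio
from endopheno.clinical import (
    classify_cohort,
    clean_clinical,
    fit_composite,
    impute_chained,
    signature_search,
)
from endopheno.pipeline import stage_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--s-max", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out

    clin = eio.read_clinical(out / "data" / "clinical.csv", out / "data" / "clinical_dictionary.json")
    part = eio.read_partition(out / "partition.tsv")
    seed = stage_seed(args.seed, "clin_sig")

    cleaned, report = clean_clinical(clin)
    print(f"cleaning: dropped {list(report['dropped'])} (>5% missing), kept {len(report['kept'])}")
    tables, _ = impute_chained(cleaned, n_imputations=5, n_iterations=10, seed=seed)

    sigs = []
    for sg in sorted(part.labels.unique()):
        sig = signature_search(tables[0], part, sg, sizes=range(1, args.s_max + 1), seed=seed)
        sigs.append(sig)
        print(f"subgroup {sg}: signature {sig.features} "
              f"(s={sig.size}, {sig.family}, CV balanced accuracy {sig.cv_performance:.3f})")

    comp = fit_composite(tables, part, sigs, seed=seed)
    print(f"composite signature ({len(comp.features)} features): {comp.features}")
    print(f"composite CV balanced accuracy: {comp.cv_balanced_accuracy:.3f}")

    vclin = eio.read_clinical(out / "data" / "validation_clinical.csv", out / "data" / "clinical_dictionary.json")
    vtabs, _ = impute_chained(vclin, 1, 10, seed=seed + 1)
    labels, probs = classify_cohort(comp, vtabs[0])
    labels.rename("predicted_subgroup").to_frame().to_csv(out / "validation_predicted.tsv", sep="\t")
    probs.to_csv(out / "validation_probabilities.tsv", sep="\t", index_label="sample_id")
    print(f"validation predictions: {labels.value_counts().sort_index().to_dict()}")

    truth_path = out / "data" / "validation_truth.json"
    disc_truth_path = out / "data" / "truth.json"
    if truth_path.exists() and disc_truth_path.exists():
        import json

        import pandas as pd
        from sklearn.metrics import balanced_accuracy_score

        # discovered cluster ids are size-canonical; map each to the planted
        # subgroup it mostly overlaps before comparing with validation truth
        disc_truth = pd.Series(json.loads(disc_truth_path.read_text())["labels"])
        mapping = {
            c: int(disc_truth.loc[part.labels.index[part.labels == c]].mode().iloc[0])
            for c in sorted(part.labels.unique())
        }
        vtruth = pd.Series(json.loads(truth_path.read_text())["labels"])
        mapped = labels.map(mapping)
        ba = balanced_accuracy_score(vtruth.loc[mapped.index], mapped)
        print(f"balanced accuracy vs planted validation labels: {ba:.3f}")


if __name__ == "__main__":
    main()
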