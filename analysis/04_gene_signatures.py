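#!/usr/bin/env python
"""Gene signatures of the discovered subgroups.

Fits one-vs-rest LASSO models on the 300 most variable genes, reports the
top-coefficient signature per subgroup, computes raw-scale fold changes
between the poor- and good-prognosis subgroups, and tests the
immunoglobulin-like block for the low/intermediate/high ordering.
"""

import argparse
import json
from pathlib import Path

from endopheno import io as eio
from endopheno.gene_signatures import (
    fold_changes,
    lasso_signatures,
    signature_expression_summary,
)
from endopheno.pipeline import stage_seed
from endopheno.preprocess import rank_genes_by_variability


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out

    m = eio.read_expression(out / "expression_arcsinh.tsv", transform_state="arcsinh")
    raw = eio.read_expression(out / "data" / "expression.tsv")
    part = eio.read_partition(out / "partition.tsv")
    seed = stage_seed(args.seed, "gene_sig")

    _, (g300,) = rank_genes_by_variability(m, sizes=[300])
    sig = lasso_signatures(m.subset_genes(g300), part, seed=seed)
    eio.write_gene_signature(sig, out / "gene_signature.tsv")
    for sg in sorted(sig.top_sets):
        print(f"subgroup {sg}: {len(sig.coefficients[sg])} nonzero genes; "
              f"top set {sig.top_sets[sg][:6]}{'...' if len(sig.top_sets[sg]) > 6 else ''}")

    union = sorted({g for s in sig.top_sets.values() for g in s})
    fc = fold_changes(raw.subset_genes(union), part, union, 1, 2)
    fc.table.sort_values("log2fc").to_csv(out / "fold_changes.tsv", sep="\t")
    n_sig = int((fc.table["p_adj"] < 0.05).sum())
    print(f"\nfold changes subgroup 1 vs 2 on {len(union)} signature genes: "
          f"{n_sig} significant after Bonferroni")

    truth_path = out / "data" / "truth.json"
    if truth_path.exists():
        ig = json.loads(truth_path.read_text())["marker_genes"]["immunoglobulin"]
        summary = signature_expression_summary(raw, part, ig)
        med = {sg: round(v["median"], 2) for sg, v in summary["per_subgroup"].items()}
        print(f"immunoglobulin-block medians per subgroup: {med} "
              f"(ordering trend p = {summary['trend_p']:.2e})")


if __name__ == "__main__":
    main()
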