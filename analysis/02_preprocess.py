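#!/usr/bin/env python
"""Prepare the expression matrix for clustering.

Applies the abundance filter (>2 TPM in at least 95% of samples), removes
sex-chromosome genes (the dominant nuisance variation in whole blood), and
arcsinh-transforms the surviving matrix.
"""

import argparse
from pathlib import Path

from endopheno import arcsinh_transform, filter_low_expression, remove_sex_genes
from endopheno import io as eio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = eio.read_expression(args.data / "expression.tsv")
    ann = eio.read_annotation(args.data / "annotation.tsv")
    n0 = expr.n_genes
    expr = filter_low_expression(expr)
    n1 = expr.n_genes
    expr = remove_sex_genes(expr, ann)
    n2 = expr.n_genes
    expr = arcsinh_transform(expr)
    args.out.mkdir(parents=True, exist_ok=True)
    eio.write_expression(expr, args.out / "expression_arcsinh.tsv")
    eio.write_json(
        {"genes_input": n0, "after_expression_filter": n1, "after_sex_removal": n2},
        args.out / "preprocess_report.json",
    )
    print(f"{n0} genes -> {n1} after abundance filter -> {n2} after sex-gene removal")
    print(f"arcsinh matrix written to {args.out/'expression_arcsinh.tsv'}")


if __name__ == "__main__":
    main()
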