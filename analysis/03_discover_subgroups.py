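#!/usr/bin/env python
"""Unsupervised subgroup discovery.

Ranks genes by variance, sizes the clustering gene set by bootstrap
stability, votes the number of subgroups with the internal-index ensemble,
and writes the final spectral partition.  If planted truth is available the
adjusted Rand index against it is reported.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from endopheno import io as eio
from endopheno.discovery import adjusted_rand_index, compare_algorithms
from endopheno.pipeline import discover_subgroups, stage_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out

    m = eio.read_expression(out / "expression_arcsinh.tsv", transform_state="arcsinh")
    seed = stage_seed(args.seed, "discover")

    consistency = compare_algorithms(m, 3)
    consistency.to_csv(out / "algorithm_consistency.tsv", sep="\t")
    winner = consistency[consistency["winner"]].index[0]
    print("partitional consistency (mean pairwise ARI across variations):")
    print(consistency[["mean_ari", "sd_ari"]].round(3).to_string())
    print(f"most consistent algorithm: {winner}")

    part, vote, stab, genes = discover_subgroups(
        m, sizes=[50, 100, 300, 600], ks=range(2, 9), n_boot=20, seed=seed
    )
    eio.write_partition(part, out / "partition.tsv")
    eio.write_json(
        {"chosen_size": stab.chosen_size, "per_size": stab.per_size}, out / "stability.json"
    )
    eio.write_json(
        {"votes": vote.votes, "tally": {str(k): v for k, v in vote.tally.items()}},
        out / "kvote.json",
    )
    print(f"\nindex votes: {vote.votes}")
    print(f"voted number of subgroups: k = {vote.majority_k}")
    print(f"most stable gene-set size: {stab.chosen_size} "
          f"(mean bootstrap Jaccard {stab.per_size[stab.chosen_size]['mean']:.3f})")
    print(f"subgroup sizes: {part.labels.value_counts().sort_index().to_dict()}")

    truth_path = out / "data" / "truth.json"
    if truth_path.exists():
        truth = pd.Series(json.loads(truth_path.read_text())["labels"])
        ari = adjusted_rand_index(
            part.labels.loc[truth.index].to_numpy(), truth.to_numpy()
        )
        print(f"ARI against planted labels: {ari:.3f}")


if __name__ == "__main__":
    main()
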