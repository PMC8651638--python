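"""Readers and writers for the pipeline's on-disk formats.

Dialect: tab-separated matrices, UTF-8, "." decimal, "NA" as the missing
token.  Every reader validates ids (no duplicates, no ragged rows) and each
write/read pair round-trips exactly for valid files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .discovery import Partition
from .preprocess import ExpressionMatrix, GeneAnnotation
from .survival import SurvivalData

NA = "NA"


# -- expression -------------------------------------------------------------


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", na_rep=NA)


def read_expression(path, transform_state: str = "raw") -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=[NA])
    except pd.errors.ParserError as e:
        raise ValueError(f"cannot parse expression file {path}: {e}") from e
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    return ExpressionMatrix(df, transform_state)


# -- gene annotation --------------------------------------------------------


def write_annotation(a: GeneAnnotation, path) -> None:
    pd.DataFrame({"gene_id": list(a.chromosome), "chromosome": list(a.chromosome.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(chromosome=dict(zip(df["gene_id"], df["chromosome"])))


def read_transcript_map(path) -> GeneAnnotation:
    """Two-column TSV: transcript_id <tab> gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"])
    if df["transcript_id"].duplicated().any():
        raise ValueError(f"duplicate transcript ids in {path}")
    return GeneAnnotation(transcript_to_gene=dict(zip(df["transcript_id"], df["gene_id"])))


# -- clinical ---------------------------------------------------------------


def write_clinical(t: ClinicalTable, path, dictionary_path=None) -> None:
    t.values.to_csv(path, index_label="sample_id", na_rep=NA)
    if dictionary_path is not None:
        payload = {"dictionary": t.dictionary, "levels": {k: list(v) for k, v in t.levels.items()}}
        Path(dictionary_path).write_text(json.dumps(payload, indent=1, default=str))


def read_clinical(path, dictionary_path) -> ClinicalTable:
    df = pd.read_csv(path, index_col="sample_id", na_values=[NA])
    meta = json.loads(Path(dictionary_path).read_text())
    dictionary = meta["dictionary"]
    undeclared = [c for c in df.columns if c not in dictionary]
    if undeclared:
        raise ValueError(f"clinical features not in dictionary: {undeclared}")
    levels = meta.get("levels", {})
    # restore numeric level types where applicable (JSON stringifies keys only)
    return ClinicalTable(df, dictionary, {k: list(v) for k, v in levels.items()})


# -- survival / genotype ----------------------------------------------------


def write_survival(d: SurvivalData, path) -> None:
    out = d.data.copy()
    out.insert(0, "time_origin", d.time_origin)
    out.to_csv(path, index_label="sample_id", na_rep=NA)


def read_survival(path) -> SurvivalData:
    df = pd.read_csv(path, index_col="sample_id", na_values=[NA])
    origin = df["time_origin"].iloc[0] if "time_origin" in df else "sampling"
    return SurvivalData(df.drop(columns=["time_origin"], errors="ignore"), time_origin=origin)


def write_genotype(g: pd.DataFrame, path) -> None:
    g.to_csv(path, index_label="sample_id", na_rep=NA)


def read_genotype(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id", na_values=[NA])


# -- partition --------------------------------------------------------------


def write_partition(p: Partition, path) -> None:
    pd.DataFrame({"sample_id": p.labels.index, "subgroup": p.labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    labels = df["subgroup"].to_numpy()
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
        warnings.warn(f"non-contiguous subgroup labels in {path}; canonicalising")
    return Partition.from_labels(labels, df["sample_id"].tolist(), provenance={"source": str(path)})


# -- signatures / network / reports ----------------------------------------


def write_gene_signature(sig, path) -> None:
    rows = []
    for sg, coefs in sig.coefficients.items():
        top = set(sig.top_sets.get(sg, []))
        for g, c in sorted(coefs.items(), key=lambda kv: -abs(kv[1])):
            rows.append({"subgroup": sg, "gene": g, "coefficient": c, "in_top_set": g in top})
    pd.DataFrame(rows, columns=["subgroup", "gene", "coefficient", "in_top_set"]).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(net, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_graph(), path)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
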