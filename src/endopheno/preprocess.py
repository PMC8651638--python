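"""Expression-matrix preparation for whole-blood RNA-seq clustering.

The clustering substrate is a gene x sample TPM matrix.  Preparation follows
four steps: transcript-to-gene aggregation, a low-expression filter (value > 2
in at least 95% of samples), removal of sex-chromosome genes (plus an optional
user-supplied exclusion list) to avoid clustering on sex, and an inverse
hyperbolic sine transform that behaves like log at high abundance while
remaining defined at zero.  Candidate gene sets for clustering are nested
prefixes of the variance ranking computed on the transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "aggregate_transcripts",
    "filter_low_expression",
    "remove_sex_genes",
    "arcsinh_transform",
    "rank_genes_by_variability",
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples.  Non-negative, no NaN.
    transform_state : str
        ``"raw"`` (TPM-like) or ``"arcsinh"``.
    """

    values: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw", "arcsinh"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains NaN/inf")
        if self.transform_state == "raw" and arr.size and (arr < 0).any():
            raise ValueError("raw expression matrix contains negative values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]} ...")
        return ExpressionMatrix(self.values.loc[genes], self.transform_state)


@dataclass
class GeneAnnotation:
    """Gene -> chromosome labels plus an optional transcript -> gene map."""

    chromosome: dict[str, str] = field(default_factory=dict)
    transcript_to_gene: dict[str, str] = field(default_factory=dict)

    def sex_genes(self, gene_ids) -> list[str]:
        return [g for g in gene_ids if self.chromosome.get(g) in SEX_CHROMOSOMES]


def aggregate_transcripts(tx_matrix: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Sum transcript-level TPM into gene-level TPM.

    Every transcript row must be mapped; column (per-sample) totals are
    preserved exactly because aggregation is a pure regrouping.
    """
    tx2g = annotation.transcript_to_gene
    if not tx2g:
        raise ValueError("empty transcript-to-gene map")
    unmapped = [t for t in tx_matrix.values.index if t not in tx2g]
    if unmapped:
        raise KeyError(f"unmapped transcripts: {unmapped[:10]}")
    gene_of = tx_matrix.values.index.map(tx2g)
    agg = tx_matrix.values.groupby(gene_of, sort=False).sum()
    agg.index.name = tx_matrix.values.index.name
    return ExpressionMatrix(agg, tx_matrix.transform_state)


def filter_low_expression(
    m: ExpressionMatrix, min_reads: float = 2.0, min_fraction: float = 0.95
) -> ExpressionMatrix:
    """Keep genes with abundance > ``min_reads`` in >= ceil(min_fraction * n) samples."""
    if m.transform_state != "raw":
        raise ValueError("low-expression filter applies to the raw-scale matrix")
    need = int(np.ceil(min_fraction * m.n_samples))
    keep = (m.values.to_numpy() > min_reads).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("all genes fail the expression filter")
    return ExpressionMatrix(m.values.loc[keep], m.transform_state)


def remove_sex_genes(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    extra_exclusions: list[str] | None = None,
) -> ExpressionMatrix:
    """Drop chrX/chrY genes and any extra listed gene ids.

    Sex chromosomes dominate the variance of whole-blood expression and would
    otherwise drive clustering toward a male/female split.
    """
    drop = set(annotation.sex_genes(m.gene_ids))
    drop.update(extra_exclusions or [])
    keep = [g for g in m.gene_ids if g not in drop]
    return ExpressionMatrix(m.values.loc[keep], m.transform_state)


def arcsinh_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise asinh(x) = ln(x + sqrt(x^2 + 1)); variance-damping, 0 -> 0."""
    if m.transform_state == "arcsinh":
        raise ValueError("matrix already arcsinh-transformed")
    return ExpressionMatrix(np.arcsinh(m.values), "arcsinh")


def rank_genes_by_variability(m: ExpressionMatrix, sizes: list[int] | None = None):
    """Rank genes by descending across-sample variance (n-1 denominator).

    Returns ``(ranked_gene_ids, nested_sets)`` where ``nested_sets`` holds one
    prefix list per requested size.  Variance ties keep matrix order (stable
    sort) so the ranking is deterministic.
    """
    if m.transform_state != "arcsinh":
        raise ValueError("variance ranking expects the arcsinh-transformed matrix")
    var = m.values.var(axis=1, ddof=1)
    order = np.argsort(-var.to_numpy(), kind="stable")
    ranked = [m.gene_ids[i] for i in order]
    sets = []
    for s in sizes or []:
        if s > len(ranked):
            raise ValueError(f"requested gene-set size {s} > {len(ranked)} genes")
        sets.append(ranked[:s])
    return ranked, sets
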