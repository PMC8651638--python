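"""Gene-clinical correlation network and qPCR confirmation arithmetic.

The network layer relates signature genes to signature clinical variables by
Spearman rank correlation over samples observed in both tables, keeping only
edges with |rho| >= 0.25 and two-tailed p < 1.11e-5 (a Bonferroni-style
cutoff treated here as a plain configurable threshold).  Concordance between
two networks is the fraction of shared pairs whose correlations agree in
sign.

The qPCR layer implements relative quantification against a reference assay
(GAPDH-like): dCt = Ct_target - Ct_ref, ddCt relative to the calibrator
group's mean dCt, RQ = 2^(-ddCt); group contrasts are reported as the log2
fold ratio of -dCt means with a Welch t-test, as in the validation-cohort
confirmation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import ClinicalTable
from .preprocess import ExpressionMatrix

__all__ = [
    "CorrelationNetwork",
    "QPCRTable",
    "spearman_with_p",
    "build_network",
    "correlation_concordance",
    "delta_delta_ct",
    "qpcr_group_comparison",
]


@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame  # columns: gene, feature, rho, p
    rho_min: float = 0.25
    p_max: float = 1.11e-5
    tested_pairs: int = 0
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.edges.empty:
            if (self.edges["rho"].abs() > 1 + 1e-12).any():
                raise ValueError("|rho| > 1 in network edges")
            ok = (self.edges["rho"].abs() >= self.rho_min) & (self.edges["p"] < self.p_max)
            if not ok.all():
                raise ValueError("stored edge violates thresholds")

    def pair_index(self) -> pd.DataFrame:
        return self.edges.set_index(["gene", "feature"])

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for _, r in self.edges.iterrows():
            g.add_node(r["gene"], kind="gene")
            g.add_node(r["feature"], kind="clinical")
            g.add_edge(r["gene"], r["feature"], rho=float(r["rho"]), p=float(r["p"]))
        return g


@dataclass
class QPCRTable:
    """Sample x assay Ct values (duplicates already averaged on the Ct scale)."""

    ct: pd.DataFrame
    reference_assay: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.reference_assay not in self.ct.columns:
            raise ValueError(f"reference assay {self.reference_assay!r} absent")
        if self.ct[self.reference_assay].isna().any():
            raise ValueError("missing reference Ct for some samples")
        if (self.ct.to_numpy(dtype=float) <= 0).any():
            raise ValueError("Ct values must be positive")


def spearman_with_p(x, y, seed: int = 0, exact_n: int = 12) -> tuple[float, float]:
    """Spearman rho with a two-tailed p value.

    Uses the t approximation for n >= ``exact_n``; below that, a permutation
    p (exhaustive when n! is small, otherwise 20000 seeded resamples), since
    the approximation is unreliable in tiny samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant variable: Spearman undefined")
    rho = stats.spearmanr(x, y).statistic
    if n >= exact_n:
        p = stats.spearmanr(x, y).pvalue
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    if math.factorial(n) <= 50000:
        count = total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return float(rho), count / total
    rng = np.random.default_rng(seed)
    count = 0
    n_res = 20000
    for _ in range(n_res):
        r = abs(np.corrcoef(rx, rng.permutation(ry))[0, 1])
        count += r >= obs - 1e-12
    return float(rho), (count + 1) / (n_res + 1)


def build_network(
    m: ExpressionMatrix,
    t: ClinicalTable,
    genes: list[str],
    features: list[str],
    rho_min: float = 0.25,
    p_max: float = 1.11e-5,
) -> CorrelationNetwork:
    """Bipartite gene-clinical Spearman network thresholded on |rho| and p.

    Pairs with a constant variable are skipped with a record; missing
    clinical values drop samples pairwise.
    """
    import warnings

    shared = [s for s in m.sample_ids if s in t.values.index]
    if len(shared) < 10:
        raise ValueError("need >= 10 overlapping samples")
    edges, skipped = [], []
    tested = 0
    for g in genes:
        gv = m.values.loc[g, shared]
        for f in features:
            fv = pd.to_numeric(t.values.loc[shared, f], errors="coerce")
            ok = fv.notna()
            xg, xf = gv[ok].to_numpy(dtype=float), fv[ok].to_numpy(dtype=float)
            tested += 1
            if np.unique(xg).size < 2 or np.unique(xf).size < 2 or ok.sum() < 4:
                skipped.append((g, f))
                warnings.warn(f"skipping constant/degenerate pair ({g}, {f})")
                continue
            rho, p = spearman_with_p(xg, xf)
            if abs(rho) >= rho_min and p < p_max:
                edges.append({"gene": g, "feature": f, "rho": rho, "p": p})
    edf = pd.DataFrame(edges, columns=["gene", "feature", "rho", "p"])
    return CorrelationNetwork(edges=edf, rho_min=rho_min, p_max=p_max, tested_pairs=tested, skipped=skipped)


def correlation_concordance(net_a: CorrelationNetwork, net_b: CorrelationNetwork, strict: bool = False) -> float:
    """Fraction of shared pairs whose rho signs agree.

    ``strict=True`` restricts to pairs past both networks' thresholds (they
    are by construction); otherwise any pair present in both edge lists
    counts.
    """
    a = net_a.pair_index()
    b = net_b.pair_index()
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no overlapping pairs between networks")
    sa = np.sign(a.loc[shared, "rho"].to_numpy())
    sb = np.sign(b.loc[shared, "rho"].to_numpy())
    return float((sa == sb).mean())


def delta_delta_ct(q: QPCRTable, calibrator_group) -> pd.DataFrame:
    """Relative quantity per sample and assay by the ddCt method.

    dCt = Ct_target - Ct_reference; ddCt = dCt - mean dCt of the calibrator
    group; RQ = 2^(-ddCt).  The calibrator group's geometric-mean RQ is 1 by
    construction.
    """
    assays = [c for c in q.ct.columns if c != q.reference_assay]
    dct = q.ct[assays].sub(q.ct[q.reference_assay], axis=0)
    cal = q.groups == calibrator_group
    if not cal.any():
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    ddct = dct.sub(dct[cal].mean(axis=0), axis=1)
    return 2.0 ** (-ddct)


def qpcr_group_comparison(q: QPCRTable, group_a, group_b) -> pd.DataFrame:
    """Per-assay log2 fold ratio between groups with Welch t-test p.

    The fold ratio is the difference of group means of -dCt (equivalently the
    log2 ratio of RQ geometric means, since one PCR cycle is one doubling).
    """
    assays = [c for c in q.ct.columns if c != q.reference_assay]
    dct = q.ct[assays].sub(q.ct[q.reference_assay], axis=0)
    neg = -dct
    ia = q.groups == group_a
    ib = q.groups == group_b
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for a in assays:
        va = neg.loc[ia, a].to_numpy(dtype=float)
        vb = neg.loc[ib, a].to_numpy(dtype=float)
        t = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"assay": a, "log2_fold_ratio": float(va.mean() - vb.mean()), "p": float(t.pvalue)})
    return pd.DataFrame(rows).set_index("assay")
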