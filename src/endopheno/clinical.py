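"""Clinical-feature pipeline: cleaning, imputation, signatures, transfer.

The clinical arm mirrors the supervised half of the study design: features
with more than 5% missingness are dropped and the rest numerically encoded;
residual missingness is filled by chained-equation multiple imputation
(predictive mean matching for numeric features, logistic draws for binary,
multinomial for unordered categoricals, proportional-odds draws for ordered
factors); per-subgroup clinical signatures are found by ensemble feature
selection followed by a signature-size search s = 1..20 over four classifier
families (SVM, random forest, logistic regression, kNN); the per-subgroup
signatures are pooled into a composite multi-class classifier used to
transfer the subgroup definitions onto an independent cohort in which no
transcriptome was measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .discovery import Partition

__all__ = [
    "ClinicalTable",
    "ClinicalSignature",
    "CompositeClassifier",
    "clean_clinical",
    "impute_chained",
    "ensemble_select",
    "signature_search",
    "fit_composite",
    "classify_cohort",
]

KINDS = ("numeric", "binary", "categorical", "ordered")


@dataclass
class ClinicalTable:
    """Sample x feature table with a data dictionary.

    ``values``: DataFrame (NaN = missing).  ``dictionary``: feature -> kind in
    {numeric, binary, categorical, ordered}.  ``levels``: enumerated levels
    for binary/categorical/ordered features (fixed, so encodings agree
    between cohorts).
    """

    values: pd.DataFrame
    dictionary: dict[str, str]
    levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        undeclared = [c for c in self.values.columns if c not in self.dictionary]
        if undeclared:
            raise ValueError(f"features missing from dictionary: {undeclared}")
        bad = {f: k for f, k in self.dictionary.items() if k not in KINDS}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")
        for f, k in self.dictionary.items():
            if k in ("binary", "categorical", "ordered") and f in self.values.columns:
                if f not in self.levels:
                    obs = self.values[f].dropna().unique().tolist()
                    self.levels[f] = sorted(obs)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean()

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.values.copy(), dict(self.dictionary), {k: list(v) for k, v in self.levels.items()})


# ---------------------------------------------------------------------------
# cleaning and encoding


def encode_table(t: ClinicalTable) -> pd.DataFrame:
    """Numeric encoding with a fixed scheme: binary -> {0,1} by level order,
    ordered -> integer ranks, categorical -> one-hot columns ``feat=level``.
    Level sets come from the dictionary so two cohorts encode identically."""
    cols = {}
    for f in t.values.columns:
        kind = t.dictionary[f]
        col = t.values[f]
        if kind == "numeric":
            cols[f] = col.astype(float)
        elif kind == "binary":
            lv = t.levels[f]
            if len(lv) > 2:
                raise ValueError(f"binary feature {f!r} has levels {lv}")
            mapping = {lv[0]: 0.0, lv[-1]: 1.0}
            cols[f] = col.map(mapping).astype(float)
        elif kind == "ordered":
            mapping = {l: float(i) for i, l in enumerate(t.levels[f])}
            cols[f] = col.map(mapping).astype(float)
        else:  # categorical one-hot
            for lv in t.levels[f]:
                cols[f"{f}={lv}"] = (col == lv).astype(float).where(col.notna())
    return pd.DataFrame(cols, index=t.values.index)


def clean_clinical(t: ClinicalTable, max_missing: float = 0.05):
    """Drop features with missing fraction > ``max_missing``; keep the rest.

    Returns ``(cleaned_table, report)`` where the report lists dropped
    features with their missing fractions.  Encoding is deferred to
    :func:`encode_table` so imputation can respect feature kinds.
    """
    frac = t.missing_fraction()
    dropped = frac[frac > max_missing]
    kept = [c for c in t.values.columns if c not in dropped.index]
    if not kept:
        raise ValueError("all clinical features exceed the missingness threshold")
    out = ClinicalTable(
        t.values[kept].copy(),
        {f: t.dictionary[f] for f in kept},
        {f: t.levels[f] for f in kept if f in t.levels},
    )
    report = {
        "dropped": {f: float(dropped[f]) for f in dropped.index},
        "kept": kept,
        "max_missing": max_missing,
    }
    return out, report


# ---------------------------------------------------------------------------
# chained-equation imputation


def _pmm_draw(y_obs, pred_obs, pred_mis, rng, donors: int = 5):
    """Predictive mean matching: each missing case borrows the observed value
    of one of the `donors` cases with the closest predicted mean."""
    out = np.empty(len(pred_mis))
    y_obs = np.asarray(y_obs, dtype=float)
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        pool = np.argsort(d, kind="stable")[: min(donors, len(d))]
        out[i] = y_obs[rng.choice(pool)]
    return out


def _predictors(encoded: pd.DataFrame, exclude_feature: str, t: ClinicalTable) -> pd.DataFrame:
    drop = [c for c in encoded.columns if c == exclude_feature or c.startswith(exclude_feature + "=")]
    x = encoded.drop(columns=drop)
    # guard against constant columns breaking solvers
    keep = x.columns[x.std(ddof=0) > 0]
    return x[keep]


def _impute_once(t: ClinicalTable, n_iterations: int, rng, donors: int, trace: list) -> ClinicalTable:
    work = t.copy()
    miss_cols = [f for f in work.values.columns if work.values[f].isna().any()]
    # initial fill: random draws from the observed margin
    for f in miss_cols:
        obs = work.values[f].dropna().to_numpy()
        if obs.size == 0:
            raise ValueError(f"feature {f!r} has no observed values")
        mis = work.values[f].isna()
        work.values.loc[mis, f] = rng.choice(obs, size=int(mis.sum()))
    # visit in order of increasing missingness (monotone-style sequence)
    miss_cols = sorted(miss_cols, key=lambda f: t.values[f].isna().mean())
    mask = {f: t.values[f].isna() for f in miss_cols}
    for _ in range(n_iterations):
        for f in miss_cols:
            kind = work.dictionary[f]
            enc = encode_table(work)
            x = _predictors(enc, f, work)
            obs_idx, mis_idx = ~mask[f], mask[f]
            x_obs, x_mis = x[obs_idx.to_numpy()], x[mis_idx.to_numpy()]
            y_obs = t.values.loc[obs_idx, f]
            if kind == "numeric":
                beta, *_ = np.linalg.lstsq(
                    np.c_[np.ones(len(x_obs)), x_obs.to_numpy()], y_obs.to_numpy(dtype=float), rcond=None
                )
                pred_obs = np.c_[np.ones(len(x_obs)), x_obs.to_numpy()] @ beta
                pred_mis = np.c_[np.ones(len(x_mis)), x_mis.to_numpy()] @ beta
                work.values.loc[mis_idx, f] = _pmm_draw(y_obs, pred_obs, pred_mis, rng, donors)
            else:
                levels = work.levels[f]
                y_codes = y_obs.map({l: i for i, l in enumerate(levels)}).to_numpy()
                probs = _categorical_probs(kind, x_obs.to_numpy(), y_codes, x_mis.to_numpy(), len(levels), rng)
                draws = [levels[_draw_category(p, rng)] for p in probs]
                if draws and not isinstance(levels[0], str) and work.values[f].dtype == object:
                    work.values[f] = work.values[f].astype(float)
                work.values.loc[mis_idx, f] = draws
        enc = encode_table(work)
        trace.append({f: float(enc[c].mean()) for f in miss_cols for c in enc.columns if c == f or c.startswith(f + "=")})
    return work


def _draw_category(p, rng):
    p = np.clip(p, 0, None)
    s = p.sum()
    p = p / s if s > 0 else np.full_like(p, 1.0 / len(p))
    return int(rng.choice(len(p), p=p))


def _categorical_probs(kind, x_obs, y_codes, x_mis, n_levels, rng):
    """Predicted level probabilities for binary / multinomial / ordered models."""
    present = np.unique(y_codes)
    if len(present) == 1:  # degenerate: only one level observed
        p = np.zeros(n_levels)
        p[int(present[0])] = 1.0
        return np.tile(p, (len(x_mis), 1))
    if kind == "ordered":
        try:
            from statsmodels.miscmodels.ordinal_model import OrderedModel

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = OrderedModel(y_codes, x_obs, distr="logit")
                res = mod.fit(method="bfgs", disp=False, maxiter=100)
                pr = res.model.predict(res.params, exog=x_mis)
            full = np.zeros((len(x_mis), n_levels))
            for j, lev in enumerate(np.sort(present)):
                full[:, int(lev)] = pr[:, j]
            return full
        except Exception:
            pass  # fall through to multinomial
    lr = LogisticRegression(max_iter=500, random_state=int(rng.integers(2**31 - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(x_obs, y_codes)
    pr = lr.predict_proba(x_mis)
    full = np.zeros((len(x_mis), n_levels))
    for j, lev in enumerate(lr.classes_):
        full[:, int(lev)] = pr[:, j]
    return full


def impute_chained(
    t: ClinicalTable,
    n_imputations: int = 10,
    n_iterations: int = 10,
    seed: int = 0,
    donors: int = 5,
):
    """Multiple imputation by chained equations.

    Returns ``(tables, traces)``: ``n_imputations`` completed copies plus the
    per-iteration mean trace of each imputed feature (convergence record).
    With no missing data every copy equals the input.
    """
    frac = t.missing_fraction()
    too_missing = frac[frac >= 0.5]
    if not too_missing.empty:
        raise ValueError(f"features with >= 50% missingness: {list(too_missing.index)}")
    if not t.values.isna().any().any():
        return [t.copy() for _ in range(n_imputations)], []
    root = np.random.default_rng(seed)
    tables, traces = [], []
    for _ in range(n_imputations):
        trace: list = []
        rng = np.random.default_rng(root.integers(2**31 - 1))
        tables.append(_impute_once(t, n_iterations, rng, donors, trace))
        traces.append(trace)
    return tables, traces


# ---------------------------------------------------------------------------
# signatures and transfer classification


@dataclass
class ClinicalSignature:
    subgroup: int
    features: list[str]
    coefficients: dict[str, float]
    size: int
    family: str
    cv_performance: float
    search_table: pd.DataFrame | None = None


@dataclass
class CompositeClassifier:
    features: list[str]
    scalers: list
    models: list
    classes: np.ndarray
    cv_confusion: np.ndarray | None = None
    cv_balanced_accuracy: float | None = None
    metadata: dict = field(default_factory=dict)


def _encoded_complete(t: ClinicalTable) -> pd.DataFrame:
    enc = encode_table(t)
    if enc.isna().any().any():
        raise ValueError("table has residual missingness; impute first")
    return enc


def _default_families(seed: int, rf_trees: int = 100) -> dict:
    return {
        "svm": SVC(kernel="linear", C=1.0, probability=False, random_state=seed),
        "rf": RandomForestClassifier(n_estimators=rf_trees, random_state=seed),
        "lr": LogisticRegression(max_iter=1000, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
    }


def ensemble_select(
    t: ClinicalTable,
    p: Partition,
    subgroup: int,
    seed: int = 0,
    methods: tuple = ("univariate", "l1_logistic", "rf_permutation"),
) -> pd.DataFrame:
    """Rank encoded features for one-vs-rest discrimination of a subgroup.

    Three selectors by default: absolute Welch-t effect size, |coef| of an
    L1 logistic model on standardised features, and permutation importance of
    a random forest.  Rankings are aggregated by mean rank; ties broken by
    the univariate rank.
    """
    if len(methods) < 2:
        raise ValueError("ensemble selection needs >= 2 selectors")
    if subgroup not in set(p.labels.unique()):
        raise ValueError(f"subgroup {subgroup} absent from partition")
    enc = _encoded_complete(t).loc[p.labels.index]
    y = (p.labels == subgroup).to_numpy().astype(int)
    x = enc.to_numpy()
    xs = StandardScaler().fit_transform(x)
    ranks = {}
    if "univariate" in methods:
        tstat = np.array(
            [np.abs(stats.ttest_ind(col[y == 1], col[y == 0], equal_var=False).statistic) for col in x.T]
        )
        tstat = np.nan_to_num(tstat)
        ranks["univariate"] = stats.rankdata(-tstat, method="average")
    if "l1_logistic" in methods:
        lr = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed)
        lr.fit(xs, y)
        ranks["l1_logistic"] = stats.rankdata(-np.abs(lr.coef_[0]), method="average")
    if "rf_permutation" in methods:
        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        rf.fit(x, y)
        imp = permutation_importance(rf, x, y, n_repeats=5, random_state=seed)
        ranks["rf_permutation"] = stats.rankdata(-imp.importances_mean, method="average")
    rank_df = pd.DataFrame(ranks, index=enc.columns)
    rank_df["mean_rank"] = rank_df.mean(axis=1)
    tie_key = rank_df["univariate"] if "univariate" in rank_df else rank_df["mean_rank"]
    order = np.lexsort((tie_key.to_numpy(), rank_df["mean_rank"].to_numpy()))
    return rank_df.iloc[order]


def signature_search(
    t: ClinicalTable,
    p: Partition,
    subgroup: int,
    sizes=range(1, 21),
    families: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    ranking: pd.DataFrame | None = None,
) -> ClinicalSignature:
    """Search signature sizes s over classifier families with stratified CV.

    The chosen signature is the smallest s whose best family performs within
    one standard error of the overall best (balanced accuracy), favouring
    parsimony the way the study's size/performance compromise does.
    """
    enc = _encoded_complete(t).loc[p.labels.index]
    y = (p.labels == subgroup).to_numpy().astype(int)
    if ranking is None:
        ranking = ensemble_select(t, p, subgroup, seed=seed)
    ranked_feats = list(ranking.index)
    sizes = [s for s in sizes]
    if max(sizes) > len(ranked_feats):
        raise ValueError(f"size {max(sizes)} > {len(ranked_feats)} available features")
    families = families or _default_families(seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for s in sizes:
        feats = ranked_feats[:s]
        xs = StandardScaler().fit_transform(enc[feats].to_numpy())
        for name, proto in families.items():
            from sklearn.base import clone

            scores = cross_val_score(clone(proto), xs, y, cv=cv, scoring="balanced_accuracy")
            rows.append(
                {"s": s, "family": name, "mean": scores.mean(), "se": scores.std(ddof=1) / np.sqrt(folds)}
            )
    table = pd.DataFrame(rows)
    best = table.loc[table["mean"].idxmax()]
    threshold = best["mean"] - best["se"]
    per_s = table.groupby("s")["mean"].max()
    s_star = int(min(s for s in per_s.index if per_s[s] >= threshold))
    fam_row = table[table["s"] == s_star].sort_values("mean", ascending=False).iloc[0]
    feats = ranked_feats[:s_star]
    # refit a linear model for reportable coefficients
    xs = StandardScaler().fit_transform(enc[feats].to_numpy())
    lin = SVC(kernel="linear", C=1.0, random_state=seed).fit(xs, y)
    coefs = dict(zip(feats, lin.coef_[0]))
    return ClinicalSignature(
        subgroup=subgroup,
        features=feats,
        coefficients={k: float(v) for k, v in coefs.items()},
        size=s_star,
        family=str(fam_row["family"]),
        cv_performance=float(fam_row["mean"]),
        search_table=table,
    )


def fit_composite(
    tables: ClinicalTable | list[ClinicalTable],
    p: Partition,
    signatures: list[ClinicalSignature],
    seed: int = 0,
    model: str = "svm",
) -> CompositeClassifier:
    """Pool per-subgroup signatures (union, order-preserving) and fit a
    multi-class model.  When several imputed tables are given, one model is
    fitted per table and predictions are later pooled by vote."""
    if len(signatures) < 2:
        raise ValueError("need >= 2 per-subgroup signatures to pool")
    if isinstance(tables, ClinicalTable):
        tables = [tables]
    pooled: list[str] = []
    for sig in signatures:
        for f in sig.features:
            if f not in pooled:
                pooled.append(f)
    y = p.labels.to_numpy()
    scalers, models = [], []
    for tab in tables:
        enc = _encoded_complete(tab).loc[p.labels.index]
        sc = StandardScaler().fit(enc[pooled].to_numpy())
        xs = sc.transform(enc[pooled].to_numpy())
        if model == "svm":
            # sigmoid-calibrated linear SVM: class probabilities without the
            # deprecated probability flag
            from sklearn.calibration import CalibratedClassifierCV

            clf = CalibratedClassifierCV(
                SVC(kernel="linear", C=1.0, random_state=seed), method="sigmoid", cv=3, ensemble=False
            )
        elif model == "lr":
            clf = LogisticRegression(max_iter=1000, random_state=seed)
        else:
            raise ValueError(f"unknown composite model {model!r}")
        clf.fit(xs, y)
        scalers.append(sc)
        models.append(clf)
    # CV report on the first table
    enc = _encoded_complete(tables[0]).loc[p.labels.index]
    xs = StandardScaler().fit_transform(enc[pooled].to_numpy())
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    ref = SVC(kernel="linear", C=1.0, random_state=seed) if model == "svm" else LogisticRegression(max_iter=1000)
    pred = cross_val_predict(ref, xs, y, cv=cv)
    return CompositeClassifier(
        features=pooled,
        scalers=scalers,
        models=models,
        classes=models[0].classes_,
        cv_confusion=confusion_matrix(y, pred),
        cv_balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        metadata={"seed": seed, "model": model, "n_tables": len(tables)},
    )


def classify_cohort(c: CompositeClassifier, v: ClinicalTable):
    """Predict subgroup membership for a new cohort.

    Returns ``(Partition-like label Series, probability DataFrame)``; the
    probabilities are averaged over the per-imputation models (vote pooling).
    """
    enc = _encoded_complete(v)
    missing = [f for f in c.features if f not in enc.columns]
    if missing:
        raise KeyError(f"validation table lacks required features: {missing}")
    x = enc[c.features].to_numpy()
    probs = np.zeros((len(enc), len(c.classes)))
    for sc, m in zip(c.scalers, c.models):
        probs += m.predict_proba(sc.transform(x))
    probs /= len(c.models)
    pred = c.classes[np.argmax(probs, axis=1)]
    labels = pd.Series(pred, index=enc.index, dtype=int)
    prob_df = pd.DataFrame(probs, index=enc.index, columns=[f"p_{cl}" for cl in c.classes])
    return labels, prob_df
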