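"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — preprocess, subgroup discovery, gene
signatures, clinical signatures + transfer classification, survival
validation, correlation network — over files in the documented formats, and
writes a manifest (resolved config, per-stage seeds, SHA-256 input hashes,
output names) from which every numeric output is reproducible.  The global
seed is expanded into independent per-stage streams so toggling one stage
never perturbs another's randomness.

Scaled-down defaults (bootstrap count, imputation m and iterations, signature
size range) keep a full run to desk runtime; ``full_scale=True`` switches to
the study-scale settings (m=50, 20 iterations, 100 bootstraps, s up to 20).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio
from .association import build_network
from .clinical import (
    clean_clinical,
    classify_cohort,
    ensemble_select,
    fit_composite,
    impute_chained,
    signature_search,
)
from .discovery import (
    Partition,
    rbf_affinity,
    select_stable_geneset,
    spectral_cluster,
    vote_k,
)
from .gene_signatures import fold_changes, lasso_signatures
from .preprocess import (
    arcsinh_transform,
    filter_low_expression,
    remove_sex_genes,
)
from .survival import cox_fit, km_estimate, logrank_test

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "discover_subgroups"]


def discover_subgroups(m, sizes, ks, n_boot: int = 20, seed: int = 0):
    """Full discovery path on a transformed matrix.

    Variance ranking feeds bootstrap-stability gene-set sizing; the number of
    subgroups is voted by the internal-index ensemble on the full matrix (a
    preliminary vote) and re-used for stability sizing; the final partition
    is the spectral clustering of the chosen gene set at the voted k.

    Returns ``(partition, vote, stability, genes)``.
    """
    from .preprocess import rank_genes_by_variability

    sizes = [s for s in sizes if s <= m.n_genes]
    ks = [k for k in ks if 2 <= k <= m.n_samples // 5]
    vote = vote_k(m, ks, seed=seed)
    stab = select_stable_geneset(m, sizes, vote.majority_k, n_boot=n_boot, seed=seed)
    _, (genes,) = rank_genes_by_variability(m, sizes=[stab.chosen_size])
    sub = m.subset_genes(genes)
    part = spectral_cluster(rbf_affinity(sub, "auto"), vote.majority_k, seed=seed)
    return part, vote, stab, genes


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent deterministic seed per stage (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    expression: str = ""
    annotation: str = ""
    clinical: str = ""
    clinical_dictionary: str = ""
    survival: str = ""
    validation_clinical: str = ""
    validation_survival: str = ""
    out_dir: str = "run"
    seed: int = 0
    # preprocessing
    min_reads: float = 2.0
    min_fraction: float = 0.95
    extra_sex_exclusions: tuple = ()
    # discovery
    candidate_sizes: tuple = (50, 100, 300, 600)
    candidate_ks: tuple = (2, 3, 4, 5, 6, 7, 8)
    n_boot: int = 20
    # clinical arm
    max_missing: float = 0.05
    n_imputations: int = 10
    n_iterations: int = 10
    s_max: int = 10
    # network
    rho_min: float = 0.25
    p_max: float = 1.11e-5
    full_scale: bool = False
    stages: tuple = ("preprocess", "discover", "gene_sig", "clin_sig", "survival", "network")

    def __post_init__(self) -> None:
        if self.full_scale:
            self.n_imputations, self.n_iterations = 50, 20
            self.n_boot, self.s_max = 100, 20
        if self.min_fraction <= 0 or self.min_fraction > 1:
            raise ValueError("min_fraction must lie in (0, 1]")
        if self.n_boot < 2 or self.n_imputations < 1:
            raise ValueError("invalid resampling settings")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Any stage failure is re-raised with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.resolved(), "inputs": {}, "stages": {}, "outputs": []}
    for key in ("expression", "annotation", "clinical", "clinical_dictionary", "survival",
                "validation_clinical", "validation_survival"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = _hash_file(p)

    state: dict = {}
    stage_fns = {
        "preprocess": _stage_preprocess,
        "discover": _stage_discover,
        "gene_sig": _stage_gene_sig,
        "clin_sig": _stage_clin_sig,
        "survival": _stage_survival,
        "network": _stage_network,
    }
    for stage in config.stages:
        if stage not in stage_fns:
            raise ValueError(f"unknown stage {stage!r}")
        seed = stage_seed(config.seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        try:
            stage_fns[stage](config, state, out, seed, manifest)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _stage_preprocess(cfg, state, out, seed, manifest):
    m = eio.read_expression(cfg.expression)
    ann = eio.read_annotation(cfg.annotation)
    m = filter_low_expression(m, cfg.min_reads, cfg.min_fraction)
    n_after_filter = m.n_genes
    m = remove_sex_genes(m, ann, list(cfg.extra_sex_exclusions))
    state["expr_raw"] = m
    state["expr"] = arcsinh_transform(m)
    eio.write_expression(state["expr"], out / "expression_arcsinh.tsv")
    eio.write_json(
        {"n_genes_after_filter": n_after_filter, "n_genes_after_sex_removal": m.n_genes},
        out / "preprocess_report.json",
    )


def _stage_discover(cfg, state, out, seed, manifest):
    m = state["expr"]
    part, vote, stab, genes = discover_subgroups(
        m, cfg.candidate_sizes, cfg.candidate_ks, n_boot=cfg.n_boot, seed=seed
    )
    state["partition"] = part
    state["cluster_genes"] = genes
    eio.write_partition(part, out / "partition.tsv")
    eio.write_json(
        {"chosen_size": stab.chosen_size, "per_size": stab.per_size, "n_bootstrap": stab.n_bootstrap},
        out / "stability.json",
    )
    eio.write_json(
        {"votes": vote.votes, "tally": {str(k_): v for k_, v in vote.tally.items()}, "majority_k": vote.majority_k},
        out / "kvote.json",
    )


def _stage_gene_sig(cfg, state, out, seed, manifest):
    m = state["expr"].subset_genes(state["cluster_genes"])
    sig = lasso_signatures(m, state["partition"], seed=seed)
    state["gene_signature"] = sig
    eio.write_gene_signature(sig, out / "gene_signature.tsv")
    union = sorted({g for s in sig.top_sets.values() for g in s})
    if union and state["partition"].k >= 2:
        raw = state["expr_raw"].subset_genes([g for g in union if g in state["expr_raw"].gene_ids])
        fc = fold_changes(raw, state["partition"], raw.gene_ids, 1, 2)
        fc.table.to_csv(out / "fold_changes.tsv", sep="\t")


def _stage_clin_sig(cfg, state, out, seed, manifest):
    t = eio.read_clinical(cfg.clinical, cfg.clinical_dictionary)
    part = state["partition"]
    cleaned, report = clean_clinical(t, cfg.max_missing)
    tables, _ = impute_chained(cleaned, cfg.n_imputations, cfg.n_iterations, seed=seed)
    first = tables[0]
    sigs = []
    for sg in sorted(part.labels.unique()):
        ranking = ensemble_select(first, part, sg, seed=seed)
        sigs.append(
            signature_search(first, part, sg, sizes=range(1, cfg.s_max + 1), seed=seed, ranking=ranking)
        )
    comp = fit_composite(tables, part, sigs, seed=seed)
    state["composite"] = comp
    state["clin_signatures"] = sigs
    state["clinical_first_imputed"] = first
    eio.write_json(
        {
            "clean_report": report,
            "signatures": [
                {"subgroup": s.subgroup, "features": s.features, "size": s.size, "family": s.family,
                 "cv_balanced_accuracy": s.cv_performance}
                for s in sigs
            ],
            "composite_features": comp.features,
            "composite_cv_balanced_accuracy": comp.cv_balanced_accuracy,
        },
        out / "clinical_signatures.json",
    )
    if cfg.validation_clinical:
        # validation keeps every feature the classifier needs: the 5% drop
        # rule is a training-side modelling choice, so only impute here
        vt = eio.read_clinical(cfg.validation_clinical, cfg.clinical_dictionary)
        vtables, _ = impute_chained(vt, 1, cfg.n_iterations, seed=seed + 1)
        labels, probs = classify_cohort(comp, vtables[0])
        state["validation_labels"] = labels
        pred = Partition.from_labels(labels.to_numpy(), list(labels.index))
        pred.labels = labels  # keep model's class ids, not size-ranked ones
        eio.write_partition(pred, out / "validation_predicted.tsv")
        probs.to_csv(out / "validation_probabilities.tsv", sep="\t", index_label="sample_id")


def _stage_survival(cfg, state, out, seed, manifest):
    d = eio.read_survival(cfg.survival)
    part = state.get("partition")
    res: dict = {}
    if part is not None:
        d.data = d.data.loc[part.labels.index]
        d.data["group"] = part.labels
        stat, p = logrank_test(d)
        res["logrank"] = {"statistic": stat, "p": p}
        res["five_year_survival"] = {}
        for sg in sorted(part.labels.unique()):
            km = km_estimate(d, sg)
            res["five_year_survival"][str(sg)] = km.at(5 * 365.25)
        cov = d.data.copy()
        cov["age_above_median"] = 0  # placeholder when no clinical table is loaded
        if "clinical_first_imputed" in state:
            t = state["clinical_first_imputed"]
            if "age_diagnosis" in t.values.columns:
                age = t.values.loc[part.labels.index, "age_diagnosis"].astype(float)
                cov["age_above_median"] = (age > age.median()).astype(int)
        cov["poor_subgroup"] = (part.labels == 1).astype(int)
        covs = ["poor_subgroup"] + (["age_above_median"] if cov["age_above_median"].nunique() > 1 else [])
        from .survival import SurvivalData

        fit = cox_fit(SurvivalData(cov[["time", "event", *covs]], d.time_origin), covs)
        res["cox"] = {c: {"hr": float(fit.summary.loc[c, "hr"]), "p": float(fit.summary.loc[c, "p"])} for c in covs}
    if cfg.validation_survival and "validation_labels" in state:
        vd = eio.read_survival(cfg.validation_survival)
        vd.data = vd.data.loc[state["validation_labels"].index]
        vd.data["group"] = state["validation_labels"]
        stat, p = logrank_test(vd)
        res["validation_logrank"] = {"statistic": stat, "p": p}
    eio.write_json(res, out / "survival_report.json")


def _stage_network(cfg, state, out, seed, manifest):
    if "gene_signature" not in state or "clinical_first_imputed" not in state:
        return
    sig = state["gene_signature"]
    genes = sorted({g for s in sig.top_sets.values() for g in s})
    t = state["clinical_first_imputed"]
    feats = [f for f in t.values.columns if t.dictionary[f] == "numeric"]
    if not genes or not feats:
        return
    raw = state["expr_raw"]
    genes = [g for g in genes if g in raw.gene_ids]
    net = build_network(raw, t, genes, feats, cfg.rho_min, cfg.p_max)
    eio.write_edge_list(net, out / "network_edges.tsv")
    eio.write_graphml(net, out / "network.graphml")
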