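"""Synthetic discovery/validation cohorts with planted endophenotype structure.

The generator emulates the statistical structure the analysis assumes for a
whole-blood PAH cohort, at desk scale:

* three latent subgroups — poor / moderate / good prognosis — with sizes
  proportional to 129 : 89 : 112 (the three predominant subgroups of the
  discovery cohort; two optional small extra subgroups are off by default);
* block-structured marker genes on a multiplicative (log-normal) TPM scale:
  an immunoglobulin-like block ordered low < intermediate < high across
  poor / moderate / good, an ALAS2-like block up in the poor subgroup and a
  NOG-like block up in the good subgroup;
* sex-chromosome nuisance genes whose variance is driven by a simulated sex
  label rather than by subgroup (what the sex-gene filter must remove);
* a tail of lowly expressed genes that the >2-TPM-in-95%-of-samples filter
  should discard;
* subgroup-correlated clinical features (CRP, 6MWD, age at diagnosis, BMI,
  creatinine, right atrial area, NT-proBNP ...) with MCAR (optionally MAR)
  missingness;
* exponential survival with subgroup-specific hazards calibrated to 5-year
  survival of 53% / 65% / 78% and independent exponential censoring;
* a genotype whose C/C frequency differs by subgroup (the good-prognosis
  group enriched).

Ground truth (labels, marker sets, hazards, shifts) is returned alongside so
every downstream stage can be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .preprocess import ExpressionMatrix, GeneAnnotation
from .survival import SurvivalData

__all__ = [
    "ClinicalFeatureSpec",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_validation_cohort",
    "hazard_for_survival",
]

DAYS_PER_YEAR = 365.25


def hazard_for_survival(five_year_survival: float) -> float:
    """Exponential rate (per year) with S(5) = exp(-5 * rate) at the target."""
    if not 0 < five_year_survival < 1:
        raise ValueError("five-year survival must lie in (0, 1)")
    return -np.log(five_year_survival) / 5.0


@dataclass
class ClinicalFeatureSpec:
    """One clinical feature: distribution, per-subgroup shift, missingness."""

    name: str
    kind: str = "numeric"  # numeric | binary | categorical | ordered
    dist: str = "normal"  # normal | lognormal (numeric only)
    mean: float = 0.0  # baseline mean (log-mean for lognormal)
    sd: float = 1.0
    shifts: tuple = (0.0, 0.0, 0.0)  # additive per-subgroup mean shift
    missing_rate: float = 0.0
    levels: tuple = ()  # binary/categorical/ordered
    level_probs: tuple = ()  # per-subgroup tuples of level probabilities


def _default_clinical_features() -> list[ClinicalFeatureSpec]:
    """Subgroup order: (poor, moderate, good) — analogous to subgroups I, V, II.

    Centres and shift directions follow the discovery cohort's clinical table
    (lowest 6MWD, oldest age at diagnosis, highest NT-proBNP/CRP/creatinine/
    BMI/RAA in the poor subgroup); shift magnitudes are calibrated so
    adjacent subgroups differ by roughly one SD on each informative feature —
    the separability regime in which clinical signatures transfer to an
    independent cohort.
    """
    F = ClinicalFeatureSpec
    return [
        F("crp", dist="lognormal", mean=1.3, sd=0.7, shifts=(2.2, 1.1, 0.0), missing_rate=0.03),
        F("six_mwd", mean=397.0, sd=110.0, shifts=(-200.0, -100.0, 0.0), missing_rate=0.03),
        F("age_diagnosis", mean=41.0, sd=12.0, shifts=(28.0, 14.0, 0.0), missing_rate=0.01),
        F("bmi", mean=26.0, sd=4.5, shifts=(8.0, 4.0, 0.0), missing_rate=0.02),
        F("creatinine", mean=80.0, sd=16.0, shifts=(32.0, 16.0, 0.0), missing_rate=0.03),
        F("raa", mean=21.0, sd=5.0, shifts=(10.0, 5.0, 0.0), missing_rate=0.08),
        F("nt_probnp", dist="lognormal", mean=4.9, sd=1.0, shifts=(2.6, 1.3, 0.0), missing_rate=0.03),
        F("heart_rate", mean=75.0, sd=10.0, shifts=(0.0, 0.0, 0.0), missing_rate=0.03),
        F("height", mean=168.0, sd=9.0, shifts=(0.0, 0.0, 0.0), missing_rate=0.02),
        F(
            "functional_class",
            kind="ordered",
            levels=("I", "II", "III", "IV"),
            level_probs=((0.05, 0.34, 0.50, 0.11), (0.11, 0.40, 0.45, 0.04), (0.17, 0.41, 0.39, 0.03)),
            missing_rate=0.03,
        ),
        F(
            "vasoresponder",
            kind="binary",
            levels=(0, 1),
            level_probs=((0.84, 0.16), (0.86, 0.14), (0.78, 0.22)),
            missing_rate=0.02,
        ),
    ]


@dataclass
class CohortSpec:
    """Generative description of one cohort.

    The defaults are the study conditions this package is exercised under:
    n = 330 patients in proportions 129:89:112 (poor:moderate:good), 1000
    genes of which 60 + 10 + 10 form the marker blocks, a 1.0 log-unit marker
    effect, and hazards matching 53% / 65% / 78% five-year survival.
    """

    n_samples: int = 330
    n_genes: int = 1000
    n_subgroups: int = 3
    subgroup_proportions: tuple = (129 / 330, 89 / 330, 112 / 330)
    marker_block_sizes: dict = field(
        default_factory=lambda: {"immunoglobulin": 60, "alas2": 10, "nog": 10}
    )
    marker_effect: float = 1.0
    n_sex_genes: int = 20
    sex_effect: float = 2.5
    n_low_genes: int = 50
    noise_sd_range: tuple = (0.3, 0.6)
    female_fraction: tuple = (0.62, 0.78, 0.73)
    clinical_feature_specs: list = field(default_factory=_default_clinical_features)
    five_year_survival: tuple = (0.53, 0.65, 0.78)
    censor_rate: float = 0.08  # per year
    genotype_cc_freq: tuple = (0.12, 0.20, 0.33)
    missingness_mechanism: str = "mcar"  # or "mar" (conditioned on age)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        props = np.asarray(self.subgroup_proportions, dtype=float)
        if len(props) != self.n_subgroups:
            raise ValueError("one proportion per subgroup required")
        if (props <= 0).any() or not np.isclose(props.sum(), 1.0, atol=1e-8):
            raise ValueError("subgroup proportions must be positive and sum to 1")
        if any(s <= 0 or s >= 1 for s in self.five_year_survival):
            raise ValueError("five-year survivals must lie in (0, 1)")
        if self.censor_rate <= 0:
            raise ValueError("censor rate must be positive")
        sizes = self._subgroup_sizes()
        if (sizes == 0).any():
            raise ValueError("a subgroup would receive zero samples")

    def _subgroup_sizes(self) -> np.ndarray:
        props = np.asarray(self.subgroup_proportions, dtype=float)
        sizes = np.floor(props * self.n_samples).astype(int)
        # largest-remainder rounding so sizes sum exactly to n_samples
        rem = props * self.n_samples - sizes
        for i in np.argsort(-rem)[: self.n_samples - sizes.sum()]:
            sizes[i] += 1
        return sizes

    @property
    def hazards(self) -> np.ndarray:
        return np.array([hazard_for_survival(s) for s in self.five_year_survival])


@dataclass
class SyntheticTruth:
    labels: pd.Series  # sample -> subgroup (1 = poor, 2 = moderate, 3 = good)
    marker_genes: dict
    planted_hazards: dict
    planted_clinical_shifts: dict
    planted_genotype_freqs: dict
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        sets = [set(v) for v in self.marker_genes.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("marker blocks must be disjoint")


def _gene_layout(spec: CohortSpec):
    """Gene ids, chromosome annotation and per-block index ranges."""
    blocks = {}
    ids, chrom = [], {}
    cursor = 0
    for block, size in spec.marker_block_sizes.items():
        names = [f"{block.upper()}L{i:03d}" for i in range(1, size + 1)]
        blocks[block] = names
        for g in names:
            chrom[g] = "chr1"
        ids.extend(names)
        cursor += size
    sex_names = [f"SEXG{i:03d}" for i in range(1, spec.n_sex_genes + 1)]
    for i, g in enumerate(sex_names):
        chrom[g] = "chrY" if i % 2 == 0 else "chrX"
    ids.extend(sex_names)
    low_names = [f"LOWG{i:03d}" for i in range(1, spec.n_low_genes + 1)]
    for g in low_names:
        chrom[g] = "chr2"
    ids.extend(low_names)
    n_bg = spec.n_genes - len(ids)
    if n_bg < 0:
        raise ValueError("marker + sex + low gene counts exceed n_genes")
    bg_names = [f"G{i:05d}" for i in range(1, n_bg + 1)]
    for g in bg_names:
        chrom[g] = f"chr{3 + (hash(g) % 5)}"
    ids.extend(bg_names)
    return ids, chrom, blocks, sex_names, low_names


def _block_shifts(spec: CohortSpec) -> dict:
    """Per-block, per-subgroup log-scale mean shifts (poor, moderate, good)."""
    e = spec.marker_effect
    shifts = {
        "immunoglobulin": np.array([-e, 0.0, e]),
        "alas2": np.array([e, 0.0, 0.0]),
        "nog": np.array([0.0, 0.0, e]),
    }
    if spec.n_subgroups > 3:
        # optional small extra subgroups echo the poor/good patterns
        for b in shifts:
            extra = [shifts[b][0 if i % 2 == 0 else 2] for i in range(spec.n_subgroups - 3)]
            shifts[b] = np.concatenate([shifts[b], extra])
    return {b: v for b, v in shifts.items() if b in spec.marker_block_sizes}


def _expression(spec: CohortSpec, labels, sex, rng) -> tuple[pd.DataFrame, GeneAnnotation, dict]:
    ids, chrom, blocks, sex_names, low_names = _gene_layout(spec)
    n = spec.n_samples
    log_mu = rng.normal(2.0, 1.0, size=len(ids))
    lo, hi = spec.noise_sd_range
    sigma = rng.uniform(lo, hi, size=len(ids))
    idx_of = {g: i for i, g in enumerate(ids)}
    # marker blocks emulate well-expressed blood transcripts (immunoglobulins,
    # haeme-pathway genes): keep them clear of the low-expression filter even
    # in the down-shifted subgroup
    for genes in blocks.values():
        for g in genes:
            log_mu[idx_of[g]] = rng.normal(3.0, 0.4)
    shift = np.zeros((len(ids), n))
    block_shifts = _block_shifts(spec)
    for block, genes in blocks.items():
        per_group = block_shifts[block]
        for g in genes:
            shift[idx_of[g], :] = per_group[labels - 1]
    for i, g in enumerate(sex_names):
        # chrY-like genes high in males, chrX-like high in females
        target = (sex == ("M" if i % 2 == 0 else "F")).astype(float)
        shift[idx_of[g], :] = spec.sex_effect * target
    for g in low_names:
        log_mu[idx_of[g]] = np.log(0.5)  # TPM ~ 0.5: fails the >2 filter
    vals = np.exp(log_mu[:, None] + shift + rng.normal(0.0, sigma[:, None], size=(len(ids), n)))
    df = pd.DataFrame(vals, index=ids, columns=labels.index)
    annotation = GeneAnnotation(chromosome=chrom)
    return df, annotation, blocks


def _clinical(spec: CohortSpec, labels, rng) -> ClinicalTable:
    n = spec.n_samples
    g = labels.to_numpy() - 1
    cols, dictionary, levels = {}, {}, {}
    age_ref = None
    for fs in spec.clinical_feature_specs:
        if fs.kind == "numeric":
            base = rng.normal(0.0, fs.sd, size=n)
            shifts = np.asarray(fs.shifts, dtype=float)[g]
            vals = fs.mean + shifts + base
            if fs.dist == "lognormal":
                vals = np.exp(vals)
            cols[fs.name] = vals.astype(float)
            if fs.name == "age_diagnosis":
                age_ref = vals
        else:
            probs = np.asarray(fs.level_probs, dtype=float)
            draws = [fs.levels[rng.choice(len(fs.levels), p=probs[gi] / probs[gi].sum())] for gi in g]
            cols[fs.name] = draws
            levels[fs.name] = list(fs.levels)
        dictionary[fs.name] = fs.kind
    df = pd.DataFrame(cols, index=labels.index)
    # missingness injection
    for fs in spec.clinical_feature_specs:
        if fs.missing_rate <= 0:
            continue
        if spec.missingness_mechanism == "mar" and age_ref is not None and fs.name != "age_diagnosis":
            # older patients more likely to miss the measurement
            z = (age_ref - age_ref.mean()) / (age_ref.std() + 1e-12)
            p = fs.missing_rate * np.exp(0.5 * z)
            p = np.clip(p * (fs.missing_rate / p.mean()), 0, 0.9)
        else:
            p = np.full(n, fs.missing_rate)
        mask = rng.random(n) < p
        if mask.any():
            col = df[fs.name]
            if col.dtype != object and dictionary[fs.name] in ("numeric",):
                df.loc[mask, fs.name] = np.nan
            else:
                col = col.astype(object)
                col[mask] = np.nan
                df[fs.name] = col
    return ClinicalTable(df, dictionary, levels)


def _survival(spec: CohortSpec, labels, rng) -> SurvivalData:
    g = labels.to_numpy() - 1
    lam = spec.hazards[g]
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.exponential(1.0 / spec.censor_rate, size=len(g))
    event = (t_event <= t_cens).astype(int)
    time_years = np.minimum(t_event, t_cens)
    df = pd.DataFrame(
        {
            "time": np.maximum(time_years * DAYS_PER_YEAR, 1.0),
            "event": event,
            "group": labels.to_numpy(),
        },
        index=labels.index,
    )
    return SurvivalData(df, time_origin="sampling")


def _genotype(spec: CohortSpec, labels, rng) -> pd.DataFrame:
    g = labels.to_numpy() - 1
    cc = np.asarray(spec.genotype_cc_freq, dtype=float)
    if len(cc) < spec.n_subgroups:
        cc = np.resize(cc, spec.n_subgroups)
    q = np.sqrt(cc)  # C allele frequency under Hardy-Weinberg
    genos = []
    for gi in g:
        p = np.array([q[gi] ** 2, 2 * q[gi] * (1 - q[gi]), (1 - q[gi]) ** 2])
        genos.append(("C/C", "C/T", "T/T")[rng.choice(3, p=p / p.sum())])
    return pd.DataFrame({"hla_variant": genos}, index=labels.index)


def _labels_and_sex(spec: CohortSpec, rng, prefix: str):
    sizes = spec._subgroup_sizes()
    lab = np.repeat(np.arange(1, spec.n_subgroups + 1), sizes)
    rng.shuffle(lab)
    sample_ids = [f"{prefix}{i:04d}" for i in range(1, spec.n_samples + 1)]
    labels = pd.Series(lab, index=sample_ids, dtype=int)
    female = np.resize(np.asarray(spec.female_fraction), spec.n_subgroups)[lab - 1]
    sex = pd.Series(np.where(rng.random(spec.n_samples) < female, "F", "M"), index=sample_ids)
    return labels, sex


def generate_qpcr_table(
    n_group_1: int = 53,
    n_group_2: int = 38,
    assays: tuple = ("NOG", "IGHM", "ALAS2", "NEBL"),
    shifts: dict | None = None,
    ct_sd: float = 0.8,
    seed: int = 0,
):
    """Synthetic TaqMan-style Ct table for two validation subgroups.

    Group sizes default to the qPCR confirmation arm (subgroup I n=53,
    subgroup II n=38).  ``shifts`` maps assay -> Ct difference (group 2
    relative to group 1; negative = earlier amplification = higher
    expression in group 2).  Defaults plant a 1.5-cycle higher expression of
    the NOG-like and IGHM-like assays in group 2 and of ALAS2 in group 1,
    with a null NEBL-like assay.  Duplicate wells are averaged on the Ct
    scale before return.
    """
    from .association import QPCRTable

    if shifts is None:
        shifts = {"NOG": -1.5, "IGHM": -1.5, "ALAS2": 1.0, "NEBL": 0.0}
    rng = np.random.default_rng(seed)
    n = n_group_1 + n_group_2
    groups = pd.Series(
        [1] * n_group_1 + [2] * n_group_2, index=[f"Q{i:03d}" for i in range(1, n + 1)]
    )
    base = {a: rng.uniform(22.0, 28.0) for a in assays}
    ref_ct = rng.normal(18.0, 0.3, size=(n, 2)).mean(axis=1)  # duplicates averaged
    cols = {"GAPDH": ref_ct}
    for a in assays:
        mu = base[a] + np.where(groups.to_numpy() == 2, shifts.get(a, 0.0), 0.0)
        cols[a] = (mu[:, None] + rng.normal(0.0, ct_sd, size=(n, 2))).mean(axis=1)
    ct = pd.DataFrame(cols, index=groups.index)
    return QPCRTable(ct=ct, reference_assay="GAPDH", groups=groups)


def generate_cohort(spec: CohortSpec):
    """Generate one discovery cohort.

    Returns ``(expression, clinical, survival, genotype, truth)``; same seed
    gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels, sex = _labels_and_sex(spec, rng, prefix="P")
    expr_df, annotation, blocks = _expression(spec, labels, sex, rng)
    clinical = _clinical(spec, labels, rng)
    surv = _survival(spec, labels, rng)
    geno = _genotype(spec, labels, rng)
    truth = SyntheticTruth(
        labels=labels,
        marker_genes=blocks,
        planted_hazards={i + 1: float(h) for i, h in enumerate(spec.hazards)},
        planted_clinical_shifts={
            fs.name: {i + 1: float(s) for i, s in enumerate(np.resize(fs.shifts, spec.n_subgroups))}
            for fs in spec.clinical_feature_specs
            if fs.kind == "numeric"
        },
        planted_genotype_freqs={i + 1: float(f) for i, f in enumerate(np.resize(spec.genotype_cc_freq, spec.n_subgroups))},
        sex=sex,
    )
    expr = ExpressionMatrix(expr_df, "raw")
    return expr, clinical, surv, geno, truth, annotation


def generate_validation_cohort(spec: CohortSpec, truth: SyntheticTruth | None = None, n_samples: int = 197):
    """Clinical-only cohort from the same generative model (no expression).

    ``spec`` must share clinical feature specs with the discovery spec; the
    validation cohort's own planted labels are returned in a fresh truth
    record.  Survival is reported from diagnosis, as in the validation arm.
    """
    import dataclasses

    vspec = dataclasses.replace(spec, n_samples=n_samples, seed=spec.seed + 104729)
    rng = np.random.default_rng(vspec.seed)
    labels, sex = _labels_and_sex(vspec, rng, prefix="V")
    clinical = _clinical(vspec, labels, rng)
    surv = _survival(vspec, labels, rng)
    surv.time_origin = "diagnosis"
    vtruth = SyntheticTruth(
        labels=labels,
        marker_genes={},
        planted_hazards={i + 1: float(h) for i, h in enumerate(vspec.hazards)},
        planted_clinical_shifts={
            fs.name: {i + 1: float(s) for i, s in enumerate(np.resize(fs.shifts, vspec.n_subgroups))}
            for fs in vspec.clinical_feature_specs
            if fs.kind == "numeric"
        },
        planted_genotype_freqs={i + 1: float(f) for i, f in enumerate(np.resize(vspec.genotype_cc_freq, vspec.n_subgroups))},
        sex=sex,
    )
    if truth is not None:
        disc_feats = set(truth.planted_clinical_shifts)
        val_feats = set(vtruth.planted_clinical_shifts)
        if disc_feats != val_feats:
            raise ValueError("validation cohort feature dictionary differs from discovery")
    return clinical, surv, vtruth
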