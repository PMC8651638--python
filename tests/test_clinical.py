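import numpy as np
import pandas as pd
import pytest

from endopheno.clinical import (
    ClinicalTable,
    classify_cohort,
    clean_clinical,
    encode_table,
    ensemble_select,
    fit_composite,
    impute_chained,
    signature_search,
)
from endopheno.discovery import Partition


def _table(n=40, seed=0, missing=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "flag": rng.integers(0, 2, n),
            "grade": rng.choice(["I", "II", "III"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    if missing:
        for col, frac in missing.items():
            idx = rng.choice(n, int(frac * n), replace=False)
            if df[col].dtype == object:
                col_vals = df[col].astype(object)
                col_vals.iloc[idx] = np.nan
                df[col] = col_vals
            else:
                df.loc[df.index[idx], col] = np.nan
    return ClinicalTable(
        df,
        {"a": "numeric", "b": "numeric", "flag": "binary", "grade": "ordered"},
        {"flag": [0, 1], "grade": ["I", "II", "III"]},
    )


class TestCleanClinical:
    def test_feature_above_threshold_dropped(self):
        t = _table(n=100, missing={"b": 0.06})
        out, report = clean_clinical(t, max_missing=0.05)
        assert "b" not in out.values.columns
        assert "b" in report["dropped"]

    def test_fully_observed_table_unchanged(self):
        t = _table(n=50)
        out, report = clean_clinical(t)
        assert list(out.values.columns) == list(t.values.columns)
        assert report["dropped"] == {}

    def test_surviving_features_match_hand_enumeration(self):
        t = _table(n=100, missing={"a": 0.10, "b": 0.04, "grade": 0.08})
        out, _ = clean_clinical(t, max_missing=0.05)
        frac = t.values.isna().mean()
        expected = [c for c in t.values.columns if frac[c] <= 0.05]
        assert list(out.values.columns) == expected

    def test_all_features_dropped_is_error(self):
        t = _table(n=100, missing={"a": 0.5, "b": 0.5, "flag": 0.5, "grade": 0.5})
        with pytest.raises(ValueError):
            clean_clinical(t, max_missing=0.05)


class TestEncoding:
    def test_fixed_scheme_binary_ordered_onehot(self):
        df = pd.DataFrame(
            {"flag": [0, 1], "grade": ["I", "III"], "colour": ["red", "blue"]},
            index=["s1", "s2"],
        )
        t = ClinicalTable(
            df,
            {"flag": "binary", "grade": "ordered", "colour": "categorical"},
            {"flag": [0, 1], "grade": ["I", "II", "III"], "colour": ["blue", "red"]},
        )
        enc = encode_table(t)
        assert enc.loc["s1", "flag"] == 0.0 and enc.loc["s2", "flag"] == 1.0
        assert enc.loc["s1", "grade"] == 0.0 and enc.loc["s2", "grade"] == 2.0
        assert enc.loc["s1", "colour=red"] == 1.0 and enc.loc["s1", "colour=blue"] == 0.0

    def test_undeclared_feature_rejected(self):
        with pytest.raises(ValueError):
            ClinicalTable(pd.DataFrame({"x": [1.0]}), {})


class TestImputeChained:
    def test_complete_table_returned_unchanged(self):
        t = _table(n=30)
        tables, traces = impute_chained(t, n_imputations=3, n_iterations=2, seed=0)
        assert len(tables) == 3
        for tab in tables:
            pd.testing.assert_frame_equal(tab.values, t.values)

    def test_mcar_mean_recovery_within_five_percent(self, cohort):
        import dataclasses

        from endopheno.synthetic import generate_cohort

        spec = dataclasses.replace(
            cohort["spec"],
            clinical_feature_specs=[
                dataclasses.replace(f, missing_rate=0.0) for f in cohort["spec"].clinical_feature_specs
            ],
        )
        _, clin, *_ = generate_cohort(spec)
        complete_mean = clin.values["six_mwd"].mean()
        rng = np.random.default_rng(0)
        mask = rng.random(len(clin.values)) < 0.10
        clin.values.loc[mask, "six_mwd"] = np.nan
        tables, _ = impute_chained(clin, n_imputations=5, n_iterations=5, seed=0)
        pooled = np.mean([t.values["six_mwd"].mean() for t in tables])
        assert abs(pooled - complete_mean) / abs(complete_mean) < 0.05

    def test_pmm_imputations_come_from_observed_donors(self):
        t = _table(n=60, seed=2, missing={"a": 0.2})
        observed = set(t.values["a"].dropna())
        mask = t.values["a"].isna()
        tables, _ = impute_chained(t, n_imputations=2, n_iterations=3, seed=1)
        for tab in tables:
            assert set(tab.values.loc[mask, "a"]) <= observed

    def test_categorical_imputations_use_declared_levels(self):
        t = _table(n=60, seed=3, missing={"grade": 0.15, "flag": 0.1})
        tables, _ = impute_chained(t, n_imputations=2, n_iterations=3, seed=2)
        for tab in tables:
            assert not tab.values.isna().any().any()
            assert set(tab.values["grade"]) <= {"I", "II", "III"}
            assert set(tab.values["flag"]) <= {0, 1}

    def test_majority_missing_feature_rejected(self):
        t = _table(n=40, missing={"a": 0.6})
        with pytest.raises(ValueError):
            impute_chained(t, 2, 2, seed=0)

    def test_seeded_reproducibility(self):
        t = _table(n=50, seed=4, missing={"a": 0.1, "grade": 0.1})
        a, _ = impute_chained(t, 2, 3, seed=9)
        b, _ = impute_chained(t, 2, 3, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.values, y.values)


class TestEnsembleSelect:
    def _perfect_feature_table(self, part):
        rng = np.random.default_rng(0)
        n = len(part.labels)
        df = pd.DataFrame(
            {
                "oracle": (part.labels == 1).astype(float) * 4 + rng.normal(0, 0.05, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            },
            index=part.labels.index,
        )
        return ClinicalTable(df, {c: "numeric" for c in df.columns})

    def test_perfectly_separating_feature_ranks_first(self, truth_partition):
        t = self._perfect_feature_table(truth_partition)
        ranking = ensemble_select(t, truth_partition, 1, seed=0)
        assert ranking.index[0] == "oracle"
        assert (ranking.loc["oracle"].drop("mean_rank") == 1.0).all()

    def test_planted_clinical_features_occupy_top_ranks(self, cohort, truth_partition):
        clin = cohort["clinical"]
        tables, _ = impute_chained(clin, 1, 3, seed=0)
        ranking = ensemble_select(tables[0], truth_partition, 1, seed=0)
        informative = {"crp", "six_mwd", "age_diagnosis", "bmi", "creatinine", "nt_probnp", "raa"}
        assert len(set(ranking.index[:5]) & informative) >= 4

    def test_absent_subgroup_rejected(self, truth_partition):
        t = self._perfect_feature_table(truth_partition)
        with pytest.raises(ValueError):
            ensemble_select(t, truth_partition, 99, seed=0)

    def test_requires_at_least_two_selectors(self, truth_partition):
        t = self._perfect_feature_table(truth_partition)
        with pytest.raises(ValueError):
            ensemble_select(t, truth_partition, 1, methods=("univariate",))


@pytest.fixture(scope="module")
def imputed_clinical(cohort):
    cleaned, _ = clean_clinical(cohort["clinical"])
    tables, _ = impute_chained(cleaned, 1, 5, seed=0)
    return tables[0]


@pytest.fixture(scope="module")
def fitted_composite(imputed_clinical, truth_partition):
    sigs = [
        signature_search(
            imputed_clinical, truth_partition, sg, sizes=range(1, 7), folds=3, seed=0
        )
        for sg in (1, 2, 3)
    ]
    comp = fit_composite(imputed_clinical, truth_partition, sigs, seed=0)
    return sigs, comp


class TestSignatureSearchAndComposite:
    def test_size_one_signature_is_top_ranked_feature(self, imputed_clinical, truth_partition):
        ranking = ensemble_select(imputed_clinical, truth_partition, 1, seed=0)
        sig = signature_search(
            imputed_clinical, truth_partition, 1, sizes=[1], folds=3, seed=0, ranking=ranking
        )
        assert sig.features == [ranking.index[0]]

    def test_poor_subgroup_signature_contains_planted_features(self, fitted_composite):
        sigs, _ = fitted_composite
        poor = next(s for s in sigs if s.subgroup == 1)
        informative = {"crp", "six_mwd", "age_diagnosis", "bmi", "creatinine", "nt_probnp"}
        assert set(poor.features) & informative

    def test_pooled_features_are_a_union_without_duplicates(self, fitted_composite):
        sigs, comp = fitted_composite
        union = []
        for s in sigs:
            for f in s.features:
                if f not in union:
                    union.append(f)
        assert comp.features == union
        assert len(set(comp.features)) == len(comp.features)

    def test_composite_cv_balanced_accuracy_reflects_planted_separability(self, fitted_composite):
        _, comp = fitted_composite
        assert comp.cv_balanced_accuracy >= 0.8

    def test_label_permutation_drops_to_chance(self, imputed_clinical, truth_partition, fitted_composite):
        sigs, _ = fitted_composite
        rng = np.random.default_rng(0)
        permuted = Partition(
            labels=pd.Series(
                rng.permutation(truth_partition.labels.to_numpy()),
                index=truth_partition.labels.index,
            ),
            k=3,
        )
        comp = fit_composite(imputed_clinical, permuted, sigs, seed=0)
        assert abs(comp.cv_balanced_accuracy - 1 / 3) < 0.1

    def test_oversized_signature_request_rejected(self, imputed_clinical, truth_partition):
        with pytest.raises(ValueError):
            signature_search(
                imputed_clinical, truth_partition, 1, sizes=[500], folds=3, seed=0
            )


class TestClassifyCohort:
    def test_resubstitution_agreement_at_least_cv(self, imputed_clinical, truth_partition, fitted_composite):
        _, comp = fitted_composite
        labels, probs = classify_cohort(comp, imputed_clinical)
        agree = (labels == truth_partition.labels.loc[labels.index]).mean()
        assert agree >= comp.cv_balanced_accuracy - 0.05
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_transfer_to_validation_cohort(self, validation, fitted_composite):
        from sklearn.metrics import balanced_accuracy_score

        _, comp = fitted_composite
        vtabs, _ = impute_chained(validation["clinical"], 1, 5, seed=1)
        labels, _ = classify_cohort(comp, vtabs[0])
        ba = balanced_accuracy_score(validation["truth"].labels.loc[labels.index], labels)
        assert ba >= 0.75

    def test_missing_required_feature_error_names_it(self, imputed_clinical, fitted_composite):
        _, comp = fitted_composite
        crippled = ClinicalTable(
            imputed_clinical.values.drop(columns=[comp.features[0]]),
            {k: v for k, v in imputed_clinical.dictionary.items() if k != comp.features[0]},
            imputed_clinical.levels,
        )
        with pytest.raises(KeyError, match=comp.features[0]):
            classify_cohort(comp, crippled)

    def test_row_permutation_does_not_leak(self, imputed_clinical, fitted_composite):
        _, comp = fitted_composite
        labels, _ = classify_cohort(comp, imputed_clinical)
        shuffled = ClinicalTable(
            imputed_clinical.values.sample(frac=1, random_state=0),
            imputed_clinical.dictionary,
            imputed_clinical.levels,
        )
        labels2, _ = classify_cohort(comp, shuffled)
        assert labels2.loc[labels.index].equals(labels)
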