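"""Cohort splitting, screens, diagnosis rules and the bias audit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcmicro import classify, prep
from crcmicro.classify import (
    CLASS_ORDER,
    StageModel,
    accuracy_from_confusion,
    audit_bias,
    report_from_votes,
    split_cohort,
)
from crcmicro.errors import InputError
from crcmicro.simulate import SimulationConfig, generate_cohort
from conftest import small_config


def _default_metadata():
    rows = []
    k = 0
    for g, n in (("BP", 45), ("T1", 9), ("T2", 13), ("T3", 22), ("T4", 6)):
        for _ in range(n):
            rows.append((f"S{k:03d}", g, 50 + (k % 30), "male"))
            k += 1
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "age", "gender"]
    ).set_index("sample_id")


class TestSplitCohort:
    def test_default_cohort_reproduces_67_28_with_32_bp(self):
        meta = _default_metadata()
        train, test = split_cohort(meta, seed=0)
        assert len(train) == 67 and len(test) == 28
        assert (meta.loc[train, "group"] == "BP").sum() == 32
        assert (meta.loc[test, "group"] == "BP").sum() == 13

    def test_partition_properties(self):
        meta = _default_metadata()
        train, test = split_cohort(meta, seed=3)
        assert len(train.intersection(test)) == 0
        assert set(train) | set(test) == set(meta.index)

    def test_deterministic_given_seed(self):
        meta = _default_metadata()
        a = split_cohort(meta, seed=5)
        b = split_cohort(meta, seed=5)
        assert list(a[0]) == list(b[0])

    def test_small_stratum_error(self):
        meta = _default_metadata().iloc[:46]  # one lone T1 sample
        with pytest.raises(InputError):
            split_cohort(meta, seed=0)


class TestAccuracyFromConfusion:
    def test_identity_matrix_is_perfect(self):
        m = pd.DataFrame(np.eye(5, dtype=int) * 4,
                         index=CLASS_ORDER, columns=CLASS_ORDER)
        overall, per_class = accuracy_from_confusion(m)
        assert overall == 1.0
        assert (per_class == 1.0).all()

    def test_zero_total_error(self):
        m = pd.DataFrame(0, index=CLASS_ORDER, columns=CLASS_ORDER)
        with pytest.raises(InputError):
            accuracy_from_confusion(m)

    def test_negative_entries_rejected(self):
        m = pd.DataFrame(np.eye(5), index=CLASS_ORDER, columns=CLASS_ORDER)
        m.iloc[0, 1] = -1
        with pytest.raises(InputError):
            accuracy_from_confusion(m)


class TestVoteRule:
    def test_majority_vote_wins(self):
        votes = pd.DataFrame(
            [[0.6, 0.1, 0.1, 0.1, 0.1]], index=["s1"], columns=CLASS_ORDER
        )
        observed = pd.Series(["T1"], index=["s1"])
        rep = report_from_votes(votes, observed)
        assert rep.diagnosed["s1"] == "T1"
        assert not rep.low_confidence["s1"]

    def test_uniform_votes_tie_break_by_class_order(self):
        votes = pd.DataFrame(
            [[0.2] * 5], index=["s1"], columns=CLASS_ORDER
        )
        observed = pd.Series(["T3"], index=["s1"])
        rep = report_from_votes(votes, observed)
        assert rep.diagnosed["s1"] == "T1"  # first in the fixed order
        assert rep.low_confidence["s1"]

    def test_confusion_trace_equals_overall_accuracy(self):
        rng = np.random.default_rng(0)
        raw = rng.random((30, 5))
        votes = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True),
                             index=[f"s{i}" for i in range(30)],
                             columns=CLASS_ORDER)
        observed = pd.Series(
            rng.choice(CLASS_ORDER, 30), index=votes.index
        )
        rep = report_from_votes(votes, observed)
        total = rep.confusion.to_numpy().sum()
        assert total == 30
        assert rep.overall_accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / total
        )

    def test_false_negatives_counted_from_stage_rows(self):
        votes = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0, 1.0], [1.0, 0.0, 0.0, 0.0, 0.0]],
            index=["s1", "s2"], columns=CLASS_ORDER,
        )
        observed = pd.Series(["T2", "T1"], index=votes.index)
        rep = report_from_votes(votes, observed)
        assert rep.false_negatives == 1


class TestStageModelContract:
    def test_feature_exclusion_overlap_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(InputError):
            StageModel(rank="asv", features=["a", "b"], excluded=["b"],
                       forest=RandomForestClassifier())


class TestScreens:
    def test_constant_age_error(self):
        prof = pd.DataFrame(np.random.default_rng(0).random((12, 5)),
                            index=[f"s{i}" for i in range(12)])
        ages = pd.Series(50, index=prof.index)
        with pytest.raises(InputError):
            classify.age_screen(prof, ages, n_estimators=10)

    def test_stage_screen_respects_exclusion(self, small_rarefied):
        rarefied, meta, _, truth = small_rarefied
        rel = prep.to_relative(rarefied)
        excluded = list(rel.columns[:10])
        res = classify.stage_screen(rel, meta["group"], excluded=excluded,
                                    top_k=8, seed=0, n_estimators=30)
        assert not set(res.selected) & set(excluded)
        assert len(res.selected) == 8

    def test_age_screen_cv_curve_shape(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        rel = prep.to_relative(rarefied)
        bp = meta.index[meta["group"] == "BP"]
        res = classify.age_screen(rel.loc[bp], meta["age"], seed=0,
                                  n_estimators=30)
        assert len(res.cv_errors) == len(res.cv_sizes)
        assert res.cv_sizes[-1] == 1
        assert res.cv_sizes[0] == rel.shape[1]
        assert len(res.selected) in res.cv_sizes


class TestDiagnose:
    @pytest.fixture(scope="class")
    def fitted(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        rel = prep.to_relative(rarefied)
        screen = classify.stage_screen(rel, meta["group"], top_k=8, seed=1,
                                       n_estimators=50)
        model = classify.fit_stage_model(rel, meta["group"], screen.selected,
                                         seed=1, n_estimators=50)
        return model, rel, meta

    def test_training_sample_diagnosed_with_strong_vote(self, fitted):
        model, rel, meta = fitted
        rep = classify.diagnose(model, rel, observed=meta["group"])
        assert rep.confusion.to_numpy().sum() == len(rel)
        # resubstitution votes should be confident for most samples
        assert rep.low_confidence.mean() < 0.5

    def test_missing_features_zero_filled(self, fitted, caplog):
        model, rel, meta = fitted
        dropped = rel.drop(columns=model.features[:2])
        with caplog.at_level("WARNING"):
            rep = classify.diagnose(model, dropped)
        assert "zero-filling" in caplog.text
        assert len(rep.diagnosed) == len(rel)

    def test_empty_input_error(self, fitted):
        model, rel, _ = fitted
        with pytest.raises(InputError):
            classify.diagnose(model, rel.iloc[:0])


class TestAuditBias:
    def _meta(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "group": "BP",
                "age": rng.integers(30, 80, n),
                "gender": rng.choice(["male", "female"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_all_correct_degenerate(self):
        meta = self._meta(10)
        correct = pd.Series(True, index=meta.index)
        out = audit_bias(correct, meta)
        assert out["degenerate"].all()

    def test_fisher_matches_scipy_on_hand_table(self):
        meta = pd.DataFrame(
            {
                "group": "BP",
                "age": [50] * 8,
                "gender": ["male"] * 4 + ["female"] * 4,
            },
            index=[f"s{i}" for i in range(8)],
        )
        correct = pd.Series(
            [True, True, True, False, True, False, False, False],
            index=meta.index,
        )
        out = audit_bias(correct, meta)
        table = np.array([[3, 1], [1, 3]])  # female/male x false/true
        _, p_ref = stats.fisher_exact(table)
        assert out.loc["gender_fisher", "p"] == pytest.approx(p_ref)

    def test_age_independent_errors_give_moderate_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for seed in range(20):
            meta = self._meta(40)
            correct = pd.Series(
                np.random.default_rng(seed).random(40) > 0.3, index=meta.index
            )
            out = audit_bias(correct, meta)
            if not out["degenerate"].any():
                ps.append(out.loc["age_ranksum", "p"])
        # under the null p-values are roughly uniform
        assert 0.25 < np.mean(ps) < 0.75


class TestEvaluateRank:
    def test_end_to_end_report_sums_to_cohort(self, small_rarefied):
        rarefied, meta, tax, _ = small_rarefied
        train, test = split_cohort(meta, seed=0)
        combined, test_rep, model, age_res = classify.evaluate_rank(
            rarefied, tax, meta, "asv", train, test, top_k=6, seed=0,
            n_estimators=40,
        )
        assert combined.confusion.to_numpy().sum() == len(meta)
        assert test_rep.confusion.to_numpy().sum() == len(test)
        assert not set(model.features) & set(model.excluded)
        assert age_res is not None

    def test_rank_sweep_reports_all_ranks(self, small_rarefied):
        rarefied, meta, tax, _ = small_rarefied
        reports, chosen = classify.rank_sweep(
            rarefied, tax, meta, seed=0, ranks=("phylum", "asv"), top_k=5,
            n_estimators=30,
        )
        assert set(reports) == {"phylum", "asv"}
        assert chosen in reports
        for rep in reports.values():
            assert 0.0 <= rep["combined"].overall_accuracy <= 1.0
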