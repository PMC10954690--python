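import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from speechmarkers.features import extract_markers
from speechmarkers.simulate import gen_cohort, sample1_like
from speechmarkers.stats import (
    LinearLadder,
    LogisticLadder,
    RankDeficientError,
    aggregate_participant,
    attach_outcomes,
    bh_flags,
    correlate_bh,
    group_test,
    rank_auc,
    report,
)
from speechmarkers.syntax import LexiconTagger


def brute_force_bh(pvals, alpha):
    """Step-up rule by direct threshold search."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


@pytest.fixture(scope="module")
def medium_study():
    """40-participant cohort with a reduced marker set for ladder tests."""
    cohort = gen_cohort(sample1_like(n_participants=40, rng_seed=3))
    lex = cohort.lexicon
    table = extract_markers(cohort.transcripts, lex.lexicon, lex.stimuli,
                            tagger=LexiconTagger(lex.tags))
    markers = ["on_topic", "coherence", "l1", "nodes", "density"]
    features = aggregate_participant(table, markers=markers)
    return cohort, features, markers


class TestAggregate:
    @staticmethod
    def _excerpts(values, marker="on_topic"):
        n = len(values)
        return pd.DataFrame(
            {"participant_id": ["P1"] * n, "excerpt_id": [str(i) for i in range(n)],
             "version": ["manual"] * n, marker: values}
        )

    def test_identical_excerpts_mean_identity(self):
        out = aggregate_participant(self._excerpts([0.4] * 8))
        assert out.loc[0, "on_topic"] == pytest.approx(0.4)

    def test_arithmetic_mean(self):
        out = aggregate_participant(self._excerpts(list(range(1, 9))))
        assert out.loc[0, "on_topic"] == pytest.approx(4.5)

    def test_missing_excerpt_excluded_pairwise(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, np.nan]
        out = aggregate_participant(self._excerpts(vals))
        assert out.loc[0, "on_topic"] == pytest.approx(4.0)

    def test_all_missing_gives_missing_cell(self):
        out = aggregate_participant(self._excerpts([np.nan, np.nan]))
        assert math.isnan(out.loc[0, "on_topic"])


class TestBenjaminiHochberg:
    def test_worked_step_up_example(self):
        flags = bh_flags(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert flags.all()  # thresholds 0.0167, 0.0333, 0.05

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 21))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            assert np.array_equal(bh_flags(p, alpha), brute_force_bh(p, alpha))

    def test_flags_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=12)
            flags = bh_flags(p, 0.05)
            order = np.argsort(p)
            sorted_flags = flags[order]
            # no rejected p-value above an accepted larger one
            assert not np.any(np.diff(sorted_flags.astype(int)) > 0)

    def test_nan_p_never_rejected(self):
        flags = bh_flags(np.array([0.001, np.nan]), 0.05)
        assert flags[0] and not flags[1]


class TestCorrelateBH:
    @staticmethod
    def _features(marker_vals, outcome_vals, marker="on_topic"):
        n = len(marker_vals)
        f = pd.DataFrame(
            {"participant_id": [f"P{i}" for i in range(n)], "version": "automated",
             marker: marker_vals, "spq": outcome_vals, "pdi": outcome_vals}
        )
        return f

    def test_planted_monotone_marker(self):
        vals = np.arange(20.0)
        out = correlate_bh(self._features(vals, vals * 2 + 1))
        row = out[(out.marker == "on_topic") & (out.outcome == "spq")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.significant_bh_05

    def test_constant_marker_missing_and_excluded(self):
        out = correlate_bh(self._features(np.ones(10), np.arange(10.0)))
        assert out.rho.isna().all()
        assert not out.significant_bh_05.any()


class TestGroupTest:
    @staticmethod
    def _features(x, y, marker="l1"):
        rows = []
        for g, vals in (("low", x), ("high", y)):
            for i, v in enumerate(vals):
                rows.append({"participant_id": f"{g}{i}", "version": "manual",
                             marker: v, "group": g})
        return pd.DataFrame(rows)

    def test_complete_separation_exact_p(self):
        out = group_test(self._features([1, 2, 3], [4, 5, 6]))
        row = out.iloc[0]
        assert row.u == 0.0  # statistic of the first (low) group
        assert row.p_raw == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_not_significant(self):
        out = group_test(self._features([1, 2, 3, 4], [1, 2, 3, 4]))
        assert out.iloc[0].p_raw > 0.5
        assert not out.iloc[0].significant_bh_05

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(2)
        out = group_test(self._features(rng.normal(0, 1, 50), rng.normal(1, 1, 50)))
        assert out.iloc[0].significant_bh_05

    def test_empty_group_rejected(self):
        f = self._features([1, 2], [3, 4])
        with pytest.raises(ValueError, match="2 groups"):
            group_test(f.assign(group="low"))


def _simple_features(x, marker="on_topic", version="automated"):
    n = len(x)
    return pd.DataFrame(
        {"participant_id": [f"P{i}" for i in range(n)], "version": version, marker: x}
    )


class TestLinearLadder:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        features = _simple_features(x)
        outcomes = pd.DataFrame({"participant_id": features.participant_id,
                                 "spq": 2 * x + 1})
        res = LinearLadder(markers=["on_topic"], sets=("markers_automated",)).fit(
            features, outcomes, outcome="spq").results_
        assert res.loc[0, "r2"] == pytest.approx(1.0)
        assert res.loc[0, "rmse"] == pytest.approx(0.0, abs=1e-8)

    def test_four_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        features = _simple_features(x)
        outcomes = pd.DataFrame({"participant_id": features.participant_id, "spq": y})
        lad = LinearLadder(markers=["on_topic"], sets=("markers_automated",)).fit(
            features, outcomes, outcome="spq")
        assert lad.results_.loc[0, "r2"] == pytest.approx(0.64)  # Sxy^2/(Sxx Syy)
        assert lad.models_["markers_automated"].params[1] == pytest.approx(0.8)

    def test_pure_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(4)
        adj = []
        for _ in range(10):
            x = rng.normal(size=(150, 3))
            features = pd.DataFrame(
                {"participant_id": [f"P{i}" for i in range(150)], "version": "automated",
                 "l1": x[:, 0], "l2": x[:, 1], "l3": x[:, 2]}
            )
            outcomes = pd.DataFrame({"participant_id": features.participant_id,
                                     "spq": rng.normal(size=150)})
            res = LinearLadder(markers=["l1", "l2", "l3"], sets=("markers_automated",)).fit(
                features, outcomes, outcome="spq").results_
            adj.append(res.loc[0, "adjusted_r2"])
        assert np.mean(adj) == pytest.approx(0.0, abs=0.05)

    def test_collinear_columns_error_when_not_dropping(self):
        x = np.arange(12.0)
        features = _simple_features(x).assign(coherence=2 * x)
        outcomes = pd.DataFrame({"participant_id": features.participant_id,
                                 "spq": x + 1})
        with pytest.raises(RankDeficientError, match="coherence"):
            LinearLadder(markers=["on_topic", "coherence"], sets=("markers_automated",),
                         drop_collinear=False).fit(features, outcomes, outcome="spq")

    def test_nested_sets_never_lose_r2(self, medium_study):
        cohort, features, markers = medium_study
        lad = LinearLadder(markers=markers).fit(features, cohort.outcomes, outcome="spq")
        r2 = lad.results_.set_index("regressor_set")["r2"]
        assert r2["demographics+markers_automated"] >= r2["demographics"] - 1e-12
        assert r2["demographics+markers_automated"] >= r2["markers_automated"] - 1e-12
        assert r2["demographics+markers_manual"] >= r2["markers_manual"] - 1e-12


class TestLogisticLadder:
    def test_intercept_only_null_identities(self):
        rng = np.random.default_rng(0)
        features = _simple_features(rng.normal(size=20))
        outcomes = pd.DataFrame({"participant_id": features.participant_id,
                                 "group": ["high", "low"] * 10})
        lad = LogisticLadder(markers=["on_topic"], sets=("intercept_only",)).fit(
            features, outcomes)
        row = lad.results_.iloc[0]
        assert row.nagelkerke_r2 == pytest.approx(0.0, abs=1e-10)
        assert row.tjur_r2 == pytest.approx(0.0, abs=1e-10)
        assert row.cox_snell_r2 == pytest.approx(0.0, abs=1e-10)
        assert row.auc == pytest.approx(0.5)

    def test_hand_computed_two_by_two_pseudo_r2(self):
        x = [0.0] * 4 + [1.0] * 4
        y = ["low"] * 3 + ["high"] + ["high"] * 3 + ["low"]
        features = _simple_features(np.array(x))
        outcomes = pd.DataFrame({"participant_id": features.participant_id, "group": y})
        lad = LogisticLadder(markers=["on_topic"], sets=("markers_automated",)).fit(
            features, outcomes, positive="high")
        row = lad.results_.iloc[0]
        # saturated-in-x MLE: p(x=0)=1/4, p(x=1)=3/4
        l1 = ((3 / 4) ** 3 * (1 / 4)) ** 2
        l0 = 0.5**8
        cs = 1 - (l0 / l1) ** (2 / 8)
        assert row.cox_snell_r2 == pytest.approx(cs, abs=1e-6)
        assert row.nagelkerke_r2 == pytest.approx(cs / (1 - l0 ** (2 / 8)), abs=1e-6)
        assert row.tjur_r2 == pytest.approx(0.25, abs=1e-6)
        assert row.auc == pytest.approx(0.75, abs=1e-6)
        assert row.accuracy == pytest.approx(0.75)

    def test_perfect_predictor_flagged_separation(self):
        x = np.concatenate([np.zeros(6), np.ones(6)])
        features = _simple_features(x)
        outcomes = pd.DataFrame({"participant_id": features.participant_id,
                                 "group": ["low"] * 6 + ["high"] * 6})
        lad = LogisticLadder(markers=["on_topic"], sets=("markers_automated",)).fit(
            features, outcomes, positive="high")
        row = lad.results_.iloc[0]
        assert row.separation_flagged
        assert row.accuracy == 1.0
        assert row.tjur_r2 > 0.9
        assert row.auc == pytest.approx(1.0)

    def test_loglik_monotone_across_nested_sets(self, medium_study):
        cohort, features, markers = medium_study
        out = cohort.outcomes.assign(
            group=np.where(cohort.outcomes.spq > cohort.outcomes.spq.median(), "high", "low")
        )
        lad = LogisticLadder(markers=markers).fit(features, out)
        ll = lad.results_.set_index("regressor_set")["log_likelihood"]
        assert ll["demographics+markers_automated"] >= ll["demographics"] - 1e-6
        assert ll["demographics+markers_automated"] >= ll["markers_automated"] - 1e-6

    def test_rank_auc_matches_sklearn(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 60).astype(bool)
        y[0], y[1] = True, False
        scores = rng.normal(size=60) + y * 0.7
        assert rank_auc(y, scores) == pytest.approx(roc_auc_score(y, scores))


class TestReport:
    def test_writes_tables_deterministically(self, tmp_path, medium_study):
        cohort, features, markers = medium_study
        merged = attach_outcomes(features, cohort.outcomes)
        results = {
            "correlations": correlate_bh(merged, markers=markers),
            "linear_ladder": LinearLadder(markers=markers).fit(
                features, cohort.outcomes, outcome="spq").results_,
        }
        first = report(results, tmp_path / "a")
        again = report(results, tmp_path / "b")
        assert len(first) == len(again) == 3  # two CSVs + summary
        for p1, p2 in zip(first, again):
            assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a" / "summary.txt").read_text()
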