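"""mRMR primitives, greedy ranking, and consensus selection."""

import numpy as np
import pandas as pd
import pytest

from rfa_radiomics.select import (
    CRITERIA,
    RankingResult,
    consensus_select,
    f_statistic,
    mrmr_rank,
    mrmr_score,
    mutual_information,
    pearson_redundancy,
    rf_relevance,
)


class TestMutualInformation:
    def test_identical_binary_balanced(self):
        x = np.array([0, 0, 1, 1])
        assert mutual_information(x, x, x_is_discrete=True) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_independent_crossing(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y, x_is_discrete=True) == pytest.approx(0.0, abs=1e-12)

    def test_constant_x(self):
        assert mutual_information(np.ones(10), np.arange(10) % 2) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([1.0, 2.0]), np.array([0, 1]))


class TestFStatistic:
    def test_hand_value(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert f_statistic(x, y) == pytest.approx(13.5, abs=1e-12)

    def test_equal_means(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert f_statistic(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_capped(self):
        x = np.array([0.0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            f = f_statistic(x, y)
        assert np.isfinite(f) and f > 1e6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(np.arange(4.0), np.zeros(4))


class TestPearsonRedundancy:
    def test_proportional(self):
        assert pearson_redundancy([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_absolute_value(self):
        assert pearson_redundancy([1, 2, 3], [6, 4, 2]) == pytest.approx(1.0)

    def test_orthogonal(self):
        x1 = np.array([1.0, -1, 1, -1])
        x2 = np.array([1.0, 1, -1, -1])
        assert pearson_redundancy(x1, x2) == pytest.approx(0.0, abs=1e-12)

    def test_constant_warns_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_redundancy(np.ones(5), np.arange(5.0)) == 0.0


class TestRfRelevance:
    def test_informative_feature_wins(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            y = rng.integers(0, 2, n)
            X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
            X["f0"] = y + 0.5 * rng.normal(size=n)
            imp = rf_relevance(X, y, seed=seed)
            if max(imp, key=imp.get) == "f0":
                wins += 1
        assert wins >= 19

    def test_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 50)
        assert rf_relevance(X, y, seed=3) == rf_relevance(X, y, seed=3)

    def test_scores_normalized(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, 60)
        imp = rf_relevance(X, y, seed=0)
        assert all(v >= 0 for v in imp.values())
        assert sum(imp.values()) <= 1.0 + 1e-9


class TestMrmrScore:
    def test_empty_set_is_relevance(self):
        assert mrmr_score(0.5, [], quotient=False) == 0.5

    def test_mid_miq_hand_values(self):
        assert mrmr_score(0.5, [0.2, 0.2], quotient=False) == pytest.approx(0.3)
        assert mrmr_score(0.5, [0.2, 0.2], quotient=True) == pytest.approx(2.5)


def _planted_design(seed, n=500, n_noise=16):
    """3 independent informative features (one dominant anchor), 1 redundant
    copy of the anchor, pure-noise companions. Calibrated by simulation:
    MID recovers the 3 informative features in 100/100 seeds."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    cols = {
        "info0": y + 0.3 * rng.normal(size=n),
        "info1": y + 0.45 * rng.normal(size=n),
        "info2": y + 0.45 * rng.normal(size=n),
    }
    cols["redundant"] = cols["info0"] + 0.25 * rng.normal(size=n)
    for i in range(n_noise):
        cols[f"noise{i:02d}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


class TestMrmrRank:
    def test_depth_validation(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 30)
        with pytest.raises(ValueError):
            mrmr_rank(X, y, "MID", depth=0)

    def test_unknown_criterion(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            mrmr_rank(X, rng.integers(0, 2, 30), "XXX")

    def test_first_feature_agreement(self):
        X, y = _planted_design(0)
        mid = mrmr_rank(X, y, "MID", depth=3)
        miq = mrmr_rank(X, y, "MIQ", depth=3)
        assert mid.order[0] == miq.order[0]
        fcd = mrmr_rank(X, y, "FCD", depth=3)
        fcq = mrmr_rank(X, y, "FCQ", depth=3)
        assert fcd.order[0] == fcq.order[0]

    def test_column_order_irrelevant(self):
        X, y = _planted_design(1)
        a = mrmr_rank(X, y, "MID", depth=5)
        b = mrmr_rank(X[list(reversed(X.columns))], y, "MID", depth=5)
        assert a.order == b.order

    def test_mid_prefers_independent_over_redundant(self):
        wins = 0
        n_trials = 20  # scaled-down version of the 100-seed acceptance run
        for seed in range(n_trials):
            X, y = _planted_design(seed)
            rank = mrmr_rank(X, y, "MID", depth=3)
            if set(rank.order) == {"info0", "info1", "info2"}:
                wins += 1
        assert wins >= int(0.9 * n_trials)

    def test_greedy_near_optimal_small_instance(self):
        """Greedy MID triple scores in the top decile of all triples."""
        from itertools import combinations

        X, y = _planted_design(3, n=300, n_noise=8)
        X = X[sorted(X.columns)[:12]]
        rank = mrmr_rank(X, y, "MID", depth=3)

        from rfa_radiomics.select import mutual_information as mi

        def triple_score(names):
            rel = sum(mi(X[n].to_numpy(), y) for n in names)
            red = [
                mi(X[a].to_numpy(), X[b].to_numpy())
                for a, b in combinations(names, 2)
            ]
            return rel - np.mean(red)

        all_scores = sorted(
            (triple_score(c) for c in combinations(X.columns, 3)), reverse=True
        )
        greedy = triple_score(tuple(rank.order))
        cutoff = all_scores[max(1, len(all_scores) // 10) - 1]
        assert greedy >= cutoff


class TestConsensus:
    def _identical_rankings(self, names):
        return [
            RankingResult(criterion=c, order=list(names), scores=[0.0] * len(names))
            for c in CRITERIA
        ]

    def test_identical_rankings_preserved(self, rng):
        names = [f"f{i:02d}" for i in range(20)]
        X = pd.DataFrame(rng.normal(size=(60, 20)), columns=names)
        y = np.array([0, 1] * 30)
        sel = consensus_select(
            self._identical_rankings(names), X, y, m_range=(5, 8), seed=0, n_estimators=20
        )
        assert sel.consensus_order[:15] == names[:15]

    def test_top5_everywhere_max_frequency(self, rng):
        names = [f"f{i:02d}" for i in range(20)]
        X = pd.DataFrame(rng.normal(size=(60, 20)), columns=names)
        y = np.array([0, 1] * 30)
        sel = consensus_select(
            self._identical_rankings(names), X, y, m_range=(5, 6), seed=0, n_estimators=20
        )
        assert sel.frequency[names[0]] == 15

    def test_planted_nine_feature_recovery(self):
        """The 9 planted (jointly informative) features fill the top-9
        consensus slots; the CV-chosen size covers all of them.

        Note: asserting chosen_m == 9 exactly is not stable under the
        argmax-CV-AUC rule because forest AUC plateaus for m >= 9; the robust
        part of the contract is the consensus ordering.
        """
        hits = 0
        n_trials = 6
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            n = 400
            latents = rng.normal(size=(n, 9))
            y = (latents.sum(axis=1) > 0).astype(int)
            cols = {f"sig{i}": latents[:, i] for i in range(9)}
            for i in range(11):
                cols[f"noise{i:02d}"] = rng.normal(size=n)
            X = pd.DataFrame(cols)
            rankings = [
                mrmr_rank(X, y, c, depth=15, seed=seed) for c in CRITERIA
            ]
            sel = consensus_select(
                rankings, X, y, m_range=(5, 15), seed=seed, n_estimators=30
            )
            if all(f.startswith("sig") for f in sel.consensus_order[:9]):
                hits += 1
        assert hits >= int(0.8 * n_trials)

    def test_chosen_set_size_invariant(self, rng):
        names = [f"f{i:02d}" for i in range(18)]
        X = pd.DataFrame(rng.normal(size=(60, 18)), columns=names)
        y = np.array([0, 1] * 30)
        sel = consensus_select(
            self._identical_rankings(names), X, y, m_range=(5, 7), seed=1, n_estimators=20
        )
        assert len(sel.chosen_set) == sel.chosen_m
        assert set(sel.chosen_set) <= set(names)
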