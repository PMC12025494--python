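import numpy as np
import pandas as pd
import pytest

import crlandmark as cl
from crlandmark.cif import aalen_johansen
from crlandmark.forest import (
    ForestConfig,
    cluster_bootstrap,
    fit_forest,
    grow_tree,
    minimal_depth,
    predict_cif,
    split_statistic,
    tune_hyperparameters,
)

from conftest import two_cov_config


def _single_landmark(cohort):
    sup = cohort.copy()
    sup.insert(1, "landmark_s", 0.0)
    return sup


def brute_force_logrank(time, event, group, cause):
    """Hand tabulation of the log-rank O-E and hypergeometric variance."""
    time = np.asarray(time, float)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[np.asarray(event) == cause]):
        at_risk = time >= t
        y, y1 = at_risk.sum(), (at_risk & group).sum()
        d = ((time == t) & (np.asarray(event) == cause)).sum()
        d1 = ((time == t) & (np.asarray(event) == cause) & group).sum()
        o_minus_e += d1 - y1 * d / y
        if y > 1:
            var += d * (y1 / y) * (1 - y1 / y) * (y - d) / (y - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


class TestClusterBootstrap:
    def test_single_cluster_inbag_everything(self):
        df = pd.DataFrame({"patient_id": [7, 7, 7], "time": [1, 2, 3], "event": [0, 1, 0]})
        inbag, oob = cluster_bootstrap(df, np.random.default_rng(0))
        assert sorted(inbag.tolist()) == [0, 1, 2]
        assert oob.size == 0

    def test_oob_clusters_never_inbag(self, small_super):
        rng = np.random.default_rng(5)
        for _ in range(5):
            inbag, oob = cluster_bootstrap(small_super, rng)
            inbag_ids = set(small_super["patient_id"].to_numpy()[inbag])
            assert inbag_ids.isdisjoint(oob.tolist())

    def test_whole_clusters_sampled_together(self, small_super):
        inbag, _ = cluster_bootstrap(small_super, np.random.default_rng(1))
        ids = small_super["patient_id"].to_numpy()
        rows_per_cluster = small_super.groupby("patient_id").size()
        sampled = pd.Series(ids[inbag]).value_counts()
        # every sampled cluster appears in full multiples of its row count
        assert ((sampled % rows_per_cluster[sampled.index]) == 0).all()


class TestSplitStatistic:
    def test_identical_daughters_score_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 0, 1, 0, 1, 0, 1, 0]
        group = np.array([True] * 4 + [False] * 4)
        assert split_statistic(time, event, None, group, cause=1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_logrank(self):
        # two groups of 4, distinct uncensored event times
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        event = [1] * 8
        group = np.array([True, True, True, True, False, False, False, False])
        expected = brute_force_logrank(time, event, group, 1)
        got = split_statistic(time, event, None, group, cause=1)
        assert got == pytest.approx(expected, abs=1e-10)
        # composite over one active cause = score/3
        comp = split_statistic(time, event, None, group, cause="composite")
        assert comp == pytest.approx(expected / 3.0, abs=1e-10)

    def test_all_censored_scores_zero(self):
        assert split_statistic([1, 2, 3, 4], [0, 0, 0, 0], None, np.array([True, True, False, False])) == 0.0


class TestTreeGrowth:
    def test_root_only_tree_equals_aalen_johansen(self, small_cohort):
        sup = _single_landmark(small_cohort)
        cfg = ForestConfig(ntree=1, nodesize=len(sup), seed=0)
        forest = fit_forest(sup, cfg)
        root = forest.trees[0].root
        assert root.is_terminal
        # terminal estimate is exactly the Aalen-Johansen CIF of the in-bag multiset
        ids = sup["patient_id"].to_numpy()
        rows = np.concatenate(
            [np.flatnonzero(ids == c) for c in forest.trees[0].inbag_clusters]
        )
        expected = aalen_johansen(
            sup["time"].to_numpy()[rows], sup["event"].to_numpy()[rows],
            sup["landmark_s"].to_numpy()[rows],
        )
        np.testing.assert_array_equal(root.cif.times, expected.times)
        np.testing.assert_allclose(root.cif.values, expected.values, atol=1e-12)

    def test_perfect_separator_chosen_at_root(self):
        rng = np.random.default_rng(2)
        n = 120
        sep = np.repeat([0, 1], n // 2)
        df = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "landmark_s": 0.0,
                "time": np.where(sep == 0, rng.uniform(0.1, 1.0, n), rng.uniform(8, 10, n)),
                "event": np.where(sep == 0, 1, 0),
                "separator": sep,
                "noise": rng.normal(size=n),
            }
        )
        root = grow_tree(df, ForestConfig(ntree=1, mtry=3, nodesize=5, seed=0), np.random.default_rng(0))
        assert not root.is_terminal
        # encoded column order: landmark_s, separator, noise -> separator has index 1
        var = ["landmark_s", "separator", "noise"][root.col]
        assert var == "separator"

    def test_fixed_seed_reproduces_topology(self, small_super):
        def topology(forest):
            out = []
            for tree in forest.trees:
                stack, shape = [tree.root], []
                while stack:
                    node = stack.pop()
                    shape.append((node.col, round(node.thr, 12)))
                    if not node.is_terminal:
                        stack.extend([node.left, node.right])
                out.append(shape)
            return out

        cfg = ForestConfig(ntree=5, seed=42, nodesize=25)
        f1, f2 = fit_forest(small_super, cfg), fit_forest(small_super, cfg)
        assert topology(f1) == topology(f2)
        assert f1.oob_error == f2.oob_error
        pd.testing.assert_frame_equal(minimal_depth(f1), minimal_depth(f2))


class TestForestPrediction:
    def test_root_only_forest_ignores_covariates(self, small_cohort):
        sup = _single_landmark(small_cohort)
        forest = fit_forest(sup, ForestConfig(ntree=3, nodesize=len(sup), seed=1))
        profiles = [
            cl.make_profile("better", small_cohort),
            cl.make_profile("worse", small_cohort),
        ]
        a = predict_cif(forest, profiles[0], s=0.0, conditional=False)
        b = predict_cif(forest, profiles[1], s=0.0, conditional=False)
        np.testing.assert_allclose(a.values, b.values, atol=1e-14)

    def test_ensemble_is_mean_of_tree_predictions(self, small_forest, small_cohort):
        prof = cl.make_profile("worse", small_cohort)
        full = predict_cif(small_forest, prof, s=0.0, conditional=False)
        singles = [
            predict_cif(small_forest, prof, s=0.0, conditional=False, trees=[t]).values
            for t in small_forest.trees
        ]
        np.testing.assert_allclose(full.values, np.mean(singles, axis=0), atol=1e-12)

    def test_predictions_are_valid_cifs(self, small_forest, small_cohort):
        for label in ("better", "worse"):
            prof = cl.make_profile(label, small_cohort)
            for s in (1.0, 3.0, 5.0):
                cif = predict_cif(small_forest, prof, s=s)
                assert cif.is_valid(atol=1e-10)

    def test_unseen_categorical_level_rejected(self, small_forest, small_cohort):
        prof = cl.make_profile("better", small_cohort)
        prof["approach"] = "transanal"
        with pytest.raises(ValueError, match="approach"):
            predict_cif(small_forest, prof, s=1.0)


class TestMinimalDepth:
    def test_never_split_variable_ranks_last(self, small_cohort):
        sup = _single_landmark(small_cohort)[
            ["patient_id", "landmark_s", "time", "event", "pM", "age"]
        ].copy()
        sup["constant"] = 1.0  # cannot be split on
        forest = fit_forest(sup, ForestConfig(ntree=10, mtry=4, nodesize=30, seed=3))
        table = minimal_depth(forest)
        assert table.iloc[-1]["variable"] == "constant"
        max_plus_one = np.mean([t.max_depth + 1.0 for t in forest.trees])
        assert table.set_index("variable").loc["constant", "minimal_depth"] == pytest.approx(max_plus_one)

    def test_dominant_predictor_found_first(self):
        cohort = cl.generate_cohort(two_cov_config(seed=8, beta_relapse=2.0, n_null=4), 1500)
        forest = fit_forest(_single_landmark(cohort), ForestConfig(ntree=30, seed=8, nodesize=20))
        table = minimal_depth(forest)
        ranked = table[table["variable"] != "landmark_s"]
        assert ranked.iloc[0]["variable"] == "x1"


class TestTuning:
    def test_single_cell_grid_returned(self, small_super):
        best, table = tune_hyperparameters(
            small_super, mtry_grid=[4], nodesize_grid=[40], ntree=5, seed=0
        )
        assert (best.mtry, best.nodesize) == (4, 40)
        assert len(table) == 1
        assert ((table["oob_error"] >= 0) & (table["oob_error"] <= 1)).all()

    def test_tie_break_prefers_parsimony(self, monkeypatch):
        import crlandmark.forest as fmod

        class _Fake:
            oob_error = {1: 0.3, 2: 0.3, 3: 0.3}

        monkeypatch.setattr(fmod, "fit_forest", lambda df, cfg: _Fake())
        best, _ = fmod.tune_hyperparameters(None, mtry_grid=[5, 10], nodesize_grid=[5, 50], ntree=1)
        assert (best.mtry, best.nodesize) == (5, 50)
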