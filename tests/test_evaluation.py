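import numpy as np
import pandas as pd
import pytest

import crlandmark as cl
from crlandmark.evaluation import bootstrap_ci, grouped_kfold, harrell_c_competing


def brute_force_c(scores, times, events, cause, tau):
    """Exhaustive ordered-pair enumeration of the cause-specific C rule."""
    conc = comparable = 0.0
    n = len(scores)
    for i in range(n):
        if events[i] != cause or times[i] >= tau:
            continue
        for j in range(n):
            if times[j] > times[i]:
                comparable += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return conc / comparable


class TestGroupedKFold:
    def test_even_partition_of_clusters(self):
        df = pd.DataFrame({"patient_id": np.repeat(np.arange(10), 3)})
        folds = grouped_kfold(df, k=5, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert (sizes == 2).all()

    def test_rows_of_a_patient_share_folds(self, small_super):
        folds = grouped_kfold(small_super, k=5, seed=1)
        mapped = small_super["patient_id"].map(folds)
        assert mapped.notna().all()
        # each cluster in exactly one fold, all rows covered exactly once
        per_cluster = pd.DataFrame({"pid": small_super["patient_id"], "fold": mapped})
        assert (per_cluster.groupby("pid")["fold"].nunique() == 1).all()

    def test_too_many_folds_rejected(self):
        df = pd.DataFrame({"patient_id": [1, 2, 3]})
        with pytest.raises(ValueError):
            grouped_kfold(df, k=5)


class TestHarrellC:
    def test_perfect_ordering_scores_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        scores = -times  # highest risk fails first
        assert harrell_c_competing(scores, times, np.ones(4, int), 1) == 1.0

    def test_constant_scores_give_half(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c_competing(np.zeros(4), times, np.ones(4, int), 1) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            times = rng.exponential(2.0, n).round(1) + 0.1
            events = rng.integers(0, 4, n)
            scores = rng.normal(size=n).round(1)
            tau = float(rng.choice([np.inf, np.quantile(times, 0.8)]))
            try:
                expected = brute_force_c(scores, times, events, 1, tau)
            except ValueError:
                with pytest.raises(ValueError):
                    harrell_c_competing(scores, times, events, 1, tau)
                continue
            got = harrell_c_competing(scores, times, events, 1, tau)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(2.0, 60) + 0.01
        events = rng.integers(0, 4, 60)
        scores = rng.normal(size=60)
        c = harrell_c_competing(scores, times, events, 2)
        assert harrell_c_competing(np.exp(3 * scores), times, events, 2) == pytest.approx(c)
        assert harrell_c_competing(-scores, times, events, 2) == pytest.approx(1 - c)


class TestBootstrapCI:
    @pytest.fixture
    def eval_df(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"patient_id": np.arange(50), "value": rng.normal(size=50)})

    def test_degenerate_metric_collapses_interval(self, eval_df):
        lo, hi = bootstrap_ci(lambda d: 0.7, eval_df, B=20, seed=0)
        assert (lo, hi) == (0.7, 0.7)

    def test_two_replicates_span_min_max(self, eval_df):
        vals = []
        bootstrap_ci(lambda d: vals.append(float(d["value"].mean())) or vals[-1], eval_df, B=2, seed=1)
        lo, hi = bootstrap_ci(lambda d: float(d["value"].mean()), eval_df, B=2, seed=1)
        assert lo == pytest.approx(min(vals))
        assert hi == pytest.approx(max(vals))

    def test_interval_usually_covers_point_estimate(self, eval_df):
        point = float(eval_df["value"].mean())
        covered = 0
        for seed in range(10):
            lo, hi = bootstrap_ci(lambda d: float(d["value"].mean()), eval_df, B=60, seed=seed)
            covered += lo <= point <= hi
        assert covered >= 9

    def test_excess_failures_rejected(self, eval_df):
        def flaky(d):
            raise ValueError("undefined")

        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="20%"):
                bootstrap_ci(flaky, eval_df, B=10, seed=0)


class TestCompareModels:
    def test_report_structure_and_fold_partition(self, small_cohort):
        report = cl.compare_models(
            small_cohort,
            [1.0, 3.0],
            ["age", "pM", "combined_resection"],
            forest_config=cl.ForestConfig(ntree=10, seed=2, nodesize=30),
            k=3,
            B=4,
            seed=2,
            causes=(1,),
        )
        assert set(report["model"]) == {"A", "B"}
        assert ((report["c_pooled"] >= 0) & (report["c_pooled"] <= 1)).all()
        assert (report["ci_low"] <= report["ci_high"]).all()
        assert all(len(v) == 3 for v in report["fold_values"])
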