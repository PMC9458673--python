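"""MAPE scoring, target re-scaling, bootstrap contrasts, experiment harness."""

import numpy as np
import pandas as pd
import pytest

from avprofiler import (
    mape,
    paired_bootstrap_compare,
    rescale_targets,
    run_experiment,
)
from avprofiler.evaluation import summarise_mape


class TestMape:
    def test_perfect_prediction_is_zero(self):
        assert mape([1.0, -2.0], [1.0, -2.0]) == 0.0

    def test_hand_example(self):
        assert mape([2.0], [1.0]) == pytest.approx(0.5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(20)
        yt = rng.uniform(1, 5, 100)
        yp = yt + rng.normal(0, 0.5, 100)
        oracle = sum(abs((t - p) / t) for t, p in zip(yt, yp)) / 100
        assert mape(yt, yp) == pytest.approx(oracle, rel=1e-12)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="zero ground truth"):
            mape([1.0, 0.0], [1.0, 1.0])


class TestRescaleTargets:
    def test_identical_series_identity_map(self):
        s = np.array([1.0, 2.0, 3.0])
        mapped, m = rescale_targets(s, s)
        np.testing.assert_allclose(mapped, s)
        assert m.scale == pytest.approx(1.0)
        assert m.offset == pytest.approx(0.0)

    def test_affine_example(self):
        mapped, m = rescale_targets([-0.6, -0.4, -0.5], [4.0, 5.0, 4.2])
        assert m.apply([-0.6])[0] == pytest.approx(4.0)
        assert m.apply([-0.4])[0] == pytest.approx(5.0)
        assert m.apply([-0.5])[0] == pytest.approx(4.5)

    def test_train_range_maps_exactly_and_reapplies_to_test(self):
        rng = np.random.default_rng(21)
        s = rng.normal(-0.5, 0.1, 50)
        b = rng.normal(4.7, 0.4, 50)
        train = np.arange(50) < 40
        mapped, m = rescale_targets(s, b, train_mask=train)
        assert mapped[train].min() == pytest.approx(b[train].min(), rel=1e-12)
        assert mapped[train].max() == pytest.approx(b[train].max(), rel=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescale_targets([1.0, 1.0], [2.0, 3.0])


def _result_frame(players, err, seed=0, task="a"):
    rng = np.random.default_rng(seed)
    rows = []
    for p in players:
        for g in range(6):
            yt = rng.uniform(4, 5)
            rows.append({"player_id": p, "game_id": f"g{g}", "task": task,
                         "target": "intercept", "y_true": yt,
                         "y_pred": yt * (1 + err * rng.standard_normal())})
    return pd.DataFrame(rows)


class TestPairedBootstrap:
    def test_self_comparison_is_null(self):
        a = _result_frame(list("ABCDEFGH"), 0.05)
        rep = paired_bootstrap_compare(a, a.copy(), seed=1)
        assert rep["mean_diff"] == 0.0
        assert rep["p_boot"] >= 0.9

    def test_doubled_errors_detected(self):
        a = _result_frame(list("ABCDEFGHIJ"), 0.05, seed=2)
        b = a.copy()
        b["y_pred"] = b["y_true"] + 2.0 * (b["y_pred"] - b["y_true"])
        rep = paired_bootstrap_compare(b, a, seed=3)
        assert rep["ci_low"] > 0.0
        assert rep["p_boot"] < 0.05

    def test_fixed_seed_reproducible(self):
        a = _result_frame(list("ABCDEFGH"), 0.08, seed=4)
        b = _result_frame(list("ABCDEFGH"), 0.04, seed=5, task="b")
        r1 = paired_bootstrap_compare(a, b, seed=7)
        r2 = paired_bootstrap_compare(a, b, seed=7)
        assert r1 == r2

    def test_too_few_players_refused(self):
        a = _result_frame(list("ABC"), 0.05)
        with pytest.raises(ValueError, match="5 shared players"):
            paired_bootstrap_compare(a, a.copy())


class TestExperiment:
    @pytest.fixture(scope="class")
    def result(self, tiny_season):
        return run_experiment(tiny_season, min_games=8, seed=11)

    def test_all_default_tasks_scored(self, result):
        assert result.config["failures"] == {}
        assert set(result.rows["task"]) == {
            "control", "forecast",
            "ridge-mean-commercial-I", "ridge-exp-commercial-I",
            "ridge-mean-commercial-G", "ridge-exp-commercial-G",
            "ridge-mean-raw-G", "ridge-exp-raw-G",
        }

    def test_every_task_scores_identical_test_keys(self, result):
        keys = {
            task: set(map(tuple, g[["player_id", "game_id", "target"]].to_numpy()))
            for task, g in result.rows.groupby("task")
        }
        ref = keys["control"]
        assert all(k == ref for k in keys.values())

    def test_summary_recomputable_from_rows(self, result):
        summary = summarise_mape(result.rows)
        merged = summary.merge(result.ranking, on=["task", "target"],
                               suffixes=("", "_rank"))
        np.testing.assert_allclose(merged["mape"], merged["mape_rank"], rtol=1e-12)

    def test_rerun_same_seed_identical(self, tiny_season, result):
        again = run_experiment(tiny_season, min_games=8, seed=11)
        pd.testing.assert_frame_equal(result.rows, again.rows)
        pd.testing.assert_frame_equal(result.contrasts, again.contrasts)

    def test_artifacts_written(self, tiny_season, tmp_path_factory):
        out = tmp_path_factory.mktemp("report")
        run_experiment(tiny_season, min_games=8, seed=11,
                       tasks=("control", "forecast"), out_dir=out)
        for name in ("ranking.csv", "mape_rows.csv", "contrasts.csv",
                     "run_config.json", "mape_distribution_slope.png"):
            assert (out / name).exists()


class TestControlTask:
    """Same-game features predicting same-game coefficients."""

    @pytest.fixture(scope="class")
    def tables(self, tiny_season):
        from avprofiler import AVProfileExtractor

        profiles = AVProfileExtractor().fit().transform(
            tiny_season.iter_traces(kind="game")
        )
        return tiny_season.summaries, profiles

    def test_deterministic_and_well_formed(self, tables):
        from avprofiler import run_control_task

        summaries, profiles = tables
        a = run_control_task(summaries, profiles, scope="G")
        b = run_control_task(summaries, profiles, scope="G")
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) == {"player_id", "game_id", "target", "y_true", "y_pred"}
        assert set(a["target"]) == {"slope", "intercept"}

    def test_beats_shuffled_target_ceiling(self, tables):
        """Breaking the feature/target pairing degrades prediction to the
        level of guessing the mean."""
        from avprofiler import mape, run_control_task

        summaries, profiles = tables
        real = run_control_task(summaries, profiles, scope="G")
        rng = np.random.default_rng(0)
        shuffled = profiles.copy()
        for pid, g in profiles.groupby("player_id"):
            idx = g.index.to_numpy()
            perm = rng.permutation(idx)
            shuffled.loc[idx, ["slope", "intercept"]] = profiles.loc[
                perm, ["slope", "intercept"]
            ].to_numpy()
        broken = run_control_task(summaries, shuffled, scope="G")
        for target in ("slope", "intercept"):
            m_real = mape(*real[real["target"] == target][["y_true", "y_pred"]].T.to_numpy())
            m_broken = mape(*broken[broken["target"] == target][["y_true", "y_pred"]].T.to_numpy())
            assert m_real < m_broken

    def test_per_player_scope_excludes_short_histories(self, tables):
        from avprofiler import run_control_task

        summaries, profiles = tables
        out = run_control_task(summaries, profiles, scope="I", min_games=5)
        assert not out.empty
        assert out.groupby("player_id").size().min() >= 1
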