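"""SSE engine, error metrics, bootstrap, and comparison tables."""

import numpy as np
import pandas as pd
import pytest

from bimod.kernels import loglik_oracle, make_grid
from bimod.laplace import FitOptions, fit_laplace
from bimod.simulate import simulate_dataset
from bimod.study import (bootstrap_resample, loglik_profile_table, ree, rmse,
                         run_sse, tail_bound_table)


class TestMetrics:
    def test_ree_examples(self):
        assert ree(1.0, 1.0) == 0.0
        assert ree(0.11, 0.1) == pytest.approx(0.1)
        assert ree(-0.33, -0.3) == pytest.approx(0.1)
        with pytest.raises(ZeroDivisionError):
            ree(1.0, 0.0)

    def test_rmse_examples(self):
        assert rmse([2.0, 2.0, 2.0], 2.0) == 0.0
        assert rmse([0.9, 1.1], 1.0) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            rmse([], 1.0)

    def test_rmse_brute_force(self, rng):
        for _ in range(5):
            v = rng.normal(2.0, 0.3, size=17)
            truth = 2.0
            expected = np.sqrt(np.mean(((v - truth) / truth) ** 2))
            assert rmse(v, truth) == pytest.approx(expected, abs=1e-14)


@pytest.fixture(scope="module")
def tiny_summary(scenarios):
    return run_sse(scenarios["S1"], estimator="laplace", impl="improved",
                   n_replicates=2, base_seed=606, n_subjects=30)


@pytest.fixture(scope="module")
def boot_data(scenarios):
    return simulate_dataset(scenarios["S1"].with_overrides(n_subjects=60), 4)


@pytest.fixture(scope="module")
def profile_table_default():
    return loglik_profile_table()


class TestRunSse:
    def test_bookkeeping(self, tiny_summary):
        assert tiny_summary.n_replicates == 2
        assert len(tiny_summary.seeds) == 2
        assert set(tiny_summary.results["replicate"]) == {0, 1}
        for p in tiny_summary.truth:
            assert len(tiny_summary.ree_values(p)) <= 2
        assert 0.0 <= tiny_summary.success_rate <= 1.0
        assert "success" in tiny_summary.summary()
        assert isinstance(tiny_summary.rmse_table(), pd.Series)

    def test_pipeline_determinism(self, tiny_summary, scenarios):
        again = run_sse(scenarios["S1"], estimator="laplace", impl="improved",
                        n_replicates=2, base_seed=606, n_subjects=30)
        # wall-clock timing is logged but is not part of the scientific output
        pd.testing.assert_frame_equal(tiny_summary.results.drop(columns="runtime_s"),
                                      again.results.drop(columns="runtime_s"))

    def test_explicit_seed_override(self, scenarios):
        s = run_sse(scenarios["S1"], n_replicates=2, n_subjects=25,
                    seeds=[101, 102])
        np.testing.assert_array_equal(s.seeds, [101, 102])
        with pytest.raises(ValueError):
            run_sse(scenarios["S1"], n_replicates=3, seeds=[1, 2])


class TestBootstrap:
    def test_deterministic(self, boot_data):
        data = boot_data
        a = bootstrap_resample(data, 1, seed=9)[0]
        b = bootstrap_resample(data, 1, seed=9)[0]
        assert a.attrs["bootstrap_sources"] == b.attrs["bootstrap_sources"]
        pd.testing.assert_frame_equal(a, b)

    def test_subject_count_and_block_structure(self, boot_data):
        data = boot_data
        for boot in bootstrap_resample(data, 3, seed=1):
            assert boot["ID"].nunique() == 60
            assert list(np.unique(boot["ID"])) == list(range(1, 61))
            # each re-identified subject keeps a full 5-visit block
            assert (boot.groupby("ID").size() == 5).all()

    def test_inclusion_probability(self, boot_data):
        data = boot_data
        n_boot, N = 1000, 60
        reps = bootstrap_resample(data, n_boot, seed=33)
        target_id = 7
        included = sum(target_id in r.attrs["bootstrap_sources"] for r in reps)
        p = 1 - (1 - 1 / N) ** N
        se = np.sqrt(p * (1 - p) / n_boot)
        assert abs(included / n_boot - p) < 3 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_resample(pd.DataFrame(columns=["ID", "TIME", "DV"]), 1, 0)

    def test_paired_ofv_dominance(self, scenarios):
        # improved-kernel converged OFV never exceeds the naive one on the
        # same bootstrap replicate
        data = simulate_dataset(scenarios["S1"].with_overrides(n_subjects=40), 14)
        for boot in bootstrap_resample(data, 2, seed=5):
            boot.attrs["max_score"] = 70
            a = fit_laplace(boot, scenarios["S1"].pop,
                            opts=FitOptions(implementation="improved"))
            b = fit_laplace(boot, scenarios["S1"].pop,
                            opts=FitOptions(implementation="naive"))
            if a.success and b.success:
                assert a.ofv <= b.ofv + 0.01


class TestProfileTable:
    def test_agreement_at_unit_sigma(self, profile_table_default):
        table = profile_table_default
        rows = table[table["sigma"] == 1.0]
        assert (rows["loglik_naive"] - rows["loglik_improved"]).abs().max() < 1e-9

    def test_divergence_at_small_sigma(self, profile_table_default):
        table = profile_table_default
        rows = table[table["sigma"] == 0.01]
        assert (~np.isfinite(rows["loglik_naive"])).any()
        assert np.isfinite(rows["loglik_improved"]).all()

    def test_improved_matches_oracle_on_stress_grid(self):
        g = make_grid(60)
        table = loglik_profile_table(eta_grid=np.arange(-4, 4.001, 0.5))
        for _, row in table[table["sigma"] == 0.01].iterrows():
            ref = loglik_oracle(10, g, row["eta"], 0.01)
            assert row["loglik_improved"] == pytest.approx(ref, rel=1e-6)


class TestTailBoundTable:
    def test_rows_bracket_exact(self):
        t = tail_bound_table(np.linspace(0.5, 10, 39))
        assert (t["lower"] < t["exact"]).all()
        assert (t["exact"] <= t["upper"]).all()

    def test_gap_shrinks_and_tight_by_two(self):
        t = tail_bound_table(np.linspace(0.5, 10, 39))
        gap = (t["upper"] - t["lower"]).to_numpy()
        assert np.all(np.diff(gap) < 0)
        # by z = 2 the bracket is already a few percent wide on the log scale
        gap2 = float(t.loc[(t["z"] - 2.0).abs().idxmin(), "upper"]
                     - t.loc[(t["z"] - 2.0).abs().idxmin(), "lower"])
        assert gap2 < 0.06

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            tail_bound_table([-1.0, 2.0])
        with pytest.raises(ValueError):
            tail_bound_table([50.0])
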