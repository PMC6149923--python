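import numpy as np
import pandas as pd
import pytest

from synabm.calibration import (CollinearDesignError, DoseResponseTable,
                                bootstrap_mean, build_global_objective,
                                crossvalidate, eq16_weight, fit_global,
                                fit_local, merate_from_absorbance,
                                particle_swarm, significance_test)
from synabm.synthetic_data import GeneratorSpec, generate_table


def make_table(theta=(0.1, 0.005, 0.002), noise_sd=0.0, seed=0):
    return generate_table(GeneratorSpec("pair", theta=theta,
                                        noise_sd=noise_sd, seed=seed))


class TestBootstrapMean:
    def test_constant_samples_exact(self):
        assert bootstrap_mean([0.4, 0.4, 0.4], B=100, seed=1) == 0.4

    def test_consistency_with_plain_mean(self, rng):
        x = rng.normal(0.5, 0.1, size=30)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(bootstrap_mean(x, B=10_000, seed=2) - x.mean()) < 2 * se

    def test_seeded_reproducibility(self):
        x = [0.1, 0.5, 0.9]
        assert bootstrap_mean(x, seed=7) == bootstrap_mean(x, seed=7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean([], B=10)


class TestMerate:
    @pytest.mark.parametrize("drug, control, expected", [
        (1.0, 1.0, 0.0), (0.0, 1.0, 1.0), (0.25, 0.5, 0.5),
    ])
    def test_absorbance_ratio(self, drug, control, expected):
        assert merate_from_absorbance(drug, control) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            merate_from_absorbance(0.5, 0.0)


class TestDoseResponseTable:
    def test_percent_autodetection(self, tmp_path):
        frame = pd.DataFrame({
            "pair": "p", "dose1_uM": [0.0, 10.0, 20.0],
            "dose2_uM": [0.0, 5.0, 10.0],
            "rep1": [17.0, 25.0, 33.0], "rep2": [16.0, 26.0, 31.0],
        })
        path = tmp_path / "t.csv"
        frame.to_csv(path, index=False)
        table = DoseResponseTable.from_csv(path)
        assert table.replicates.max() <= 1.0
        assert table.replicate_means()[0] == pytest.approx(0.165)

    def test_roundtrip(self, tmp_path):
        table = make_table(noise_sd=0.02, seed=3)
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = DoseResponseTable.from_csv(path)
        np.testing.assert_allclose(back.replicates, table.replicates)

    def test_invalid_fractions_rejected(self):
        frame = pd.DataFrame({"dose1_uM": [0.0, 1.0, 2.0],
                              "dose2_uM": [0.0, 1.0, 2.0],
                              "rep1": [0.1, 1.4, 0.2]})
        with pytest.raises(ValueError):
            DoseResponseTable(frame, "bad")


class TestFitLocal:
    def test_noiseless_recovery(self):
        table = make_table(theta=(0.1, 0.005, 0.002), noise_sd=0.0)
        fit = fit_local(table)
        np.testing.assert_allclose(fit.theta, [0.1, 0.005, 0.002], atol=1e-4)
        assert fit.loss < 1e-10
        assert fit.p_value < 1e-6

    def test_matches_least_squares_oracle(self, rng):
        table = make_table(noise_sd=0.03, seed=5)
        y = table.replicate_means()
        X = np.column_stack([np.ones(table.m), table.doses])
        oracle, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit = fit_local(table)
        np.testing.assert_allclose(fit.theta, oracle, atol=1e-7)

    def test_doubling_response_doubles_theta(self):
        table = make_table(theta=(0.05, 0.002, 0.001), noise_sd=0.01, seed=8)
        fit = fit_local(table)
        doubled = fit_local(table, merate=2 * table.replicate_means())
        np.testing.assert_allclose(doubled.theta, 2 * fit.theta, atol=1e-8)

    def test_zero_dose_design_signals_collinearity(self):
        frame = pd.DataFrame({"dose1_uM": np.zeros(6),
                              "dose2_uM": np.zeros(6),
                              "rep1": np.full(6, 0.3)})
        with pytest.raises(CollinearDesignError):
            fit_local(DoseResponseTable(frame, "degenerate"))

    def test_too_few_rows_rejected(self):
        frame = pd.DataFrame({"dose1_uM": [0.0, 1.0], "dose2_uM": [1.0, 0.0],
                              "rep1": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_local(DoseResponseTable(frame, "tiny"))


class TestParticleSwarm:
    def test_sphere_recovery(self):
        truth = np.array([0.3, 0.7, 1.2])
        best, best_f, _ = particle_swarm(
            lambda x: float(((x - truth) ** 2).sum()),
            bounds=[(0, 1), (0, 1), (0, 2)], swarm_size=20, iters=200,
            seed=3)
        np.testing.assert_allclose(best, truth, atol=1e-3)

    def test_global_best_history_non_increasing(self):
        _, _, history = particle_swarm(
            lambda x: float((x ** 2).sum()), bounds=[(-5, 5)] * 3,
            swarm_size=10, iters=50, seed=1)
        assert (np.diff(history) <= 0).all()

    def test_frozen_single_particle_returns_initialization(self):
        calls = []

        def objective(x):
            calls.append(x.copy())
            return float((x ** 2).sum())

        best, _, _ = particle_swarm(objective, bounds=[(0, 1), (0, 1)],
                                    swarm_size=1, iters=5, seed=4,
                                    w=0.0, c_cog=0.0, c_soc=0.0)
        np.testing.assert_allclose(best, calls[0])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            particle_swarm(lambda x: 0.0, bounds=[])
        with pytest.raises(ValueError):
            particle_swarm(lambda x: 0.0, bounds=[(1.0, 0.0)])


class TestFitGlobal:
    def test_analytic_surrogate_recovery(self):
        """With a cheap analytic stand-in for the simulator, the swarm's
        optimum beats the truth's own objective up to the noise floor."""
        truth = (0.2, 0.1, 1.0)

        def surrogate(c1, c2, lam, d1, d2):
            return min(1.0, 0.05 + c1 * 0.3 + c2 * (0.002 * d1 + 0.004 * d2)
                       + 0.05 * lam)

        spec = GeneratorSpec("pair", theta=(0.05, 0.002, 0.004),
                             noise_sd=0.01, seed=6)
        means = np.array([surrogate(*truth, d1, d2)
                          for d1, d2 in spec.dose_grid])
        rng = np.random.default_rng(6)
        reps = np.clip(means[:, None] + rng.normal(0, 0.01, (30, 3)), 0, 1)
        frame = pd.DataFrame({"dose1_uM": spec.dose_grid[:, 0],
                              "dose2_uM": spec.dose_grid[:, 1]})
        for k in range(3):
            frame[f"rep{k+1}"] = reps[:, k]
        table = DoseResponseTable(frame, "pair")

        fit = fit_global(table, surrogate, swarm_size=15, iters=40, seed=2)
        objective = build_global_objective(table, surrogate)
        assert fit.objective <= objective(np.array(truth)) + 1e-9

    def test_weight_definition(self):
        assert eq16_weight(np.array([0.2, 0.5, 0.4])) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            eq16_weight(np.zeros(3))


class TestCrossvalidate:
    def test_perfect_simulator_gives_zero_re(self):
        table = make_table(noise_sd=0.0)
        y = dict(zip(map(tuple, table.doses), table.replicate_means()))
        res = crossvalidate({"pair": table}, fit=lambda t: None,
                            predict=lambda m, d1, d2: y[(d1, d2)])
        assert res["pair"].mean_abs_re == pytest.approx(0.0, abs=1e-12)

    def test_uniform_overshoot_gives_mean_re(self):
        table = make_table(theta=(0.1, 0.005, 0.002), noise_sd=0.0)
        y = dict(zip(map(tuple, table.doses), table.replicate_means()))
        res = crossvalidate({"pair": table}, fit=lambda t: None,
                            predict=lambda m, d1, d2: 1.1 * y[(d1, d2)])
        assert res["pair"].mean_abs_re == pytest.approx(0.1, abs=1e-9)

    def test_zero_merate_rows_excluded_with_warning(self):
        frame = pd.DataFrame({"dose1_uM": np.arange(6.0),
                              "dose2_uM": np.arange(6.0)[::-1],
                              "rep1": [0.0, 0.2, 0.0, 0.3, 0.4, 0.5]})
        table = DoseResponseTable(frame, "z")
        with pytest.warns(RuntimeWarning):
            res = crossvalidate({"z": table}, fit=lambda t: None,
                                predict=lambda m, d1, d2: 0.1)
        assert res["z"].n_excluded >= 1

    def test_loocv_protocol_tests_every_row(self):
        table = make_table(noise_sd=0.01, seed=2)
        y = table.replicate_means()
        res = crossvalidate(
            {"pair": table},
            fit=lambda t: None,
            predict=lambda m, d1, d2: 0.5,
            protocol="loocv")
        assert len(res["pair"].relative_errors) == (y > 0).sum()


class TestSignificanceTest:
    def test_identical_series_maximal_p(self):
        x = np.linspace(0.1, 0.9, 20)
        assert significance_test(x, x) == 1.0
        assert significance_test(x, x, method="ttest") == 1.0

    def test_detects_large_shift(self, rng):
        noise = 0.02
        exp = rng.uniform(0.2, 0.8, size=30)
        sim = exp + 10 * noise + rng.normal(0, noise, size=30)
        assert significance_test(sim, exp) < 0.001

    def test_pairing_order_invariance(self, rng):
        exp = rng.uniform(0.2, 0.8, size=25)
        sim = exp + rng.normal(0, 0.05, size=25)
        p = significance_test(sim, exp)
        perm = rng.permutation(25)
        assert significance_test(sim[perm], exp[perm]) == pytest.approx(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            significance_test([0.1, 0.2], [0.1])
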