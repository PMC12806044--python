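"""Multi-condition objective and the least-squares fitting machinery."""

import numpy as np
import pandas as pd
import pytest

import labferm as lf
from labferm.estimation import (
    FIT_PARAMETER_NAMES,
    BatchFermentationModel,
    ExperimentTable,
    objective,
)
from labferm.simulate import InitialConditions
from labferm.synthetic import NoiseSpec, synthesize

PRESET = lf.get_preset("bulgaricus")
TRUTH = PRESET.params
TRUTH_VALUES = {
    **{k: getattr(TRUTH, k) for k in FIT_PARAMETER_NAMES[:-1]},
    "Q0": PRESET.Q0,
}


def noiseless_suite(S0s=(26.0, 43.0), times=None):
    times = times or tuple(np.linspace(1.0, 24.0, 12))
    return [
        synthesize(
            TRUTH,
            InitialConditions(S0=S0, Q0=PRESET.Q0, X0=PRESET.X0, A0=0.0),
            NoiseSpec(cv=0.0, sampling_times=times),
        )
        for S0 in S0s
    ]


class TestExperimentTable:
    def test_validation_rejects_bad_tables(self):
        good = pd.DataFrame({
            "time_h": [1.0, 2.0], "S_g_per_dm3": [25.0, 20.0],
            "X_g_per_dm3": [0.05, 0.2], "A_g_per_dm3": [0.5, 2.0],
        })
        ExperimentTable(S0=26.0, X0=0.02, A0=0.0, observations=good)
        with pytest.raises(ValueError):
            ExperimentTable(26.0, 0.02, 0.0, good.iloc[::-1].reset_index(drop=True))
        with pytest.raises(ValueError):
            bad = good.copy()
            bad.loc[0, "S_g_per_dm3"] = -1.0
            ExperimentTable(26.0, 0.02, 0.0, bad)
        with pytest.raises(ValueError):
            ExperimentTable(26.0, 0.02, 0.0, good.drop(columns=["A_g_per_dm3"]))
        with pytest.raises(ValueError):
            ExperimentTable(26.0, 0.02, 0.0, good.iloc[:0])

    def test_partial_observations_allowed_and_counted(self):
        df = pd.DataFrame({
            "time_h": [1.0, 2.0], "S_g_per_dm3": [25.0, np.nan],
            "X_g_per_dm3": [np.nan, 0.2], "A_g_per_dm3": [0.5, 2.0],
        })
        table = ExperimentTable(26.0, 0.02, 0.0, df)
        assert table.n_observed == 4

    def test_csv_round_trip(self, tmp_path):
        table = noiseless_suite()[0]
        path = tmp_path / "exp.csv"
        table.to_csv(path)
        back = ExperimentTable.from_csv(path)
        assert back.S0 == table.S0 and back.X0 == table.X0
        pd.testing.assert_frame_equal(back.observations, table.observations)
        assert back.metadata["synthetic"] is True

    def test_headerless_csv_infers_from_t0_row(self, tmp_path):
        path = tmp_path / "plain.csv"
        path.write_text(
            "time_h,S_g_per_dm3,X_g_per_dm3,A_g_per_dm3\n"
            "0,26,0.02,0\n4,20,0.3,4.2\n"
        )
        table = ExperimentTable.from_csv(path)
        assert table.S0 == 26.0 and table.X0 == 0.02 and table.A0 == 0.0


class TestObjective:
    def test_self_consistency_is_numerically_zero(self):
        datasets = noiseless_suite()
        F = objective(TRUTH, PRESET.Q0, datasets)
        assert F <= 1e-10

    def test_single_residual_hand_sum(self):
        # one dataset, one row, only X observed, off by exactly 0.5
        init = InitialConditions(S0=26.0, Q0=PRESET.Q0, X0=PRESET.X0, A0=0.0)
        traj = lf.simulate(TRUTH, init, t_end=8.0)
        X_sim = float(np.interp(8.0, traj.times, traj.X))
        df = pd.DataFrame({
            "time_h": [8.0], "S_g_per_dm3": [np.nan],
            "X_g_per_dm3": [X_sim + 0.5], "A_g_per_dm3": [np.nan],
        })
        table = ExperimentTable(26.0, PRESET.X0, 0.0, df)
        assert objective(TRUTH, PRESET.Q0, [table]) == pytest.approx(0.25, rel=1e-6)

    def test_perturbing_mu_max_increases_objective(self):
        datasets = noiseless_suite()
        F0 = objective(TRUTH, PRESET.Q0, datasets)
        for factor in (0.9, 0.97, 1.03, 1.1):
            F = objective(TRUTH.replace(mu_max=factor * TRUTH.mu_max),
                          PRESET.Q0, datasets)
            assert F > F0

    def test_invariant_to_dataset_ordering_and_splitting(self):
        datasets = noiseless_suite()
        F_fwd = objective(TRUTH, PRESET.Q0, datasets)
        F_rev = objective(TRUTH, PRESET.Q0, datasets[::-1])
        assert F_fwd == F_rev
        # split one table's rows into two tables with the same initials
        t = datasets[0]
        obs = t.observations
        halves = [
            ExperimentTable(t.S0, t.X0, t.A0, obs.iloc[:6].reset_index(drop=True)),
            ExperimentTable(t.S0, t.X0, t.A0, obs.iloc[6:].reset_index(drop=True)),
        ]
        F_split = objective(TRUTH, PRESET.Q0, halves + [datasets[1]])
        assert F_split == pytest.approx(F_fwd, abs=1e-14)

    def test_failed_simulation_penalised_not_raised(self):
        datasets = noiseless_suite()
        bad = TRUTH.replace(mu_max=4.9, nu=4.9)  # extreme but in bounds
        F = objective(bad, 9.9, datasets)
        assert np.isfinite(F)


class TestFit:
    def test_noop_fit_returns_fixed_values(self):
        datasets = noiseless_suite()
        model = BatchFermentationModel(datasets, free=[], fixed=TRUTH_VALUES)
        res = model.fit()
        assert res.F == pytest.approx(objective(TRUTH, PRESET.Q0, datasets), abs=1e-12)
        assert res.estimates == TRUTH_VALUES
        assert res.converged

    def test_free_and_fixed_must_cover_all_parameters(self):
        datasets = noiseless_suite()
        with pytest.raises(ValueError):
            BatchFermentationModel(datasets, free=["mu_max"], fixed={})
        with pytest.raises(ValueError):
            BatchFermentationModel(datasets, free=["bogus"], fixed=TRUTH_VALUES)

    def test_subset_recovery_on_noiseless_data(self):
        datasets = noiseless_suite()
        free = ["mu_max", "gamma_XS", "Q0"]
        fixed = {k: v for k, v in TRUTH_VALUES.items() if k not in free}
        res = BatchFermentationModel(datasets, free=free, fixed=fixed).fit(
            seed=0, n_starts=4
        )
        for name in free:
            assert res.estimates[name] == pytest.approx(
                TRUTH_VALUES[name], rel=1e-3
            )
        assert res.F < 1e-8

    def test_fit_is_bit_reproducible(self):
        datasets = noiseless_suite()
        free = ["mu_max", "Q0"]
        fixed = {k: v for k, v in TRUTH_VALUES.items() if k not in free}
        kwargs = dict(free=free, fixed=fixed)
        r1 = BatchFermentationModel(datasets, **kwargs).fit(seed=3, n_starts=3)
        r2 = BatchFermentationModel(datasets, **kwargs).fit(seed=3, n_starts=3)
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.F == r2.F

    def test_profile_of_objective_is_locally_convex(self):
        datasets = noiseless_suite()
        for name in FIT_PARAMETER_NAMES:
            v0 = TRUTH_VALUES[name]
            if v0 == 0.0:  # one-sided for parameters at the zero boundary
                grid = np.linspace(0.0, 0.2, 11)
            else:
                grid = v0 * np.linspace(0.9, 1.1, 21)
            F = []
            for v in grid:
                values = dict(TRUTH_VALUES)
                values[name] = v
                Q0 = values.pop("Q0")
                F.append(objective(lf.ModelParameters(**values), Q0, datasets))
            F = np.array(F)
            i_min = int(np.argmin(F))
            assert grid[i_min] == pytest.approx(v0, abs=grid[1] - grid[0])
            # strictly decreasing into the minimum, increasing out of it
            assert np.all(np.diff(F[: i_min + 1]) <= 0)
            assert np.all(np.diff(F[i_min:]) >= 0)

    def test_summary_and_save(self, tmp_path):
        datasets = noiseless_suite()
        free = ["mu_max", "Q0"]
        fixed = {k: v for k, v in TRUTH_VALUES.items() if k not in free}
        res = BatchFermentationModel(datasets, free=free, fixed=fixed).fit(
            seed=0, n_starts=2
        )
        text = res.summary()
        assert "mu_max" in text and "free" in text and "fixed" in text
        out = tmp_path / "fit.json"
        res.save(out)
        assert out.exists() and out.with_suffix(".txt").exists()
        import json

        payload = json.loads(out.read_text())
        assert payload["estimates"]["mu_max"] == pytest.approx(TRUTH.mu_max, rel=1e-3)

    def test_standard_errors_reported_for_noisy_fit(self):
        suite = lf.make_paper_like_suite("bulgaricus", seed=5, cv=0.05)
        free = ["mu_max", "Q0"]
        fixed = {k: v for k, v in TRUTH_VALUES.items() if k not in free}
        res = BatchFermentationModel(suite, free=free, fixed=fixed).fit(
            seed=0, n_starts=2
        )
        assert res.bse["mu_max"] > 0
        assert np.isfinite(res.bse["Q0"])
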