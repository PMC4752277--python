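"""Sequential estimation pipeline: per-stage fits, bootstrap, assembly."""

import numpy as np
import pandas as pd
import pytest

from gutphage import (
    EstimationError,
    FecalObservationSet,
    ModelParameters,
    PopulationState,
    ScenarioConfig,
    bootstrap_ci,
    equilibrium,
    estimate_all,
    fit_growth,
    fit_induction_latency,
    fit_lysogenization,
    generate_mouse_experiment,
    simulate,
    solve_adsorption,
)
from gutphage.observations import merge_observation_sets

GROWTH_TIMES = (0.0, 6.0, 24.0, 30.0, 48.0, 72.0)


def _mono(params, seed=0, n_mice=3, noise_cv=0.0, initial_cv=0.0, times=GROWTH_TIMES):
    config = ScenarioConfig(
        scenario="mono", n_mice=n_mice, sample_times=times, noise_cv=noise_cv, initial_cv=initial_cv, seed=seed
    )
    return generate_mouse_experiment(config, params)


def _lamb(params, seed=0, n_mice=3, noise_cv=0.0, initial_cv=0.0, times=(0.0, 6.0, 24.0, 48.0, 72.0, 96.0)):
    config = ScenarioConfig(
        scenario="lamB_competition", n_mice=n_mice, sample_times=times, noise_cv=noise_cv, initial_cv=initial_cv, seed=seed
    )
    return generate_mouse_experiment(config, params)


def _competition(params, times=(0.0, 36.0, 48.0), n_mice=1, noise_cv=0.0, initial_cv=0.0, seed=0):
    groups = [
        generate_mouse_experiment(
            ScenarioConfig(
                scenario="wt_competition", n_mice=n_mice, ratio=ratio, sample_times=times,
                noise_cv=noise_cv, initial_cv=initial_cv, seed=seed + i,
            ),
            params,
        )
        for i, ratio in enumerate(("1:1", "1:10", "1:100"))
    ]
    return merge_observation_sets(groups)


class TestGrowthFit:
    def test_noiseless_recovery(self, params):
        fit = fit_growth(_mono(params))
        assert fit.estimates["r"] == pytest.approx(params.r, rel=1e-4)
        assert fit.estimates["k"] == pytest.approx(params.k, rel=1e-4)

    def test_scale_equivariance(self, params):
        """Scaling all counts by c scales k by c and leaves r unchanged."""
        obs = _mono(params)
        scaled_data = obs.data.assign(count_per_g=obs.data["count_per_g"] * 7.0)
        scaled = FecalObservationSet(scaled_data, scenario="mono", detection_limit=obs.detection_limit)
        base, shifted = fit_growth(obs), fit_growth(scaled)
        assert shifted.estimates["r"] == pytest.approx(base.estimates["r"], rel=1e-6)
        assert shifted.estimates["k"] == pytest.approx(7.0 * base.estimates["k"], rel=1e-6)

    def test_noisy_recovery_rate_across_seeds(self, params):
        """CV 0.2, 4 mice, 6 time points: r lands in [1.0, 1.2] in >= 90% of seeds."""
        hits = 0
        for seed in range(100):
            obs = _mono(params, seed=seed, n_mice=4, noise_cv=0.2, initial_cv=0.3)
            hits += 1.0 <= fit_growth(obs, n_starts=1).estimates["r"] <= 1.2
        assert hits >= 90

    def test_plateau_only_data_flags_r(self, params):
        obs = _mono(params, times=(0.0, 6.0, 12.0))
        plateau = obs.data.copy()
        plateau["count_per_g"] = params.k * (1 - params.d / params.r)
        flat = FecalObservationSet(plateau, scenario="mono", detection_limit=obs.detection_limit)
        fit = fit_growth(flat)
        assert fit.diagnostics.get("r_non_identifiable") is True

    def test_monotone_information_in_window(self, params):
        narrow = fit_growth(_mono(params, times=(0.0, 6.0, 24.0)))
        wide = fit_growth(_mono(params))
        err = lambda fit: abs(fit.estimates["r"] - params.r) / params.r
        assert err(wide) <= err(narrow) + 1e-6


class TestInductionLatencyFit:
    def test_noiseless_recovery(self, params):
        fit = fit_induction_latency(_lamb(params), d=params.d, r=params.r, k=params.k)
        assert fit.estimates["x"] == pytest.approx(params.x, rel=0.01)
        assert fit.estimates["l"] == pytest.approx(params.l, rel=0.05)

    def test_zero_induction_generator(self, params):
        quiet = params.replace(x=0.0, y=1.0)
        fit = fit_induction_latency(_lamb(quiet, n_mice=2), d=params.d, r=params.r, k=params.k)
        assert fit.estimates["x"] < 1e-4
        assert fit.diagnostics.get("q_all_censored") is True

    def test_objective_surface_minimum_at_generating_pair(self, params):
        """Independent grid scan of the log10 SSE over (x, l)."""
        obs = _lamb(params, n_mice=1)
        sub = obs.data[(~obs.data["censored"]) & obs.data["compartment"].isin(["L", "S_lineage", "Q"])]
        times = np.sort(sub["time_h"].unique())
        grid_t = times if times[0] == 0 else np.concatenate([[0.0], times])
        init = PopulationState(S=1e6, L=1e6)

        xs = np.linspace(0.004, 0.028, 13)  # includes 0.016
        ls = np.linspace(0.2, 1.4, 13)  # includes 0.8
        sse = np.empty((13, 13))
        for i, x in enumerate(xs):
            for j, l in enumerate(ls):
                p = ModelParameters(d=params.d, r=params.r, k=params.k, x=x, l=l, y=1.0, a=0.0, g=0.0)
                traj = simulate(p, init, grid_t)
                pred = {"L": traj.L, "S_lineage": traj.S + traj.SL, "Q": np.maximum(traj.Q, 1e-3)}
                err = 0.0
                for _, row in sub.iterrows():
                    t_idx = np.searchsorted(grid_t, row["time_h"])
                    err += (np.log10(pred[row["compartment"]][t_idx]) - np.log10(row["count_per_g"])) ** 2
                sse[i, j] = err
        i_min, j_min = np.unravel_index(sse.argmin(), sse.shape)
        assert xs[i_min] == pytest.approx(0.016, abs=1e-12)
        assert ls[j_min] == pytest.approx(0.8, abs=1e-12)


class TestAdsorptionInversion:
    def test_recovers_a_from_model_equilibrium(self, params, equal_start):
        eq = equilibrium(params, equal_start)
        sol = solve_adsorption(params.y, V_star=eq.V, Q_star=eq.Q, N_star=eq.N, l=params.l, d=params.d)
        assert sol.a == pytest.approx(2.6e-9, rel=0.01)
        assert not sol.clipped

    def test_balanced_production_gives_zero(self, params):
        # y l Q* = d V*: production exactly offsets washout, no adsorption term
        q, v = 1e6, 1e6 * params.y * params.l / params.d
        sol = solve_adsorption(params.y, V_star=v, Q_star=q, N_star=1e9, l=params.l, d=params.d)
        assert sol.a == 0.0

    def test_roughly_linear_in_burst_size(self, params, equal_start):
        eq = equilibrium(params, equal_start)
        one = solve_adsorption(params.y, eq.V, eq.Q, eq.N, l=params.l, d=params.d).a
        two = solve_adsorption(2 * params.y, eq.V, eq.Q, eq.N, l=params.l, d=params.d).a
        assert two / one == pytest.approx(2.0, rel=0.05)

    def test_negative_inversion_clipped_and_flagged(self, params):
        sol = solve_adsorption(params.y, V_star=1e9, Q_star=1.0, N_star=1e9, l=params.l, d=params.d)
        assert sol.a == 0.0 and sol.clipped

    def test_undefined_without_phage(self, params):
        with pytest.raises(EstimationError):
            solve_adsorption(params.y, V_star=0.0, Q_star=1e6, N_star=1e9)


class TestLysogenizationFit:
    def test_noiseless_recovery(self, params):
        fit = fit_lysogenization(_competition(params), params.replace(g=0.5))
        assert fit.estimates["g"] == pytest.approx(0.19, rel=0.02)

    def test_boundary_generator_all_lysogenize(self, params):
        comp = _competition(params.replace(g=1.0))
        fit = fit_lysogenization(comp, params.replace(g=0.5))
        assert fit.estimates["g"] > 0.98

    def test_objective_unimodal_in_g(self, params):
        """Independent grid scan: single interior minimum at the true value."""
        comp = _competition(params)
        targets = []
        for _, rows in comp.data.groupby("mouse_id"):
            by = {(row["compartment"], row["time_h"]): row["count_per_g"] for _, row in rows.iterrows()}
            targets.append((by[("L", 0.0)], by[("S_lineage", 0.0)], by[("L", 36.0)] / by[("S_lineage", 36.0)]))
        gs = np.concatenate([np.linspace(0.01, 0.99, 12), [0.19]])
        gs.sort()
        sse = []
        for g in gs:
            err = 0.0
            for l0, s0, obs_ratio in targets:
                traj = simulate(params.replace(g=g), PopulationState(S=s0, L=l0), np.array([0.0, 36.0]))
                model_ratio = traj.L[-1] / (traj.S[-1] + traj.SL[-1])
                err += (np.log10(model_ratio) - np.log10(obs_ratio)) ** 2
            sse.append(err)
        sse = np.array(sse)
        assert gs[sse.argmin()] == pytest.approx(0.19)
        sign_changes = np.sum(np.diff(np.sign(np.diff(sse))) != 0)
        assert sign_changes == 1  # unimodal on the grid

    def test_no_observation_near_fit_time_errors(self, params):
        comp = _competition(params, times=(0.0, 6.0, 96.0))
        with pytest.raises(EstimationError, match="96"):
            fit_lysogenization(comp, params, fit_time=36.0, time_tol=10.0)


class TestBootstrap:
    def test_zero_noise_interval_degenerates(self, params):
        obs = _mono(params, n_mice=3)
        ci, n_failed = bootstrap_ci(lambda o: fit_growth(o, n_starts=1), obs, n_boot=30, seed=5)
        lo, hi = ci["r"]
        assert n_failed == 0
        assert (hi - lo) < 0.01 * params.r

    def test_deterministic_given_seed_and_ordered(self, params):
        obs = _mono(params, n_mice=4, noise_cv=0.2, initial_cv=0.3, seed=3)
        run = lambda: bootstrap_ci(lambda o: fit_growth(o, n_starts=1), obs, n_boot=40, seed=11)[0]
        first, second = run(), run()
        assert first == second
        for lo, hi in first.values():
            assert lo <= hi

    def test_needs_three_mice(self, params):
        with pytest.raises(EstimationError):
            bootstrap_ci(fit_growth, _mono(params, n_mice=2), n_boot=10, seed=0)


class TestEstimateAll:
    def test_missing_dataset_names_blocked_stage(self, params, noiseless_bundle):
        partial = {"mono": noiseless_bundle["mono"], "competition": noiseless_bundle["competition"]}
        with pytest.raises(EstimationError, match="stage 2"):
            estimate_all(partial)

    def test_mouse_relabeling_leaves_estimates_unchanged(self, params, noiseless_bundle):
        shuffled = dict(noiseless_bundle)
        renamed = noiseless_bundle["mono"].data.copy()
        mapping = {m: f"zz{i}" for i, m in enumerate(reversed(sorted(renamed["mouse_id"].unique())))}
        renamed["mouse_id"] = renamed["mouse_id"].map(mapping)
        shuffled["mono"] = FecalObservationSet(
            renamed, scenario="mono", detection_limit=noiseless_bundle["mono"].detection_limit
        )
        a = estimate_all(noiseless_bundle)
        b = estimate_all(shuffled)
        for name in ("r", "k", "x", "l", "a", "g"):
            assert b.estimates[name] == pytest.approx(a.estimates[name], rel=1e-9)
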