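"""Sequential calibration of the gut model from fecal observation sets.

The eight model parameters separate into four groups that can be estimated
sequentially, each from the dataset in which it dominates the dynamics:

1. growth: r and k from monocolonization series (d fixed a priori from
   gut transit measurements),
2. induction/latency: x and l from receptor-less (LamB-) competitions in
   which latent cells Q are counted and adsorption is off,
3. adsorption: a from the free-virus equilibrium balance, given the burst
   size y measured in vitro,
4. lysogenization: g from the lysogen/susceptible ratio in wild-type
   competitions.

All residuals are computed on log10 densities (plating spans decades and its
noise is multiplicative).  Counts recorded at the detection limit are treated
as censored and excluded from residuals.  Confidence intervals come from
case-resampling mice with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .model import ModelParameters, PopulationState, simulate
from .observations import FecalObservationSet

__all__ = [
    "FitResult",
    "EstimationError",
    "fit_growth",
    "fit_induction_latency",
    "solve_adsorption",
    "AdsorptionSolution",
    "fit_lysogenization",
    "bootstrap_ci",
    "estimate_all",
]


class EstimationError(RuntimeError):
    """An estimation stage could not run or did not converge."""


@dataclass
class FitResult:
    """Point estimates with provenance.

    ``estimates`` maps parameter names to values (a subset of the eight model
    parameters, or all of them for the full pipeline); ``ci95`` holds
    per-parameter (lower, upper) bootstrap bounds where computed.
    """

    estimates: dict[str, float]
    objective: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    data_ref: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective (residual sum of squares) must be >= 0")
        for name, (lo, hi) in self.ci95.items():
            est = self.estimates.get(name)
            if est is not None and not (lo <= est <= hi or math.isclose(lo, est) or math.isclose(hi, est)):
                raise ValueError(f"ci95 for {name} ({lo}, {hi}) does not bracket the estimate {est}")


# ---------------------------------------------------------------------------
# stage 1: growth (r, k)
# ---------------------------------------------------------------------------


def _logistic_with_dilution(t: np.ndarray, n0: float, r: float, k: float, d: float) -> np.ndarray:
    """Closed form of dN/dt = r N (1 - N/k) - d N.

    Equivalent to a logistic with effective rate r - d and effective capacity
    k (1 - d/r); washout decay when r <= d.
    """
    rho = r - d
    if rho <= 0:
        return n0 * np.exp(rho * t)
    keff = k * (1.0 - d / r)
    return keff / (1.0 + (keff / n0 - 1.0) * np.exp(-rho * t))


def _uncensored(obs: FecalObservationSet, compartment: str):
    sub = obs.counts(compartment, include_censored=False)
    if sub.empty:
        raise EstimationError(f"no uncensored {compartment} observations to fit")
    return sub


def fit_growth(mono_obs: FecalObservationSet, d: float = 0.25, n_starts: int = 5) -> FitResult:
    """Estimate r and k from monocolonization series (1-D logistic + dilution).

    Squared residuals of log10 density are minimized jointly over mice with
    shared (r, k); each mouse's time-0 count is its initial condition.
    ``n_starts`` controls the multi-start guard against local minima (the
    closed-form objective is well behaved, so bootstrap refits can use 1).
    """
    comps = [c for c in mono_obs.compartments if c != "V"]
    if len(comps) != 1:
        raise EstimationError(f"monocolonization data must contain a single bacterial lineage, found {comps}")
    sub = _uncensored(mono_obs, comps[0])

    groups = []  # (times, log10 counts, n0) per mouse
    for mouse, rows in sub.groupby("mouse_id"):
        rows = rows.sort_values("time_h")
        t0 = rows[rows["time_h"] == 0.0]
        if t0.empty:
            raise EstimationError(f"mouse {mouse!r} lacks an uncensored time-0 density")
        groups.append((rows["time_h"].to_numpy(), np.log10(rows["count_per_g"].to_numpy()), float(t0["count_per_g"].iloc[0])))
    n_points = sum(len(t) for t, _, _ in groups)
    if n_points < 4:
        raise EstimationError("need at least 4 observations spanning growth and plateau")

    top = max(c.max() for _, c, _ in groups)
    early = min(c[0] for _, c, _ in groups)
    r_identifiable = (top - early) > 0.5  # data not entirely at plateau

    def residuals(theta: np.ndarray) -> np.ndarray:
        r, log10k = theta
        k = 10.0**log10k
        out = []
        for times, logc, n0 in groups:
            pred = _logistic_with_dilution(times, n0, r, k, d)
            out.append(np.log10(np.maximum(pred, 1e-300)) - logc)
        return np.concatenate(out)

    k0 = top  # plateau log10 is close to log10 k(1-d/r)
    starts = [(1.0, k0), (0.5, k0), (2.0, k0), (1.0, k0 + 1.0), (0.7, k0 - 0.5)]
    best = None
    for r0, lk0 in starts[: max(1, n_starts)]:
        sol = least_squares(
            residuals,
            x0=[r0, lk0],
            bounds=([d + 1e-8, 3.0], [10.0, 12.0]),
            xtol=1e-12,
            ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise EstimationError(f"growth fit did not converge: {getattr(best, 'message', 'no solution')}")

    r_hat, k_hat = float(best.x[0]), float(10.0 ** best.x[1])
    diagnostics = {"n_points": n_points, "n_mice": len(groups), "optimizer_status": best.status}
    if not r_identifiable:
        diagnostics["r_non_identifiable"] = True
    return FitResult(
        estimates={"r": r_hat, "k": k_hat},
        objective=float(2 * best.cost),
        data_ref=f"{mono_obs.scenario} (seed={mono_obs.seed})",
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# stage 2: induction and latency (x, l)
# ---------------------------------------------------------------------------


def _stage2_groups(lamB_obs: FecalObservationSet):
    """Per-mouse (initial state, residual targets) for the a = 0 submodel."""
    needed = {"L", "S_lineage"}
    have = set(lamB_obs.compartments)
    if not needed <= have:
        raise EstimationError(f"LamB- data must contain L and S_lineage series, found {sorted(have)}")
    groups = []
    for mouse, rows in lamB_obs.data.groupby("mouse_id"):
        init = {}
        for comp in ("L", "S_lineage", "Q"):
            at0 = rows[(rows["time_h"] == 0.0) & (rows["compartment"] == comp) & (~rows["censored"])]
            init[comp] = float(at0["count_per_g"].iloc[0]) if len(at0) else 0.0
        targets = rows[(~rows["censored"]) & rows["compartment"].isin(["L", "S_lineage", "Q"])]
        targets = targets.sort_values("time_h")
        if targets.empty:
            continue
        groups.append((init, targets))
    if not groups:
        raise EstimationError("no usable LamB- observations")
    return groups


def fit_induction_latency(
    lamB_obs: FecalObservationSet,
    d: float = 0.25,
    r: float = 1.1,
    k: float = 4.6e9,
) -> FitResult:
    """Estimate x and l from receptor-less competitions with latent-cell counts.

    With a = 0 the model reduces to L, S and Q; squared log10 residuals of the
    three series are minimized (equal weights) over (x, l) >= 0 with r, k, d
    fixed from stage 1.
    """
    groups = _stage2_groups(lamB_obs)
    q_all_censored = all((targets["compartment"] != "Q").all() for _, targets in groups)

    sim_cache: dict = {}

    def predict(x: float, l: float, init: dict, times: np.ndarray) -> dict[str, np.ndarray]:
        key = (round(x, 12), round(l, 12), init["L"], init["S_lineage"], init["Q"], tuple(times))
        if key not in sim_cache:
            params = ModelParameters(d=d, r=r, k=k, x=x, l=l, y=1.0, a=0.0, g=0.0)
            grid = times if times[0] == 0 else np.concatenate([[0.0], times])
            initial = PopulationState(S=init["S_lineage"], L=init["L"], Q=init["Q"])
            traj = simulate(params, initial, grid)
            keep = np.isin(grid, times)
            sim_cache[key] = {
                "L": traj.L[keep],
                "S_lineage": (traj.S + traj.SL)[keep],
                "Q": traj.Q[keep],
            }
        return sim_cache[key]

    def residuals(theta: np.ndarray) -> np.ndarray:
        x, l = theta
        out = []
        for init, targets in groups:
            times = np.unique(targets["time_h"].to_numpy())
            pred = predict(x, l, init, times)
            tindex = {t: i for i, t in enumerate(times)}
            for _, row in targets.iterrows():
                model = pred[row["compartment"]][tindex[row["time_h"]]]
                out.append(np.log10(max(model, 1e-3)) - np.log10(row["count_per_g"]))
        return np.asarray(out)

    starts = [(0.005, 0.3), (0.02, 0.8), (0.05, 1.5), (0.1, 0.5), (0.3, 2.0)]
    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0=x0, bounds=([0.0, 0.0], [1.0, 5.0]), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise EstimationError(f"induction/latency fit did not converge: {getattr(best, 'message', 'no solution')}")

    x_hat, l_hat = (float(v) for v in best.x)
    diagnostics = {"n_mice": len(groups), "optimizer_status": best.status}
    if q_all_censored:
        diagnostics["q_all_censored"] = True
    if x_hat < 1e-6:
        diagnostics["x_at_boundary"] = True
    return FitResult(
        estimates={"x": x_hat, "l": l_hat},
        objective=float(2 * best.cost),
        data_ref=f"{lamB_obs.scenario} (seed={lamB_obs.seed})",
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# stage 3: adsorption constant a from the free-virus equilibrium balance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdsorptionSolution:
    """Adsorption constant deduced from equilibrium densities (g/h)."""

    a: float
    clipped: bool = False


def solve_adsorption(
    y: float,
    V_star: float,
    Q_star: float,
    N_star: float,
    l: float = 0.8,
    d: float = 0.25,
) -> AdsorptionSolution:
    """Invert the equilibrium condition dV/dt = 0 for the adsorption constant.

    At equilibrium phage production balances removal, y l Q* = (a N* + d) V*,
    giving a = (y l Q* - d V*) / (N* V*).  A negative inversion (production
    below washout) is clipped to 0 and flagged.
    """
    if V_star <= 0 or N_star <= 0:
        raise EstimationError("equilibrium inversion undefined: require V* > 0 and N* > 0")
    a = (y * l * Q_star - d * V_star) / (N_star * V_star)
    if a < 0:
        return AdsorptionSolution(a=0.0, clipped=True)
    return AdsorptionSolution(a=float(a))


# ---------------------------------------------------------------------------
# stage 4: lysogenization probability g
# ---------------------------------------------------------------------------


def fit_lysogenization(
    comp_obs: FecalObservationSet,
    params: ModelParameters,
    fit_time: float = 36.0,
    time_tol: float | None = None,
) -> FitResult:
    """Estimate g by fitting the L/(S+SL) ratio in wild-type competitions.

    For each mouse the observed log10 ratio at the observation nearest
    ``fit_time`` (within ``time_tol``, default one sampling interval) is
    matched by simulating from that mouse's observed initial densities; g is
    found by bounded scalar minimization on [0, 1] with all other parameters
    fixed.
    """
    have = set(comp_obs.compartments)
    if not {"L", "S_lineage"} <= have:
        raise EstimationError(f"competition data must contain L and S_lineage, found {sorted(have)}")

    all_times = comp_obs.times
    if time_tol is None:
        time_tol = float(np.max(np.diff(all_times))) if all_times.size > 1 else 0.0
    usable = all_times[np.abs(all_times - fit_time) <= time_tol]
    if usable.size == 0:
        raise EstimationError(
            f"no observations within {time_tol} h of the fitting time {fit_time} h; observed times: {list(all_times)}"
        )

    targets = []  # (L0, S0, t_obs, observed log10 ratio)
    for mouse, rows in comp_obs.data.groupby("mouse_id"):
        rows = rows[~rows["censored"]]
        mouse_times = np.unique(rows["time_h"].to_numpy())
        near = mouse_times[np.abs(mouse_times - fit_time) <= time_tol]
        if near.size == 0:
            continue
        t_obs = float(near[np.argmin(np.abs(near - fit_time))])

        def _one(comp: str, t: float):
            sel = rows[(rows["time_h"] == t) & (rows["compartment"] == comp)]
            return float(sel["count_per_g"].iloc[0]) if len(sel) else None

        l_obs, s_obs = _one("L", t_obs), _one("S_lineage", t_obs)
        l0, s0 = _one("L", 0.0), _one("S_lineage", 0.0)
        if None in (l_obs, s_obs, l0, s0) or s_obs <= 0:
            continue
        targets.append((l0, s0, t_obs, math.log10(l_obs / s_obs)))
    if not targets:
        raise EstimationError("no mouse has usable L and S_lineage observations at the fitting time")

    sim_cache: dict = {}

    def model_log_ratio(g: float, l0: float, s0: float, t_obs: float) -> float:
        key = (round(g, 12), l0, s0, t_obs)
        if key not in sim_cache:
            traj = simulate(params.replace(g=g), PopulationState(S=s0, L=l0), np.array([0.0, t_obs]))
            lineage_s = traj.S[-1] + traj.SL[-1]
            sim_cache[key] = math.log10(max(traj.L[-1], 1e-3) / max(lineage_s, 1e-3))
        return sim_cache[key]

    def objective(g: float) -> float:
        return sum((model_log_ratio(g, l0, s0, t) - obs_lr) ** 2 for l0, s0, t, obs_lr in targets)

    sol = minimize_scalar(objective, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-7})
    if not sol.success:
        raise EstimationError(f"lysogenization fit did not converge: {sol.message}")
    return FitResult(
        estimates={"g": float(sol.x)},
        objective=float(sol.fun),
        data_ref=f"{comp_obs.scenario} (seed={comp_obs.seed})",
        diagnostics={"fit_time_h": fit_time, "n_mice_used": len(targets)},
    )


# ---------------------------------------------------------------------------
# bootstrap and full pipeline
# ---------------------------------------------------------------------------


def bootstrap_ci(
    estimator,
    obs: FecalObservationSet,
    n_boot: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Case-bootstrap 95% intervals: resample mice with replacement, refit.

    ``estimator`` maps an observation set to a :class:`FitResult`.  Replicates
    whose fit fails are dropped and counted; more than 20% failures aborts.
    Deterministic given ``seed``.  Returns (intervals, n_failed).
    """
    mice = obs.mice
    if len(mice) < 3:
        raise EstimationError("bootstrap needs at least 3 mice")
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    n_failed = 0
    for _ in range(n_boot):
        picked = [mice[i] for i in rng.integers(0, len(mice), size=len(mice))]
        try:
            fit = estimator(obs.resample_mice(picked))
        except Exception:
            n_failed += 1
            continue
        for name, value in fit.estimates.items():
            draws.setdefault(name, []).append(value)
    if n_failed > max_failure_fraction * n_boot:
        raise EstimationError(f"bootstrap failed in {n_failed}/{n_boot} replicates")
    intervals = {
        name: (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        for name, vals in draws.items()
    }
    return intervals, n_failed


def estimate_all(
    datasets: dict[str, FecalObservationSet],
    d: float = 0.25,
    y: float = 12.1,
    fit_time: float = 36.0,
    n_boot: int = 0,
    seed: int = 0,
) -> FitResult:
    """Run the four estimation stages in sequence and assemble all parameters.

    ``datasets`` must provide keys ``mono``, ``lamB`` and ``competition``.
    The dilution rate ``d`` and burst size ``y`` are fixed inputs (transit
    measurements and the in vitro single-burst assay respectively).  With
    ``n_boot`` > 0, bootstrap intervals are computed for the fitted stages.

    Stage 3 uses the mean densities across mice at the latest competition
    sample time as the equilibrium observations; the latent density Q*
    (not countable in wild-type experiments) is reconstructed from the
    stage-2 estimates via the dQ/dt = 0 balance, Q* = x (L* + SL*) / (l + d).
    """
    for key, stage in (("mono", "1 (growth)"), ("lamB", "2 (induction/latency)"), ("competition", "4 (lysogenization)")):
        if key not in datasets:
            raise EstimationError(f"missing dataset {key!r}: required for stage {stage}")

    stage1 = fit_growth(datasets["mono"], d=d)
    r, k = stage1.estimates["r"], stage1.estimates["k"]

    stage2 = fit_induction_latency(datasets["lamB"], d=d, r=r, k=k)
    x, l = stage2.estimates["x"], stage2.estimates["l"]

    comp = datasets["competition"]
    t_eq = float(comp.times.max())
    eq_rows = comp.data[(comp.data["time_h"] == t_eq) & (~comp.data["censored"])]
    eq_mean = eq_rows.groupby("compartment")["count_per_g"].mean()
    try:
        v_star = float(eq_mean["V"])
        l_star = float(eq_mean["L"])
        s_lineage_star = float(eq_mean["S_lineage"])
    except KeyError as err:
        raise EstimationError(f"stage 3 needs uncensored {err} observations at the last competition time") from err
    sl_star = float(eq_mean.get("SL", 0.0))
    n_star = l_star + s_lineage_star
    q_star = x * (l_star + sl_star) / (l + d)
    stage3 = solve_adsorption(y, V_star=v_star, Q_star=q_star, N_star=n_star, l=l, d=d)

    base = ModelParameters(d=d, r=r, k=k, x=x, l=l, y=y, a=stage3.a, g=0.5)
    stage4 = fit_lysogenization(comp, base, fit_time=fit_time)
    g = stage4.estimates["g"]

    ci95: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        ci_1, _ = bootstrap_ci(lambda o: fit_growth(o, d=d), datasets["mono"], n_boot=n_boot, seed=seed)
        ci_2, _ = bootstrap_ci(
            lambda o: fit_induction_latency(o, d=d, r=r, k=k), datasets["lamB"], n_boot=n_boot, seed=seed + 1
        )
        ci95.update(ci_1)
        ci95.update(ci_2)

    estimates = {"d": d, "r": r, "k": k, "x": x, "l": l, "y": y, "a": stage3.a, "g": g}
    return FitResult(
        estimates=estimates,
        objective=stage1.objective + stage2.objective + stage4.objective,
        ci95=ci95,
        n_boot=n_boot,
        seed=seed,
        data_ref=", ".join(f"{key}={ds.scenario}" for key, ds in datasets.items()),
        diagnostics={
            "stage1": stage1,
            "stage2": stage2,
            "stage3": stage3,
            "stage4": stage4,
            "equilibrium_observations": {"t_h": t_eq, "V": v_star, "N": n_star, "Q_reconstructed": q_star},
        },
    )
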