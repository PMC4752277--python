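"""Synthetic fecal time series and bench assay datasets.

These generators stand in for the animal and bench experiments: they simulate
the gut model (or the closed-form assay kinetics), then apply the sampling
design and measurement noise that fecal plating and plaque assays impose —
multiplicative lognormal count noise, a plating detection limit, lognormal
inter-mouse spread of inoculum densities.

Scenarios
---------
``mono``
    monocolonization by a single phage-free lineage (growth/carrying-capacity
    design); emits ``S_lineage`` only.
``lamB_competition``
    L vs S competition between receptor-less (LamB-) strains: no adsorption
    (a = 0), free phage arise from induction only; emits L, S_lineage, Q, V.
``wt_competition``
    L vs S competition between wild-type strains at initial L:S ratios 1:1,
    1:10 or 1:100; emits L, S_lineage, SL, V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import AssayDataset
from .model import ModelParameters, PopulationState, simulate
from .observations import FecalObservationSet

__all__ = [
    "SCENARIOS",
    "DEFAULT_SAMPLE_TIMES",
    "ScenarioConfig",
    "generate_mouse_experiment",
    "generate_adsorption_assay",
    "generate_burst_assay",
]

SCENARIOS = ("mono", "lamB_competition", "wt_competition")

#: daily fecal sampling, densified over the first 48 h where dynamics are fast
DEFAULT_SAMPLE_TIMES = (0.0, 6.0, 24.0, 30.0, 48.0, 72.0, 96.0, 144.0, 216.0)

_RATIOS = {"1:1": 1.0, "1:10": 10.0, "1:100": 100.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Design of one synthetic mouse experiment.

    ``initial_density`` is the nominal gavage density of the lysogen lineage
    (cfu/g); the susceptible lineage starts at ``initial_density`` times the
    S side of ``ratio`` (L:S).  For ``mono`` it is the single lineage's
    density.  ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal plating noise; ``initial_cv`` the lognormal
    spread of per-mouse inoculum densities around their nominal values.
    """

    scenario: str = "wt_competition"
    n_mice: int = 8
    ratio: str = "1:1"
    initial_density: float = 1e6
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES
    noise_cv: float = 0.2
    initial_cv: float = 0.3
    detection_limit: float = 1e2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid scenarios: {SCENARIOS}")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.ratio not in _RATIOS:
            raise ValueError(f"ratio must be one of {sorted(_RATIOS)}, got {self.ratio!r}")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size < 2 or times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must start at 0 and increase strictly")
        if self.noise_cv < 0 or self.initial_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.initial_density <= 0:
            raise ValueError("initial_density must be > 0")

    @property
    def s_factor(self) -> float:
        return _RATIOS[self.ratio]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _observed_compartments(scenario: str) -> tuple[str, ...]:
    if scenario == "mono":
        return ("S_lineage",)
    if scenario == "lamB_competition":
        # free phage can be spun away before plating, so latent cells Q are countable
        return ("L", "S_lineage", "Q", "V")
    return ("L", "S_lineage", "SL", "V")


def generate_mouse_experiment(config: ScenarioConfig, params: ModelParameters) -> FecalObservationSet:
    """Simulate one group of mice under ``config`` and plate them.

    Per mouse: draw inoculum densities (lognormal around nominal with
    ``initial_cv``), integrate the model (with a forced to 0 for the LamB-
    scenario), read the plating observables at the sample times, multiply by
    lognormal noise of CV ``noise_cv``, and floor at the detection limit
    (floored records carry ``censored=True``).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    run_params = params.replace(a=0.0) if config.scenario == "lamB_competition" else params
    times = np.asarray(config.sample_times, dtype=float)
    compartments = _observed_compartments(config.scenario)

    records = []
    for m in range(config.n_mice):
        mouse = f"m{m + 1:02d}"
        if config.scenario == "mono":
            s0 = config.initial_density * _lognormal_factor(rng, config.initial_cv)
            initial = PopulationState(S=s0)
        else:
            l0 = config.initial_density * _lognormal_factor(rng, config.initial_cv)
            s0 = config.initial_density * config.s_factor * _lognormal_factor(rng, config.initial_cv)
            initial = PopulationState(S=s0, L=l0)
        traj = simulate(run_params, initial, times)
        for j, t in enumerate(times):
            state = traj.states[j]
            obs = {
                "L": state[1],
                "S_lineage": state[0] + state[2],
                "SL": state[2],
                "Q": state[3],
                "V": state[4],
            }
            for comp in compartments:
                noisy = obs[comp] * _lognormal_factor(rng, config.noise_cv)
                censored = noisy < config.detection_limit
                records.append(
                    {
                        "mouse_id": mouse,
                        "time_h": float(t),
                        "compartment": comp,
                        "count_per_g": float(max(noisy, config.detection_limit)),
                        "censored": bool(censored),
                    }
                )

    data = pd.DataFrame.from_records(records)
    return FecalObservationSet(
        data=data,
        scenario=config.scenario,
        detection_limit=config.detection_limit,
        params=run_params,
        noise={"noise_cv": config.noise_cv, "initial_cv": config.initial_cv},
        seed=config.seed,
    )


def generate_adsorption_assay(
    a: float,
    B: float,
    N0: float,
    times: Sequence[float],
    noise: str = "none",
    seed: int | None = None,
) -> AssayDataset:
    """Unadsorbed-phage decay series N_t = N0 * exp(-B a t).

    ``a`` is the in vitro adsorption rate (ml/h), ``B`` the adsorbing
    bacterial density (per ml), ``N0`` the input phage count.  With
    ``noise="poisson"`` each count is Poisson-sampled around its expectation.
    """
    if a < 0 or B <= 0 or N0 <= 0:
        raise ValueError("require a >= 0, B > 0, N0 > 0")
    if noise not in ("none", "poisson"):
        raise ValueError(f"noise must be 'none' or 'poisson', got {noise!r}")
    times = np.asarray(times, dtype=float)
    values = N0 * np.exp(-B * a * times)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        values = rng.poisson(values).astype(float)
    return AssayDataset(kind="adsorption_decay", times=times, values=values, B=B)


def generate_burst_assay(
    y: float,
    latency_time: float,
    N0: float,
    times: Sequence[float] | None = None,
    rise_width: float = 0.0,
) -> AssayDataset:
    """Single-burst PFU series: N0 before lysis, y*N0 at the plateau.

    ``rise_width`` > 0 smooths the step with a logistic rise of that
    half-width (hours), mimicking the spread of individual burst times.
    """
    if y < 1:
        raise ValueError("burst size y must be >= 1")
    if times is None:
        # 10-minute sampling over ~2 h, the bench protocol's cadence
        times = np.arange(0.0, 2.01, 1.0 / 6.0)
    times = np.asarray(times, dtype=float)
    if rise_width > 0:
        frac = 1.0 / (1.0 + np.exp(-(times - latency_time) / (rise_width / 4.0)))
    else:
        frac = (times >= latency_time).astype(float)
    values = N0 * (1.0 + (y - 1.0) * frac)
    return AssayDataset(kind="single_burst", times=times, values=values)


def generate_calibration_bundle(
    params: ModelParameters,
    seed: int = 0,
    noise_cv: float = 0.0,
    initial_cv: float = 0.0,
    n_mice_mono: int = 3,
    n_mice_lamB: int = 3,
    n_mice_per_ratio: int = 2,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
) -> dict[str, FecalObservationSet]:
    """The three datasets the sequential calibration pipeline consumes.

    Returns ``{"mono", "lamB", "competition"}``: a monocolonization group, a
    receptor-less competition group, and wild-type competitions pooled over
    the three initial L:S ratios.  Defaults are noiseless (the
    self-consistency configuration); raise the CVs for realistic runs.
    """
    from .observations import merge_observation_sets

    mono = generate_mouse_experiment(
        ScenarioConfig(
            scenario="mono", n_mice=n_mice_mono, sample_times=sample_times,
            noise_cv=noise_cv, initial_cv=initial_cv, seed=seed,
        ),
        params,
    )
    lamB = generate_mouse_experiment(
        ScenarioConfig(
            scenario="lamB_competition", n_mice=n_mice_lamB, sample_times=sample_times,
            noise_cv=noise_cv, initial_cv=initial_cv, seed=seed + 1,
        ),
        params,
    )
    groups = [
        generate_mouse_experiment(
            ScenarioConfig(
                scenario="wt_competition", n_mice=n_mice_per_ratio, ratio=ratio,
                sample_times=sample_times, noise_cv=noise_cv, initial_cv=initial_cv,
                seed=seed + 2 + i,
            ),
            params,
        )
        for i, ratio in enumerate(("1:1", "1:10", "1:100"))
    ]
    return {"mono": mono, "lamB": lamB, "competition": merge_observation_sets(groups)}
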