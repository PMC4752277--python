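"""One-at-a-time parameter sweeps of the final lysogen-lineage gain.

The quantity of interest is the lysogen over susceptible-lineage ratio
L/(S+SL) after the competition has essentially settled (default horizon
100 h), evaluated for the three initial L:S ratios used experimentally.
Sweeping each parameter over a log grid around its calibrated value shows
which rates shape the final gain; the lysogenization probability g gets a
dedicated sweep with an inverse-proportionality diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import PARAM_NAMES, ModelParameters, PopulationState, simulate

__all__ = [
    "SweepResult",
    "final_ratio",
    "parameter_sweep",
    "gain_vs_g",
    "initial_state_for_ratio",
    "default_sweep_values",
]

DEFAULT_RATIOS = ("1:1", "1:10", "1:100")
_RATIO_FACTORS = {"1:1": 1.0, "1:10": 10.0, "1:100": 100.0}


def initial_state_for_ratio(ratio: str, L0: float = 1e6) -> PopulationState:
    """Gavage state for an initial L:S ratio label ('1:1', '1:10', '1:100')."""
    if ratio not in _RATIO_FACTORS:
        raise ValueError(f"unknown initial ratio {ratio!r}; expected one of {sorted(_RATIO_FACTORS)}")
    return PopulationState(S=L0 * _RATIO_FACTORS[ratio], L=L0)


@dataclass(frozen=True)
class SweepResult:
    """Final-ratio matrix over (tested values x initial ratios)."""

    parameter: str
    values: np.ndarray
    initial_ratios: tuple[str, ...]
    final_ratios: np.ndarray  # shape (len(values), len(initial_ratios))
    horizon: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        matrix = np.asarray(self.final_ratios, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "final_ratios", matrix)
        if matrix.shape != (values.size, len(self.initial_ratios)):
            raise ValueError(
                f"final_ratios shape {matrix.shape} inconsistent with "
                f"{values.size} values x {len(self.initial_ratios)} ratios"
            )
        if np.any(matrix < 0):
            raise ValueError("final ratios must be >= 0")

    def to_frame(self):
        """Long-format DataFrame: parameter,value,initial_ratio,final_ratio."""
        import pandas as pd

        rows = [
            {
                "parameter": self.parameter,
                "value": self.values[i],
                "initial_ratio": ratio,
                "final_ratio": self.final_ratios[i, j],
            }
            for i in range(self.values.size)
            for j, ratio in enumerate(self.initial_ratios)
        ]
        return pd.DataFrame(rows)


def final_ratio(
    params: ModelParameters,
    initial: PopulationState,
    horizon: float = 100.0,
) -> float:
    """L/(S+SL) at the horizon; inf (with a warning) if the S lineage is extinct."""
    traj = simulate(params, initial, np.array([0.0, horizon]))
    lineage_s = traj.S[-1] + traj.SL[-1]
    if lineage_s <= 0:
        warnings.warn(f"susceptible lineage extinct at {horizon} h; ratio is infinite", stacklevel=2)
        return math.inf
    return float(traj.L[-1] / lineage_s)


def default_sweep_values(params: ModelParameters, name: str, n: int = 21) -> np.ndarray:
    """Log grid from x0.1 to x10 of the baseline value (capped at 1 for g)."""
    base = getattr(params, name)
    if base == 0:
        raise ValueError(f"cannot build a multiplicative grid around {name} = 0")
    values = np.geomspace(0.1 * base, 10.0 * base, n)
    if name == "g":
        values = values[values <= 1.0]
    if name == "y":
        values = values[values >= 1.0]
    return values


def parameter_sweep(
    params: ModelParameters,
    name: str,
    values: Sequence[float] | None = None,
    initial_ratios: Sequence[str] = DEFAULT_RATIOS,
    L0: float = 1e6,
    horizon: float = 100.0,
) -> SweepResult:
    """Final ratio for each (parameter value, initial ratio) pair.

    All other parameters are held at ``params``; values violating the
    parameter invariants raise a ValueError naming the offender.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; the model parameters are {PARAM_NAMES}")
    if values is None:
        values = default_sweep_values(params, name)
    values = np.asarray(values, dtype=float)
    initials = [initial_state_for_ratio(ratio, L0) for ratio in initial_ratios]

    matrix = np.empty((values.size, len(initials)))
    for i, value in enumerate(values):
        try:
            trial = params.replace(**{name: float(value)})
        except ValueError as err:
            raise ValueError(f"invalid sweep value {name}={value}: {err}") from err
        for j, initial in enumerate(initials):
            matrix[i, j] = final_ratio(trial, initial, horizon)
    return SweepResult(
        parameter=name,
        values=values,
        initial_ratios=tuple(initial_ratios),
        final_ratios=matrix,
        horizon=horizon,
    )


def gain_vs_g(
    params: ModelParameters,
    g_values: Sequence[float],
    initial_ratios: Sequence[str] = DEFAULT_RATIOS,
    L0: float = 1e6,
    horizon: float = 100.0,
) -> SweepResult:
    """Sweep of g with inverse-proportionality diagnostics.

    The final gain of the lysogen lineage scales like 1/g near equilibrium:
    the fewer infections lysogenize, the more susceptible competitors are
    lysed per phage.  Besides the final-ratio matrix, reports the products
    ``ratio_times_g`` and ``gain_times_g`` ((ratio - 1) x g); flatness of
    either across the sweep is the proportionality check.  g = 0 values are
    excluded with a warning (the ratio diverges).
    """
    g_values = np.asarray(g_values, dtype=float)
    if np.any(g_values == 0):
        warnings.warn("g = 0 excluded from the sweep: the final ratio diverges", stacklevel=2)
        g_values = g_values[g_values != 0]
    if np.any((g_values < 0) | (g_values > 1)):
        raise ValueError("g values must lie in (0, 1]")
    sweep = parameter_sweep(params, "g", g_values, initial_ratios, L0, horizon)
    ratio_times_g = sweep.final_ratios * g_values[:, None]
    gain_times_g = (sweep.final_ratios - 1.0) * g_values[:, None]
    return SweepResult(
        parameter="g",
        values=sweep.values,
        initial_ratios=sweep.initial_ratios,
        final_ratios=sweep.final_ratios,
        horizon=horizon,
        diagnostics={"ratio_times_g": ratio_times_g, "gain_times_g": gain_times_g},
    )
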