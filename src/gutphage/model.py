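"""Five-population ODE model of temperate phage-bacteria dynamics in the gut.

The model tracks five densities in one gram of feces of a monoxenic mouse
colonized with a lysogenic (L) and an isogenic susceptible (S) *E. coli*
lineage, infected by a temperate phage:

    S   susceptible bacteria                      (cfu/g)
    L   original lysogens                         (cfu/g)
    SL  newly lysogenized susceptibles            (cfu/g)
    Q   latent cells undergoing lytic development (cfu/g)
    V   free phage                                (pfu/g)

With N = S + L + SL the total replicating bacterial population, the dynamics
are

    dS/dt  = r S (1 - N/k) - a S V - d S
    dL/dt  = r L (1 - N/k) - x L - d L
    dSL/dt = r SL (1 - N/k) + g a S V - x SL - d SL
    dQ/dt  = (1 - g) a S V + x (L + SL) - l Q - d Q
    dV/dt  = y l Q - a N V - d V

Bacteria grow logistically at maximal rate ``r`` toward carrying capacity
``k``.  Free phage adsorb to all bacteria at rate ``a`` (lysogens adsorb but
are immune, hence -aNV in dV while only -aSV removes susceptibles).  An
infection lysogenizes with probability ``g`` and otherwise enters the latent
pool, which lyses at rate ``l`` releasing ``y`` phage per cell.  Prophages in
L and SL induce at rate ``x``.  Gastrointestinal transit dilutes every
compartment at rate ``d``.  Latent cells do not divide.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "DEFAULT_PARAMETERS",
    "ModelParameters",
    "PopulationState",
    "Trajectory",
    "IntegrationError",
    "EquilibriumError",
    "derivatives",
    "simulate",
    "simulate_two_phase",
    "equilibrium",
    "state_to_observables",
]

PARAM_NAMES = ("d", "r", "k", "x", "l", "y", "a", "g")
STATE_NAMES = ("S", "L", "SL", "Q", "V")

#: default solver settings (shared by :func:`simulate` and the CLI)
DEFAULT_SOLVER_OPTIONS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-2}


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last time reached in ``last_t``."""

    def __init__(self, message: str, last_t: float | None = None):
        super().__init__(message)
        self.last_t = last_t


class EquilibriumError(RuntimeError):
    """Equilibrium search did not converge within the allowed horizon."""


@dataclass(frozen=True)
class ModelParameters:
    """The eight rates and probabilities of the gut phage-bacteria model.

    Parameters
    ----------
    d : dilution (gastrointestinal transit) rate, 1/h
    r : maximal bacterial growth rate, 1/h
    k : carrying capacity, cfu/g
    x : prophage induction rate, 1/h
    l : latency (lysis) rate, 1/h
    y : burst size, phage released per lysed cell (dimensionless)
    a : adsorption constant, g/h (in vivo, per gram of feces)
    g : lysogenization probability, dimensionless in [0, 1]
    """

    d: float
    r: float
    k: float
    x: float
    l: float
    y: float
    a: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")
        if self.g > 1:
            raise ValueError(f"lysogenization probability g must be <= 1, got {self.g}")
        # phage production is modeled whenever induction or adsorption is
        # active; a burst size below one cell^-1 is then unphysical
        if (self.x > 0 or self.a > 0) and self.y < 1:
            raise ValueError(f"burst size y must be >= 1 when phage production is modeled, got {self.y}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with some parameters overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


#: calibrated reference parameter set for phage lambda / E. coli MG1655 in
#: monoxenic mouse gut (packaged default, also shipped as data/default_params.txt)
DEFAULT_PARAMETERS = ModelParameters(
    d=0.25, r=1.1, k=4.6e9, x=0.016, l=0.8, y=12.1, a=2.6e-9, g=0.19
)


@dataclass(frozen=True)
class PopulationState:
    """Densities of the five compartments at one time point (per gram)."""

    S: float = 0.0
    L: float = 0.0
    SL: float = 0.0
    Q: float = 0.0
    V: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"state component {name} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"state component {name} must be >= 0, got {value}")

    @property
    def N(self) -> float:
        """Total replicating bacterial population S + L + SL (excludes Q)."""
        return self.S + self.L + self.SL

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.L, self.SL, self.Q, self.V], dtype=float)

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "PopulationState":
        s, lys, sl, q, v = (float(u) for u in vec)
        return cls(S=s, L=lys, SL=sl, Q=q, V=v)


def _rhs(t: float, vec: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Right-hand side on the raw state vector (solver-facing)."""
    s, lys, sl, q, v = vec
    n = s + lys + sl
    growth = p.r * (1.0 - n / p.k)
    infection = p.a * s * v
    ds = growth * s - infection - p.d * s
    dl = growth * lys - p.x * lys - p.d * lys
    dsl = growth * sl + p.g * infection - p.x * sl - p.d * sl
    dq = (1.0 - p.g) * infection + p.x * (lys + sl) - p.l * q - p.d * q
    dv = p.y * p.l * q - p.a * n * v - p.d * v
    return np.array([ds, dl, dsl, dq, dv])


def derivatives(state: PopulationState, params: ModelParameters) -> dict[str, float]:
    """Instantaneous rates of change (per hour) for each compartment.

    Returns a mapping ``{"S": dS/dt, "L": ..., "SL": ..., "Q": ..., "V": ...}``.
    """
    vec = state.as_array()
    if not np.all(np.isfinite(vec)):
        raise ValueError("state contains non-finite components")
    out = _rhs(0.0, vec, params)
    return dict(zip(STATE_NAMES, (float(u) for u in out)))


@dataclass(frozen=True)
class Trajectory:
    """Solution of the model on a time grid.

    ``states`` is an (n_times, 5) array ordered (S, L, SL, Q, V).
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if states.shape != (times.size, 5):
            raise ValueError(f"states must have shape ({times.size}, 5), got {states.shape}")
        if np.any(states < 0):
            raise ValueError("trajectory contains negative densities")

    def __len__(self) -> int:
        return self.times.size

    def compartment(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def S(self) -> np.ndarray:
        return self.compartment("S")

    @property
    def L(self) -> np.ndarray:
        return self.compartment("L")

    @property
    def SL(self) -> np.ndarray:
        return self.compartment("SL")

    @property
    def Q(self) -> np.ndarray:
        return self.compartment("Q")

    @property
    def V(self) -> np.ndarray:
        return self.compartment("V")

    @property
    def N(self) -> np.ndarray:
        return self.S + self.L + self.SL

    def state_at(self, t: float) -> PopulationState:
        """State at a grid time ``t`` (exact match required)."""
        idx = np.nonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} h is not on the trajectory grid")
        return PopulationState.from_array(self.states[idx[0]])

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns time_h,S,L,SL,Q,V."""
        import pandas as pd

        data = {"time_h": self.times}
        data.update({name: self.compartment(name) for name in STATE_NAMES})
        return pd.DataFrame(data)


def _clean_solution(ys: np.ndarray, atol: float) -> np.ndarray:
    """Clamp solver-noise negatives to zero; real excursions are errors.

    The adaptive solver controls local error to atol + rtol*|y| per step, so
    negative dips of a few atol around zero (and of ~1e-6 of the solution
    scale on 1e9-magnitude problems) are numerical noise, not a sign the
    dynamics left the physical region.  Anything below that band aborts.
    """
    floor = -(10.0 * atol + 1e-6 * float(ys.max(initial=0.0)))
    low = ys.min()
    if low < floor:
        raise IntegrationError(
            f"integration produced a component {low:.3g} below the noise floor {floor:.3g}; "
            "the solution left the physical region"
        )
    return np.clip(ys, 0.0, None)


def simulate(
    params: ModelParameters,
    initial: PopulationState,
    t_grid: Sequence[float],
    solver_options: Mapping | None = None,
) -> Trajectory:
    """Integrate the model on ``t_grid`` (hours, starting at 0).

    Integration is in linear space with tight tolerances (rtol 1e-8,
    atol 1e-2 cfu/g by default); components within (-atol, 0) at output are
    round-off and clamped to zero, anything more negative raises
    :class:`IntegrationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must contain at least two time points")
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    opts = dict(DEFAULT_SOLVER_OPTIONS)
    if solver_options:
        opts.update(solver_options)
    method = opts.pop("method")
    atol = opts["atol"]

    y0 = initial.as_array()
    sol = solve_ivp(
        _rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        args=(params,),
        method=method,
        **opts,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_t=last_t)
    states = _clean_solution(sol.y.T, atol)
    meta = {"method": method, **{key: opts[key] for key in ("rtol", "atol")}}
    return Trajectory(times=t_grid, states=states, params=params, meta=meta)


def simulate_two_phase(
    params: ModelParameters,
    phase2_overrides: Mapping[str, float],
    switch_time: float,
    initial: PopulationState,
    t_grid: Sequence[float],
    solver_options: Mapping | None = None,
) -> Trajectory:
    """Integrate with ``params`` until ``switch_time``, then with overrides.

    The state is continuous at the switch.  Used e.g. for a LamB- switch (the
    host loses the phage receptor at 48 h, modeled as a = 0 afterwards) or a
    non-inducible prophage (x override).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] <= switch_time <= t_grid[-1]):
        raise ValueError(f"switch_time {switch_time} h outside t_grid range " f"[{t_grid[0]}, {t_grid[-1]}] h")
    params2 = params.replace(**dict(phase2_overrides))
    if params2 == params:
        return simulate(params, initial, t_grid, solver_options)

    before = t_grid[t_grid <= switch_time]
    after = t_grid[t_grid > switch_time]
    grid1 = before if before.size and before[-1] == switch_time else np.append(before, switch_time)
    traj1 = simulate(params, initial, grid1, solver_options)
    state_switch = PopulationState.from_array(traj1.states[-1])

    # integrate phase 2 on a local clock starting at 0, then shift back
    grid2_local = np.concatenate([[0.0], after - switch_time])
    traj2 = simulate(params2, state_switch, grid2_local, solver_options)

    keep1 = np.isin(grid1, before)
    times = np.concatenate([grid1[keep1], after])
    states = np.concatenate([traj1.states[keep1], traj2.states[1:]])
    meta = dict(traj1.meta)
    meta.update({"switch_time_h": float(switch_time), "phase2_overrides": dict(phase2_overrides)})
    return Trajectory(times=times, states=states, params=params, meta=meta)


def equilibrium(
    params: ModelParameters,
    initial_guess: PopulationState,
    tol: float = 1e-9,
    horizon: float = 2000.0,
    max_horizon: float = 32000.0,
) -> PopulationState:
    """Asymptotic steady state reached from ``initial_guess``.

    Found by long-horizon integration followed by Newton refinement of the
    algebraic system; converged when every derivative satisfies
    ``|f_i| <= tol * (1 + |y_i|)``.  When growth cannot offset dilution
    (r <= d) the washout (all-zero) state is returned directly.
    """
    if params.r <= params.d:
        return PopulationState()

    t_end = horizon
    state = initial_guess.as_array()
    while t_end <= max_horizon:
        grid = np.linspace(0.0, t_end, 201)
        traj = simulate(params, PopulationState.from_array(state), grid)
        candidate = traj.states[-1]
        sol = root(lambda vec: _rhs(0.0, vec, params), candidate, method="hybr")
        refined = sol.x
        ok = (
            sol.success
            and np.all(refined >= -1e-2)
            and np.all(np.abs(_rhs(0.0, refined, params)) <= tol * (1.0 + np.abs(refined)))
        )
        if ok:
            return PopulationState.from_array(np.clip(refined, 0.0, None))
        # not settled yet: keep integrating from where we stopped
        state = candidate
        t_end *= 2
    raise EquilibriumError(f"no equilibrium found within horizon {max_horizon} h (tol {tol})")


def state_to_observables(state: PopulationState) -> dict[str, float]:
    """Map model compartments to what fecal plating measures.

    Plating distinguishes the lysogen lineage (L), the susceptible lineage
    total S + SL (``S_lineage``), new lysogens within it (SL), free phage (V)
    and, in receptor-less experiments where free phage can be washed away
    before plating, latent cells (Q).
    """
    return {
        "L": state.L,
        "S_lineage": state.S + state.SL,
        "SL": state.SL,
        "V": state.V,
        "Q": state.Q,
    }
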