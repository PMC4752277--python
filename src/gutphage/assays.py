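"""Closed-form and regression estimators for bench assay quantities.

Four small estimators, each matching one bench protocol:

* exponential-decay fit of unadsorbed phage -> in vitro adsorption rate;
* single-burst series -> burst size;
* per-generation decline of the L/S ratio in receptor-less competitions ->
  model-independent induction rate;
* infective-centre counts -> per-plating induction rate with an exact
  binomial interval.

Units are tagged on every rate estimate.  The in vitro adsorption rate is per
millilitre of culture; the in vivo model constant is per gram of feces — the
two are never interconverted here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import binomtest

__all__ = [
    "AssayDataset",
    "RateEstimate",
    "adsorption_rate_from_decay",
    "burst_size",
    "generations_elapsed",
    "induction_rate_regression",
    "infective_centre_rate",
]

_KINDS = ("adsorption_decay", "single_burst", "ratio_series", "infective_centre")


@dataclass(frozen=True)
class AssayDataset:
    """One small bench dataset.

    ``times``/``values`` hold the series for the time-series kinds
    (PFU counts for decay and burst assays, L/S ratios for ratio series);
    ``B`` is the adsorbing bacterial density (per ml, decay assays);
    ``n_centres``/``n_plated`` the counts for infective-centre assays.
    """

    kind: str
    times: np.ndarray | None = None
    values: np.ndarray | None = None
    B: float | None = None
    n_centres: int | None = None
    n_plated: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown assay kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "infective_centre":
            if self.n_plated is None or self.n_centres is None:
                raise ValueError("infective_centre assays need n_centres and n_plated")
            if self.n_plated <= 0 or self.n_centres < 0:
                raise ValueError("require n_plated > 0 and n_centres >= 0")
            if self.n_centres > self.n_plated:
                raise ValueError("n_centres cannot exceed n_plated")
            return
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D and of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("counts/ratios must be >= 0")
        if self.kind == "adsorption_decay":
            if self.B is None or self.B <= 0:
                raise ValueError("adsorption_decay assays need adsorbing density B > 0")


@dataclass(frozen=True)
class RateEstimate:
    """A rate with its standard error (or interval) and an explicit unit tag."""

    value: float
    stderr: float | None
    units: str
    ci95: tuple[float, float] | None = None


def adsorption_rate_from_decay(data: AssayDataset) -> RateEstimate:
    """In vitro adsorption rate from an unadsorbed-PFU decay series.

    Free phage decay as N_t = N0 * exp(-B a t) while adsorbing to bacteria at
    density B, so ordinary least squares of ln N_t on t gives a = -slope / B.
    Zero counts are censored at 1 PFU (with a warning) so the log is defined.
    """
    if data.kind != "adsorption_decay":
        raise ValueError(f"expected an adsorption_decay dataset, got {data.kind!r}")
    values = np.asarray(data.values, dtype=float)
    if np.count_nonzero(values > 0) < 3:
        raise ValueError("need at least 3 positive PFU counts")
    if np.any(values == 0):
        warnings.warn("zero PFU counts censored at 1 before log transform", stacklevel=2)
        values = np.maximum(values, 1.0)
    design = sm.add_constant(np.asarray(data.times))
    fit = sm.OLS(np.log(values), design).fit()
    slope, slope_se = fit.params[1], fit.bse[1]
    return RateEstimate(value=-slope / data.B, stderr=float(slope_se / data.B), units="ml h^-1")


def burst_size(data: AssayDataset) -> float:
    """Burst size: the factor between maximum and initial PFU counts."""
    if data.kind != "single_burst":
        raise ValueError(f"expected a single_burst dataset, got {data.kind!r}")
    if data.values.size < 2:
        raise ValueError("need at least 2 time points")
    n0 = data.values[0]
    if n0 <= 0:
        raise ValueError("initial PFU count must be > 0")
    return float(data.values.max() / n0)


def generations_elapsed(t: float, r: float = 1.1, d: float = 0.25, phase_switch: float = 24.0) -> float:
    """Bacterial generations elapsed by fecal time t under a two-phase schedule.

    Net growth proceeds at rate ``r`` for the first ``phase_switch`` hours of
    colonization (expansion) and at the excretion rate ``d`` thereafter
    (turnover at carrying capacity); dividing the accumulated exponential
    growth by ln 2 converts it to generations.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    expo = r * min(t, phase_switch) + d * max(t - phase_switch, 0.0)
    return expo / math.log(2)


def induction_rate_regression(
    data: AssayDataset,
    r: float = 1.1,
    d: float = 0.25,
    phase_switch: float = 24.0,
) -> RateEstimate:
    """Model-independent induction rate from the decline of the L/S ratio.

    In receptor-less competitions induction is the only process distinguishing
    the two lineages, removing a fraction x of lysogens per generation, so
    ln(L/S) declines linearly in generation number with slope -x (to first
    order in x).  Returns x = -slope of the OLS regression of ln(ratio) on
    :func:`generations_elapsed`, with its standard error.
    """
    if data.kind != "ratio_series":
        raise ValueError(f"expected a ratio_series dataset, got {data.kind!r}")
    ratios = np.asarray(data.values, dtype=float)
    if ratios.size < 3:
        raise ValueError("need at least 3 ratio observations")
    if np.any(ratios <= 0):
        raise ValueError("all L/S ratios must be > 0 (both lineages detected)")
    gens = np.array([generations_elapsed(t, r=r, d=d, phase_switch=phase_switch) for t in data.times])
    fit = sm.OLS(np.log(ratios), sm.add_constant(gens)).fit()
    return RateEstimate(value=float(-fit.params[1]), stderr=float(fit.bse[1]), units="generation^-1")


def infective_centre_rate(n_centres: int, n_plated: int) -> RateEstimate:
    """Per-plating induction rate from infective-centre counts.

    Point estimate n_centres / n_plated with an exact (Clopper-Pearson) 95%
    binomial interval.
    """
    if n_plated <= 0:
        raise ValueError("n_plated must be > 0")
    if n_centres < 0 or n_centres > n_plated:
        raise ValueError("need 0 <= n_centres <= n_plated")
    ci = binomtest(n_centres, n_plated).proportion_ci(confidence_level=0.95, method="exact")
    return RateEstimate(
        value=n_centres / n_plated,
        stderr=None,
        units="per plated lysogen",
        ci95=(float(ci.low), float(ci.high)),
    )
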