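"""Containers for per-mouse fecal count observations.

Observations are long-format records (mouse id, time in hours, compartment,
count per gram of feces), the shape produced by serial plating of fecal
samples.  Compartments follow plating semantics: ``L`` (lysogen lineage),
``S_lineage`` (susceptible lineage total S + SL), ``SL`` (new lysogens),
``V`` (free phage) and ``Q`` (latent cells, countable only in receptor-less
experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["COMPARTMENTS", "FecalObservationSet", "merge_observation_sets"]

COMPARTMENTS = ("L", "S_lineage", "SL", "Q", "V")

_COLUMNS = ["mouse_id", "time_h", "compartment", "count_per_g"]


@dataclass
class FecalObservationSet:
    """A set of noisy per-mouse fecal counts plus its provenance.

    Parameters
    ----------
    data : DataFrame with columns mouse_id, time_h, compartment, count_per_g
        (an optional boolean ``censored`` column marks counts recorded at the
        detection limit).
    scenario : label of the experimental design that produced the data.
    detection_limit : plating detection limit, counts per gram.
    params : generating model parameters (synthetic data) or None.
    noise : generator noise settings (synthetic data) or empty.
    seed : generator seed (synthetic data) or None.
    """

    data: pd.DataFrame
    scenario: str = "unknown"
    detection_limit: float = 1e2
    params: object = None
    noise: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table is missing columns {missing}")
        if "censored" not in self.data.columns:
            self.data = self.data.assign(censored=self.data["count_per_g"] <= self.detection_limit)
        bad = set(self.data["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}; expected {COMPARTMENTS}")
        if (self.data["count_per_g"] < 0).any():
            raise ValueError("counts must be >= 0")
        for mouse, sub in self.data.groupby("mouse_id"):
            if 0.0 not in set(sub["time_h"]):
                raise ValueError(f"mouse {mouse!r} has no time-0 record")

    @property
    def mice(self) -> list:
        return sorted(self.data["mouse_id"].unique())

    @property
    def compartments(self) -> list[str]:
        return [c for c in COMPARTMENTS if c in set(self.data["compartment"])]

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.data["time_h"].unique()))

    def counts(self, compartment: str, include_censored: bool = True) -> pd.DataFrame:
        """Rows for one compartment, optionally dropping detection-limit rows."""
        sub = self.data[self.data["compartment"] == compartment]
        if not include_censored:
            sub = sub[~sub["censored"]]
        return sub.copy()

    def pivot(self, compartment: str) -> pd.DataFrame:
        """Wide table (rows: time_h, columns: mouse_id) of one compartment."""
        sub = self.counts(compartment)
        return sub.pivot_table(index="time_h", columns="mouse_id", values="count_per_g")

    def subset_mice(self, mouse_ids: Iterable) -> "FecalObservationSet":
        wanted = list(mouse_ids)
        sub = self.data[self.data["mouse_id"].isin(set(wanted))].copy()
        return FecalObservationSet(
            data=sub,
            scenario=self.scenario,
            detection_limit=self.detection_limit,
            params=self.params,
            noise=dict(self.noise),
            seed=self.seed,
        )

    def relabel_mice(self, suffix: str) -> "FecalObservationSet":
        """Copy with ``suffix`` appended to every mouse id."""
        sub = self.data.copy()
        sub["mouse_id"] = sub["mouse_id"].astype(str) + suffix
        return FecalObservationSet(
            data=sub,
            scenario=self.scenario,
            detection_limit=self.detection_limit,
            params=self.params,
            noise=dict(self.noise),
            seed=self.seed,
        )

    def resample_mice(self, mouse_ids: Sequence) -> "FecalObservationSet":
        """Case-resampled copy: mice drawn (with repeats) get fresh unique ids."""
        if not hasattr(self, "_by_mouse"):
            # cache per-mouse blocks: bootstrap loops call this thousands of times
            object.__setattr__(self, "_by_mouse", {m: sub for m, sub in self.data.groupby("mouse_id")})
        parts = []
        for i, mouse in enumerate(mouse_ids):
            sub = self._by_mouse.get(mouse)
            if sub is None:
                raise KeyError(f"unknown mouse id {mouse!r}")
            sub = sub.copy()
            sub["mouse_id"] = f"{mouse}#b{i}"
            parts.append(sub)
        return FecalObservationSet(
            data=pd.concat(parts, ignore_index=True),
            scenario=self.scenario,
            detection_limit=self.detection_limit,
            params=self.params,
            noise=dict(self.noise),
            seed=self.seed,
        )


def merge_observation_sets(sets: Sequence[FecalObservationSet], scenario: str | None = None) -> FecalObservationSet:
    """Pool several groups (e.g. the three initial-ratio groups) into one set.

    Mouse ids are suffixed per group so mice stay distinct.  Detection limits
    must agree across groups.
    """
    if not sets:
        raise ValueError("need at least one observation set")
    limits = {obs.detection_limit for obs in sets}
    if len(limits) != 1:
        raise ValueError(f"detection limits differ across groups: {sorted(limits)}")
    relabeled = [obs.relabel_mice(f"/g{i}") for i, obs in enumerate(sets)]
    return FecalObservationSet(
        data=pd.concat([obs.data for obs in relabeled], ignore_index=True),
        scenario=scenario or sets[0].scenario,
        detection_limit=sets[0].detection_limit,
        params=sets[0].params,
        noise=dict(sets[0].noise),
        seed=sets[0].seed,
    )
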