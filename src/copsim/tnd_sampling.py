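"""Test-negative design (TND) sampling of the simulated epidemic.

On a sampling day, every symptomatically infectious agent is a
test-positive case; each case is matched with four test-negative
controls drawn uniformly at random (without replacement within a match
set) from that day's susceptible agents — with or without prior
immunological exposure — independently of their COP level and risk
group.  Latently infected (E) agents are excluded from the control
pool: they carry the pathogen and would not test negative, and
admitting their case-like frozen COP values into the controls
measurably attenuates every estimator.  A case's COP is its level frozen at
infection — immunity does not wane during the latent and infectious
stages — so the value read at sampling time is exposure-proximal.
Multi-day windows pool the per-day match sets, which is incidence-density
sampling: each control is at risk on the day its case occurred.

Sampling days must lie on the simulator's snapshot grid (every
``record_interval`` days).  Because the aggregated windows sample every
10 days and the infectious period is 7 days, no agent can appear as a
case on two sampled days of one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .transmission import SimHistory, STATE_I, STATE_S

__all__ = ["TNDDataset", "sample_day", "sample_period"]

CONTROLS_PER_CASE = 4


@dataclass
class TNDDataset:
    """Matched case-control rows plus sampling metadata.

    ``data`` columns: day, match_id (case-set identifier), case (1/0),
    id (agent), cop (COP at sampling), risk (1/2).  Every match set has
    one case row and four control rows sharing the same day.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return int(self.data["case"].sum())

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cop, risk, case) arrays for model fitting."""
        return (
            self.data["cop"].to_numpy(float),
            self.data["risk"].to_numpy(int),
            self.data["case"].to_numpy(int),
        )

    def to_csv(self, path, metadata_path=None) -> None:
        self.data.to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def read_csv(cls, path, metadata_path=None) -> "TNDDataset":
        meta = {}
        if metadata_path is not None:
            with open(metadata_path) as fh:
                meta = json.load(fh)
        return cls(pd.read_csv(path), meta)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": np.empty(0, int),
            "match_id": np.empty(0, int),
            "case": np.empty(0, int),
            "id": np.empty(0, int),
            "cop": np.empty(0, float),
            "risk": np.empty(0, int),
        }
    )


def _draw_control_sets(
    pool: np.ndarray, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform (n_sets, 4) draws from ``pool``, no repeats within a set.

    Controls may recur across different sets.  Rows with within-set
    duplicates (rare for large pools) are redrawn.
    """
    if pool.size < CONTROLS_PER_CASE:
        raise ValueError(
            f"only {pool.size} eligible controls for {CONTROLS_PER_CASE}-control sets"
        )
    picks = rng.integers(0, pool.size, size=(n_sets, CONTROLS_PER_CASE))
    while True:
        sorted_rows = np.sort(picks, axis=1)
        bad = np.flatnonzero((np.diff(sorted_rows, axis=1) == 0).any(axis=1))
        if bad.size == 0:
            break
        picks[bad] = rng.integers(0, pool.size, size=(bad.size, CONTROLS_PER_CASE))
    return pool[picks]


def sample_day(
    history: SimHistory,
    day: int,
    rng: np.random.Generator | int | None = None,
    _match_id_start: int = 0,
) -> TNDDataset:
    """One day's TND sample: every prevalent symptomatic case with 4 controls.

    Cases are the agents symptomatically infectious on ``day``; their COP
    (frozen since infection) and the controls' current COP are read from
    the day's population snapshot.  Controls come from the day's
    susceptible pool; selection looks only at epidemiological state,
    never at COP or risk group.
    """
    if day not in history.snapshots:
        raise KeyError(f"day {day} is not a recorded snapshot day")
    rng = np.random.default_rng(rng)
    state, cop = history.snapshots[day]

    case_ids = np.flatnonzero(state == STATE_I)
    n_cases = case_ids.size
    if n_cases == 0:
        return TNDDataset(_empty_frame(), {"days": [day], "n_cases_achieved": 0})

    pool = np.flatnonzero(state == STATE_S)
    control_ids = _draw_control_sets(pool, n_cases, rng)

    match_ids = np.arange(_match_id_start, _match_id_start + n_cases)
    ids = np.concatenate([case_ids, control_ids.ravel()])
    frame = pd.DataFrame(
        {
            "day": np.full(ids.size, day, dtype=int),
            "match_id": np.concatenate(
                [match_ids, np.repeat(match_ids, CONTROLS_PER_CASE)]
            ),
            "case": np.concatenate(
                [np.ones(n_cases, int), np.zeros(n_cases * CONTROLS_PER_CASE, int)]
            ),
            "id": ids,
            "cop": cop[ids],
            "risk": history.risk[ids].astype(int),
        }
    )
    frame = frame.sort_values(["match_id", "case"], ascending=[True, False])
    frame = frame.reset_index(drop=True)
    return TNDDataset(frame, {"days": [day], "n_cases_achieved": int(n_cases)})


def sample_period(
    history: SimHistory,
    days: Sequence[int],
    n_cases_target: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> TNDDataset:
    """Incidence-density TND sample pooled over several sampling days.

    Match sets from :func:`sample_day` on each listed day are pooled; if
    more than ``n_cases_target`` cases accrue, a uniform random subset of
    ``n_cases_target`` complete match sets is kept (a case is never
    separated from its controls).  If fewer accrue, all are returned and
    ``metadata["short_of_target"]`` is set.
    """
    if n_cases_target is not None and n_cases_target <= 0:
        raise ValueError("n_cases_target must be positive")
    rng = np.random.default_rng(rng)
    days = [int(d) for d in days]

    frames = []
    offset = 0
    for day in days:
        ds = sample_day(history, day, rng, _match_id_start=offset)
        if len(ds.data):
            frames.append(ds.data)
            offset = int(ds.data["match_id"].max()) + 1
    pooled = pd.concat(frames, ignore_index=True) if frames else _empty_frame()

    n_pooled = int(pooled["case"].sum())
    meta = {
        "days": days,
        "n_cases_requested": n_cases_target,
        "n_cases_achieved": n_pooled,
        "short_of_target": False,
    }
    if n_cases_target is not None and n_pooled > n_cases_target:
        keep = rng.choice(
            pooled["match_id"].unique(), size=n_cases_target, replace=False
        )
        pooled = pooled[pooled["match_id"].isin(keep)].reset_index(drop=True)
        meta["n_cases_achieved"] = n_cases_target
    elif n_cases_target is not None and n_pooled < n_cases_target:
        meta["short_of_target"] = True
    return TNDDataset(pooled, meta)
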