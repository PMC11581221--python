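"""Daily tiller-number dynamics and allocation of tillers to nodes.

The actual tiller count per plant follows the daily recursion

    APPSTN_i = APPSTN_{i-1} + dAPPSTN_i
    dAPPSTN_i = Tv * dPPSTN_i * FL * min(NF, WDF)

where ``dPPSTN_i`` is the potential daily increase for the variety,
``Tv`` the tillering-power coefficient and ``FL``/``NF``/``WDF`` the
leaf-age, nitrogen and water-deficit factors (each in [0, 1]).  The
trajectory starts from the seedling main culm (``APPSTN_0 = 1`` by
default) and is tracked as a real number; the geometric realization
rounds down to whole tillers.  Senescence-driven decline is out of
model scope: the recursion only adds tillers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from oryzasim.phenology import EventSchedule

__all__ = [
    "TillerTrajectory",
    "tiller_step",
    "simulate_tillers",
    "allocate_tillers",
    "TillerAllocation",
    "logistic_pulse_potential",
]


@dataclass
class TillerTrajectory:
    """Per-day actual tiller numbers and daily increments."""

    day_index: np.ndarray
    appstn: np.ndarray
    delta: np.ndarray

    def count_at(self, day: float) -> int:
        """Whole-tiller count on a given day (floor of APPSTN minus the main culm)."""
        if not len(self.day_index):
            return 0
        idx = min(int(np.searchsorted(self.day_index, day, side="right")) - 1,
                  len(self.day_index) - 1)
        if idx < 0:
            return 0
        return max(int(np.floor(self.appstn[idx])) - 1, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day_index, "appstn": self.appstn, "delta": self.delta}
        )


def _check_factor(name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {v}")


def tiller_step(
    prev: float, delta_potential: float, Tv: float, FL: float, NF: float, WDF: float
) -> float:
    """One day of the tiller recursion: ``prev + Tv * dPPSTN * FL * min(NF, WDF)``."""
    if Tv < 0:
        raise ValueError(f"Tv must be >= 0, got {Tv}")
    for name, v in (("FL", FL), ("NF", NF), ("WDF", WDF)):
        _check_factor(name, v)
    return prev + Tv * delta_potential * FL * min(NF, WDF)


def simulate_tillers(
    potential_series: Sequence[float],
    Tv: float,
    factor_series: Optional[Sequence[Tuple[float, float, float]]] = None,
    appstn0: float = 1.0,
) -> TillerTrajectory:
    """Run the full daily recursion from ``APPSTN_0``.

    ``factor_series`` holds per-day ``(FL, NF, WDF)`` tuples; omitted,
    all factors are non-limiting (1).  ``appstn0`` defaults to 1: the
    seedling main culm counts as the initial stem.
    """
    potential = np.asarray(potential_series, dtype=float)
    n = potential.size
    if factor_series is None:
        factors = [(1.0, 1.0, 1.0)] * n
    else:
        factors = list(factor_series)
        if len(factors) != n:
            raise ValueError(
                f"factor_series length {len(factors)} != potential length {n}"
            )
    appstn = np.empty(n)
    delta = np.empty(n)
    prev = appstn0
    for i in range(n):
        fl, nf, wdf = factors[i]
        cur = tiller_step(prev, potential[i], Tv, fl, nf, wdf)
        delta[i] = cur - prev
        appstn[i] = cur
        prev = cur
    return TillerTrajectory(day_index=np.arange(1, n + 1), appstn=appstn, delta=delta)


def logistic_pulse_potential(
    n_days: int, total: float = 12.0, midpoint: float = 30.0, width: float = 8.0
) -> np.ndarray:
    """Built-in potential daily tiller increase ``dPPSTN_i``.

    The derivative of a logistic pulse: tillering accelerates, peaks
    near ``midpoint`` days after emergence and tails off, integrating
    to ``total`` potential tillers.  A stand-in generator for the
    variety-specific potential model, which is cultivar-calibrated
    outside this package.
    """
    t = np.arange(0, n_days + 1, dtype=float)
    sigmoid = 1.0 / (1.0 + np.exp(-(t - midpoint) / width))
    # daily increments of the pulse, normalized so a long season sums to total
    return total * np.diff(sigmoid) / (1.0 - sigmoid[0])


@dataclass
class TillerAllocation:
    """Tiller-to-node assignment with an overflow flag."""

    assignment: Dict[int, int]  # node -> tiller index (emergence order)
    overflow: bool = False


def allocate_tillers(
    count: int,
    schedule: EventSchedule,
    seed: int,
    gdd_now: Optional[float] = None,
) -> TillerAllocation:
    """Assign ``count`` tillers to eligible basal nodes.

    Eligible nodes are those whose synchrony emergence time has passed
    (all scheduled nodes when ``gdd_now`` is None).  Assignment is
    earliest-eligible-first; nodes with equal emergence times are
    ordered by a seeded shuffle.  If ``count`` exceeds the eligible
    nodes the allocation caps there and sets the overflow flag.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    eligible = [
        (t, node)
        for node, t in schedule.tiller_emerge.items()
        if gdd_now is None or t <= gdd_now
    ]
    rng = np.random.default_rng(seed)
    # seeded tie-break among equally eligible nodes
    tie = rng.permutation(len(eligible))
    order = sorted(range(len(eligible)), key=lambda i: (eligible[i][0], tie[i]))
    overflow = count > len(eligible)
    chosen = order[: min(count, len(eligible))]
    assignment = {eligible[i][1]: k for k, i in enumerate(chosen)}
    return TillerAllocation(assignment=assignment, overflow=overflow)
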