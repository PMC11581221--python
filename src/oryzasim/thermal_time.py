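"""Thermal time: daily weather to accumulated growing degree days.

GDD is the simulator's clock: every organ event and every growth curve
is indexed by accumulated degree-days above a base temperature.  The
accumulation uses the standard daily formulation
``gdd_cum[i] = sum_{j<=i} max(0, T_j - base_temp)`` with no upper
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["GDDSeries", "accumulate_gdd", "synth_weather", "read_weather_csv"]


@dataclass(frozen=True)
class GDDSeries:
    """Accumulated thermal time indexed by day.

    ``days`` are integer day indices (0-based from the first weather
    record); ``gdd_cum`` is nondecreasing and the same length.
    """

    days: np.ndarray
    gdd_cum: np.ndarray
    base_temp: float = 10.0

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        cum = np.asarray(self.gdd_cum, dtype=float)
        if days.shape != cum.shape:
            raise ValueError("days and gdd_cum must have the same length")
        if cum.size and np.any(np.diff(cum) < 0):
            raise ValueError("gdd_cum must be nondecreasing")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "gdd_cum", cum)

    def __len__(self) -> int:
        return len(self.days)

    @property
    def total(self) -> float:
        return float(self.gdd_cum[-1]) if len(self) else 0.0

    def gdd_at_day(self, day: float) -> float:
        """Accumulated GDD at a (possibly fractional) day index."""
        if not len(self):
            raise ValueError("empty series")
        return float(np.interp(day, self.days.astype(float), self.gdd_cum))

    def day_at_gdd(self, gdd: float) -> float:
        """First (interpolated) day at which the accumulation reaches ``gdd``."""
        if not len(self):
            raise ValueError("empty series")
        if gdd > self.gdd_cum[-1]:
            raise ValueError(f"gdd {gdd} beyond end of series ({self.gdd_cum[-1]})")
        idx = int(np.searchsorted(self.gdd_cum, gdd))
        if idx == 0:
            return float(self.days[0])
        g0, g1 = self.gdd_cum[idx - 1], self.gdd_cum[idx]
        d0, d1 = float(self.days[idx - 1]), float(self.days[idx])
        if g1 == g0:
            return d1
        return d0 + (d1 - d0) * (gdd - g0) / (g1 - g0)


def accumulate_gdd(
    daily_mean_temp: Sequence[float], base_temp: float = 10.0
) -> GDDSeries:
    """Accumulate daily growing degree days above ``base_temp``.

    Days with mean temperature below the base contribute zero (clamped,
    never negative).  An empty input yields an empty series.
    """
    temps = np.asarray(daily_mean_temp, dtype=float)
    if temps.size and not np.all(np.isfinite(temps)):
        raise ValueError("temperatures must be finite")
    daily = np.maximum(temps - base_temp, 0.0)
    return GDDSeries(
        days=np.arange(temps.size), gdd_cum=np.cumsum(daily), base_temp=base_temp
    )


def synth_weather(
    n_days: int,
    seed: int,
    mean: float = 25.0,
    amplitude: float = 5.0,
    noise: float = 1.5,
    period: float = 365.0,
) -> np.ndarray:
    """Synthetic daily mean temperatures: sinusoid plus bounded noise.

    Emulates a temperate rice growing season, peaking mid-series.
    Deterministic per seed; ``amplitude=0, noise=0`` gives a constant
    series.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    seasonal = mean + amplitude * np.sin(np.pi * t / max(min(period, n_days), 1))
    eps = rng.uniform(-noise, noise, size=n_days) if noise else np.zeros(n_days)
    return seasonal + eps


def read_weather_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a weather CSV with columns ``day,tmean`` (or ``tmin,tmax``).

    When ``tmean`` is absent it is computed as ``(tmin + tmax) / 2``.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "tmean" not in cols:
        if "tmin" in cols and "tmax" in cols:
            df["tmean"] = (df[cols["tmin"]] + df[cols["tmax"]]) / 2.0
        else:
            raise ValueError("weather CSV needs tmean or both tmin and tmax")
    return df
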