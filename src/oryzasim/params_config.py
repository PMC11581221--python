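"""Cultivar, environment and simulation parameters.

All per-cultivar constants live in :class:`CultivarParams`: final leaf
count ``LN``, elongated internode count ``m``, per-rank final leaf
lengths and thermal-time windows, the logistic expansion coefficients
``La``/``Lb``, the leaf-width coefficients ``P``/``WLR``/``WPd``/``WPe``,
the tillering-power coefficient ``Tv``, the phyllochron, and planting
spacings.  Only ``La`` and ``Lb`` have literature-fixed defaults
(8.65 and 6.26); everything else is a cultivar-specific input that a
practitioner estimates from field data, so the package treats them as
configuration with documented fixture defaults.

Units: organ lengths in cm, planting spacing in m, thermal time in
degree-days (deg C * d) above ``base_temp`` (default 10 deg C, the
standard rice base temperature).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CultivarParams",
    "EnvironmentFactors",
    "OrganDims",
    "load_cultivar",
    "save_cultivar",
    "synth_cultivar",
]


class OrganDims(BaseModel):
    """Final dimensions (cm) for the cylinder-shaped organs of one rank.

    Sheaths and internodes expand toward these values with the same
    logistic-in-GDD functional form used for leaf blades; roots use a
    constant diameter.
    """

    sheath_length: float = 18.0
    sheath_diameter: float = 0.5
    internode_length: float = 12.0
    internode_diameter: float = 0.6
    root_length: float = 15.0
    root_diameter: float = 0.12

    @model_validator(mode="after")
    def _positive(self) -> "OrganDims":
        for name, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        return self


class CultivarParams(BaseModel):
    """All cultivar-level constants needed to simulate one rice variety."""

    name: str = "fixture"
    LN: int = Field(..., description="final leaf count on the main stem")
    m: int = Field(..., description="number of elongated internodes")
    final_leaf_lengths: Dict[int, float] = Field(
        ..., description="rank -> final blade length LL_n (cm)"
    )
    leaf_init_gdd: Dict[int, float] = Field(
        ..., description="rank -> initial GDD of leaf n, IGDD_n (deg C*d)"
    )
    leaf_grow_gdd: Dict[int, float] = Field(
        ..., description="rank -> GDD needed for full growth of leaf n (deg C*d)"
    )
    La: float = 8.65
    Lb: float = 6.26
    P: float = 0.55
    WLR: float = 12.0
    WPd: float = -0.0012
    WPe: float = 0.08
    Tv: float = 1.0
    phyllochron: float = 100.0
    row_spacing: float = 0.30
    col_spacing: float = 0.30
    base_temp: float = 10.0
    # geometry extras (plumbing, not cultivar biology)
    tiller_scale: float = 1.0
    tiller_angle_deg: float = 20.0
    visibility_fraction: float = 0.01
    heading_fix_days: float = 8.0
    root_node_offset: int = 0
    organ_dims: OrganDims = Field(default_factory=OrganDims)

    @field_validator("LN")
    @classmethod
    def _ln_min(cls, v: int) -> int:
        if v < 4:
            raise ValueError(f"LN must be >= 4, got {v}")
        return v

    @field_validator("La", "Lb", "phyllochron", "row_spacing", "col_spacing")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("leaf_grow_gdd")
    @classmethod
    def _grow_positive(cls, v: Dict[int, float]) -> Dict[int, float]:
        for rank, g in v.items():
            if g <= 0:
                raise ValueError(f"leaf_grow_gdd[{rank}] must be positive, got {g}")
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "CultivarParams":
        if not (1 <= self.m < self.LN):
            raise ValueError(f"m must satisfy 1 <= m < LN, got m={self.m}, LN={self.LN}")
        for field in ("final_leaf_lengths", "leaf_init_gdd", "leaf_grow_gdd"):
            table = getattr(self, field)
            missing = [n for n in range(1, self.LN + 1) if n not in table]
            if missing:
                raise ValueError(f"{field} missing ranks {missing}")
        if self.heading_fix_days <= 0:
            raise ValueError("heading_fix_days must be positive")
        return self

    def rank_params(self, rank: int) -> tuple[float, float, float]:
        """(LL_n, IGDD_n, dGDD_n) for one leaf rank."""
        return (
            self.final_leaf_lengths[rank],
            self.leaf_init_gdd[rank],
            self.leaf_grow_gdd[rank],
        )


class EnvironmentFactors(BaseModel):
    """Stress scaling factors, each in [0, 1] (1 = non-limiting).

    FN/FW scale organ expansion (nitrogen and water); FL/NF/WDF scale
    the daily tiller increment (leaf-age, nitrogen and water-deficit
    factors of the tiller-number model).
    """

    FN: float = 1.0
    FW: float = 1.0
    NF: float = 1.0
    WDF: float = 1.0
    FL: float = 1.0

    @field_validator("FN", "FW", "NF", "WDF", "FL")
    @classmethod
    def _unit_interval(cls, v: float, info) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{info.field_name} must be in [0, 1], got {v}")
        return v


def _int_keys(d: dict) -> dict:
    return {int(k): v for k, v in d.items()}


def load_cultivar(path: Union[str, Path]) -> CultivarParams:
    """Read a cultivar parameter file (JSON or YAML by extension).

    Raises a pydantic ``ValidationError`` naming the offending field if
    the file violates any invariant (e.g. ``m == 0``).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    for key in ("final_leaf_lengths", "leaf_init_gdd", "leaf_grow_gdd"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = _int_keys(raw[key])
    return CultivarParams.model_validate(raw)


def save_cultivar(params: CultivarParams, path: Union[str, Path]) -> Path:
    """Write a cultivar parameter file; round-trips losslessly."""
    path = Path(path)
    data = params.model_dump(mode="json")
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
    return path


def synth_cultivar(seed: int, name: str | None = None) -> CultivarParams:
    """Generate a plausible synthetic cultivar parameter set.

    Deterministic per seed.  Final leaf lengths follow the canonical
    rice profile: short early leaves rising to a maximum two to three
    ranks below the flag leaf, with the flag leaf slightly shorter.
    """
    rng = np.random.default_rng(seed)
    LN = int(rng.integers(14, 19))
    m = int(rng.integers(4, min(8, LN - 1)))
    phyllochron = float(rng.uniform(85.0, 115.0))
    peak_rank = LN - int(rng.integers(2, 4))
    max_len = float(rng.uniform(35.0, 55.0))

    lengths: Dict[int, float] = {}
    for n in range(1, LN + 1):
        # unimodal: quadratic fall-off from the peak rank, floor well above 0
        rel = 1.0 - 0.7 * ((n - peak_rank) / max(peak_rank - 1, LN - peak_rank, 1)) ** 2
        jitter = float(rng.uniform(0.97, 1.03))
        lengths[n] = round(max(3.0, max_len * rel * jitter), 2)

    init_gdd = {n: round((n - 1) * phyllochron, 1) for n in range(1, LN + 1)}
    grow_gdd = {
        n: round(float(rng.uniform(1.5, 2.5)) * phyllochron, 1) for n in range(1, LN + 1)
    }

    return CultivarParams(
        name=name or f"synthetic-{seed}",
        LN=LN,
        m=m,
        final_leaf_lengths=lengths,
        leaf_init_gdd=init_gdd,
        leaf_grow_gdd=grow_gdd,
        P=float(rng.uniform(0.4, 0.7)),
        WLR=float(rng.uniform(10.0, 14.0)),
        WPd=float(rng.uniform(-0.0015, -0.0009)),
        WPe=float(rng.uniform(0.06, 0.10)),
        Tv=float(rng.uniform(0.6, 1.2)),
        phyllochron=phyllochron,
    )
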