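"""Time-dependent organ geometry: leaf growth, width profile, area.

The leaf blade elongates along a logistic curve in thermal time,

    LL_n(GDD) = LL_n / (1 + La * exp(-Lb * (GDD - IGDD_n) / dGDD_n))
                * min(FN, FW),

where ``LL_n`` is the final length of leaf *n*, ``IGDD_n`` its initial
GDD, ``dGDD_n`` the thermal time it needs to complete growth, and
``FN``/``FW`` nitrogen and water stress factors.  ``La = 8.65`` and
``Lb = 6.26``.

The blade's full width at vein position ``x`` (measured from the tip,
so width vanishes there) is

    LWid_n(x) = P * x / WLR              for ranks 1 and LN,
    LWid_n(x) = WPd * x**2 + WPe * x     for ranks 2 .. LN-1,

clamped at zero.  Leaf area is computed by cutting the blade into
``N_sp`` equal segments perpendicular to the vein; each segment is two
symmetric trapeziums whose parallel sides are the half-widths at the
segment's ends, so

    S = 2 * sum_i (hw_i + hw_{i+1}) * (L / N_sp) / 2.

This is the trapezoid rule on the half-width profile: exact for linear
profiles and an underestimate for concave ones, so area is
nondecreasing in ``N_sp`` there.

Sheaths, internodes and roots are cylinders whose length and diameter
expand with the same logistic form toward configured final dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np

from oryzasim.params_config import CultivarParams, EnvironmentFactors

__all__ = [
    "LeafGeometry",
    "leaf_length_at",
    "leaf_width_at",
    "width_profile",
    "segment_leaf",
    "leaf_area",
    "leaf_geometry_at",
    "cylinder_organ_dims",
]


@dataclass
class LeafGeometry:
    """One leaf's current axis length, segmentation and area (cm, cm^2)."""

    rank: int
    axis_length: float
    n_segments: int
    segment_areas: List[float]
    area: float

    def __post_init__(self) -> None:
        if self.axis_length < 0:
            raise ValueError("axis_length must be >= 0")
        expected = 2.0 * sum(self.segment_areas)
        if not math.isclose(self.area, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("area must equal 2 * sum(segment_areas)")


def _logistic(gdd_now: float, final: float, igdd: float, dgdd: float,
              la: float, lb: float) -> float:
    return final / (1.0 + la * math.exp(-lb * (gdd_now - igdd) / dgdd))


def leaf_length_at(
    gdd_now: float,
    rank_params: Tuple[float, float, float],
    La: float = 8.65,
    Lb: float = 6.26,
    env: EnvironmentFactors | None = None,
    visibility_fraction: float = 0.01,
) -> float:
    """Leaf axis length (cm) at thermal time ``gdd_now``.

    ``rank_params`` is ``(LL_n, IGDD_n, dGDD_n)``.  The logistic never
    reaches zero, so lengths below ``visibility_fraction * LL_n``
    (default 1%) are reported as 0: the leaf is not yet visible.  At
    ``GDD = IGDD_n`` the length is ``LL_n / (1 + La)``; as GDD grows it
    approaches ``LL_n * min(FN, FW)``.
    """
    ll_n, igdd_n, dgdd_n = rank_params
    if dgdd_n <= 0:
        raise ValueError(f"dGDD_n must be positive, got {dgdd_n}")
    env = env or EnvironmentFactors()
    length = _logistic(gdd_now, ll_n, igdd_n, dgdd_n, La, Lb) * min(env.FN, env.FW)
    if length < visibility_fraction * ll_n:
        return 0.0
    return length


def leaf_width_at(
    x: float, rank: int, params: CultivarParams, axis_length: float
) -> float:
    """Full blade width (cm) at vein position ``x`` from the tip.

    Ranks 1 and ``LN`` use the linear form ``P * x / WLR``; middle
    ranks the quadratic ``WPd * x^2 + WPe * x``.  Negative evaluations
    clamp to zero.
    """
    if not (0.0 <= x <= axis_length + 1e-12):
        raise ValueError(f"x={x} outside [0, {axis_length}]")
    if rank in (1, params.LN):
        w = params.P * x / params.WLR
    else:
        w = params.WPd * x * x + params.WPe * x
    return max(w, 0.0)


def width_profile(rank: int, params: CultivarParams) -> Callable[[float], float]:
    """Width function ``x -> full width`` for one leaf rank."""
    if rank in (1, params.LN):
        return lambda x: max(params.P * x / params.WLR, 0.0)
    return lambda x: max(params.WPd * x * x + params.WPe * x, 0.0)


def segment_leaf(
    axis_length: float, width_fn: Callable[[float], float], n_segments: int
) -> List[float]:
    """Trapezoid areas of the ``n_segments`` half-leaf segments (cm^2).

    The vein is divided into equal intervals; each segment's area is
    ``(hw_i + hw_{i+1}) * dx / 2`` with half-widths at the interval
    ends.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if axis_length < 0:
        raise ValueError("axis_length must be >= 0")
    if axis_length == 0:
        return [0.0] * n_segments
    xs = np.linspace(0.0, axis_length, n_segments + 1)
    half = np.array([width_fn(float(x)) for x in xs]) / 2.0
    dx = axis_length / n_segments
    return list((half[:-1] + half[1:]) * dx / 2.0)


def leaf_area(
    axis_length: float, width_fn: Callable[[float], float], n_segments: int
) -> float:
    """Total leaf area ``S = 2 * sum(S_i)`` (cm^2)."""
    return 2.0 * sum(segment_leaf(axis_length, width_fn, n_segments))


def leaf_geometry_at(
    rank: int,
    gdd_now: float,
    params: CultivarParams,
    n_segments: int,
    env: EnvironmentFactors | None = None,
    scale: float = 1.0,
) -> LeafGeometry:
    """Current geometry of one leaf rank (optionally scaled for tillers)."""
    length = scale * leaf_length_at(
        gdd_now,
        params.rank_params(rank),
        params.La,
        params.Lb,
        env,
        params.visibility_fraction,
    )
    fn = width_profile(rank, params)
    segs = segment_leaf(length, fn, n_segments)
    return LeafGeometry(
        rank=rank,
        axis_length=length,
        n_segments=n_segments,
        segment_areas=segs,
        area=2.0 * sum(segs),
    )


def cylinder_organ_dims(
    organ: str,
    rank: int,
    gdd_now: float,
    params: CultivarParams,
    start_gdd: float | None = None,
    grow_gdd: float | None = None,
) -> Tuple[float, float]:
    """(length, diameter) in cm of a sheath, internode or root cylinder.

    The organ expands from its scheduled start with the same logistic
    form as the leaf blade; before the start it is (0, 0).  Raises if
    the organ was never scheduled (``start_gdd`` is None).
    """
    if organ not in {"sheath", "internode", "root"}:
        raise ValueError(f"unknown organ {organ!r}")
    if start_gdd is None:
        raise ValueError(f"{organ} rank {rank} has no scheduled start")
    dims = params.organ_dims
    final_len, final_dia = {
        "sheath": (dims.sheath_length, dims.sheath_diameter),
        "internode": (dims.internode_length, dims.internode_diameter),
        "root": (dims.root_length, dims.root_diameter),
    }[organ]
    if gdd_now < start_gdd:
        return (0.0, 0.0)
    dgdd = grow_gdd if grow_gdd is not None else 2.0 * params.phyllochron
    # logistic expansion with midpoint half-way through the growth window
    tau = gdd_now - start_gdd - 0.5 * dgdd
    frac = 1.0 / (1.0 + params.La * math.exp(-params.Lb * tau / dgdd))
    return (final_len * frac, final_dia * frac)
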