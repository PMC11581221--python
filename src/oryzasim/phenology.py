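"""Organ event scheduling from main-stem leaf age.

Rice development is tightly synchronized around the emergence of
main-stem leaves.  When leaf *n* emerges:

* sheath *n* and leaf *n+1* elongate, and the internode between leaves
  *n-1* and *n-2* elongates (only after the jointing stage for lower
  internodes);
* the first leaf appears on the tiller at node *n-3* and the second
  leaf on the tiller at node *n-4*;
* the adventitious root on leaf segment *n-3* starts to grow, segment
  *n-4* gains first-order branches and segment *n-5* second-order
  branches (branching lags its parent by exactly one leaf cycle).

The jointing stage for a cultivar with ``LN`` leaves and ``m``
elongated internodes falls at leaf age ``LN - m + 3``, equivalently the
``(m-2)``-th leaf counted from the top.  Leaf age itself is realized
here with a constant phyllochron in GDD.

Any rule that would index a rank below 1 simply emits no event: early
in development the lower positions do not exist yet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from oryzasim.params_config import CultivarParams
from oryzasim.thermal_time import GDDSeries

__all__ = [
    "LeafAge",
    "Event",
    "EventSchedule",
    "jointing_leaf_age",
    "leaf_emergence_schedule",
    "synchrony_events",
    "seedling_root_events",
    "heading_schedule",
    "root_node_count",
    "build_schedule",
]

HEADING_SPAN_DAYS = 5.0  # panicle emergence from flag-leaf sheath


@dataclass(frozen=True)
class LeafAge:
    """Continuous main-stem leaf count (emerged leaves + fraction)."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("leaf age cannot be negative")


@dataclass(frozen=True)
class Event:
    organ: str  # leaf | sheath | internode | tiller | root_segment | root_branch
    rank: int
    detail: str = ""
    order: int = 0  # branch order for root_branch events; leaf number for tiller events


def jointing_leaf_age(LN: int, m: int) -> LeafAge:
    """Leaf age at the physiological jointing stage.

    With ``LN`` total leaves and ``m`` elongated internodes, jointing
    occurs at the ``(m-2)``-th reciprocal leaf age, i.e. at absolute
    leaf age ``LN - m + 3``.  Both forms are computed and checked for
    consistency.
    """
    if not (3 <= m < LN):
        raise ValueError(f"m must satisfy 3 <= m < LN, got m={m}, LN={LN}")
    absolute = LN - m + 3
    # reciprocal rank r counts from the top: absolute rank = LN - r + 1
    reciprocal_form = LN - (m - 2) + 1
    assert absolute == reciprocal_form, "jointing leaf-age forms disagree"
    return LeafAge(float(absolute))


@dataclass
class LeafEmergence:
    """Main-stem leaf emergence times in GDD, possibly truncated."""

    emergence: Dict[int, float]
    truncated: bool = False


def leaf_emergence_schedule(params: CultivarParams, gdd: GDDSeries) -> LeafEmergence:
    """Schedule main-stem leaf emergences at a constant phyllochron.

    Leaf ``n`` emerges when the accumulation first reaches
    ``n * phyllochron``.  If the season ends before ``LN`` leaves can
    emerge, only the reachable ranks are scheduled and the result is
    flagged as truncated.
    """
    out: Dict[int, float] = {}
    truncated = False
    for n in range(1, params.LN + 1):
        target = n * params.phyllochron
        if target > gdd.total:
            truncated = True
            break
        out[n] = target
    return LeafEmergence(emergence=out, truncated=truncated)


def synchrony_events(n: int, params: CultivarParams) -> List[Event]:
    """Organ events triggered by the emergence of main-stem leaf ``n``.

    Internode ``n-2`` (the one between leaves ``n-1`` and ``n-2``)
    elongates only if it is one of the top ``m`` internodes — lower
    internodes stay frozen until after jointing, and with the jointing
    leaf age at ``LN - m + 3`` the first unfrozen internode
    (rank ``LN - m + 1``) is triggered exactly at jointing.
    """
    if not (1 <= n <= params.LN):
        raise ValueError(f"leaf rank {n} out of range 1..{params.LN}")
    events: List[Event] = [Event("sheath", n, "elongate")]
    if n + 1 <= params.LN:
        events.append(Event("leaf", n + 1, "elongate"))
    internode_rank = n - 2
    first_elongating = params.LN - params.m + 1
    if internode_rank >= first_elongating and internode_rank >= 1:
        events.append(Event("internode", internode_rank, "elongate"))
    if n - 3 >= 1:
        events.append(Event("tiller", n - 3, "leaf_appears", order=1))
        events.append(Event("root_segment", n - 3, "start"))
    if n - 4 >= 1:
        events.append(Event("tiller", n - 4, "leaf_appears", order=2))
        events.append(Event("root_branch", n - 4, "branch", order=1))
    if n - 5 >= 1:
        events.append(Event("root_branch", n - 5, "branch", order=2))
    return events


def seedling_root_events() -> List[Tuple[int, str, Optional[int]]]:
    """Root events of the first three leaf stages, in order.

    Adventitious roots appear on the coleoptile segment with leaf 1,
    reach about five roots with leaf 2, and the incomplete-leaf segment
    roots become visible with leaf 3.
    """
    return [
        (1, "coleoptile_roots_appear", None),
        (2, "coleoptile_root_count", 5),
        (3, "incomplete_leaf_segment_roots_appear", None),
    ]


@dataclass(frozen=True)
class HeadingSchedule:
    start_day: float
    end_day: float
    internode_fix_day: float
    start_gdd: float
    end_gdd: float
    internode_fix_gdd: float


def heading_schedule(
    internode_elongate_top: float, gdd: GDDSeries, fix_days: float = 8.0
) -> HeadingSchedule:
    """Heading window from the uppermost internode's elongation start.

    Heading (panicle emergence from the flag-leaf sheath) begins with
    the uppermost internode's elongation and spans about 5 days; that
    internode reaches fixed length 7-9 days after the start (default 8,
    roughly one leaf cycle).  Day-based spans are mapped back to GDD
    through the weather series.
    """
    start_day = gdd.day_at_gdd(internode_elongate_top)
    end_day = start_day + HEADING_SPAN_DAYS
    fix_day = start_day + fix_days
    last = float(gdd.days[-1])
    return HeadingSchedule(
        start_day=start_day,
        end_day=end_day,
        internode_fix_day=fix_day,
        start_gdd=internode_elongate_top,
        end_gdd=gdd.gdd_at_day(min(end_day, last)),
        internode_fix_gdd=gdd.gdd_at_day(min(fix_day, last)),
    )


def root_node_count(LN: int, m: int, offset: int = 0) -> int:
    """Number of root-bearing nodes on a culm.

    Computed from the total leaf count and the elongated internode
    count as ``LN - m + offset``: nodes whose internodes elongate are
    lifted above the soil and bear no roots.  The offset accommodates
    cultivar-convention differences in counting the basal segments.
    """
    if not (1 <= m < LN):
        raise ValueError(f"invalid (LN, m) = ({LN}, {m})")
    count = LN - m + offset
    if count < 0:
        raise ValueError("offset drives root node count negative")
    return count


@dataclass
class EventSchedule:
    """The dated tree of organ events for one plant, all times in GDD."""

    leaf_emerge: Dict[Tuple[str, int], float] = field(default_factory=dict)
    sheath_elongate: Dict[Tuple[str, int], float] = field(default_factory=dict)
    internode_elongate: Dict[Tuple[str, int], float] = field(default_factory=dict)
    tiller_emerge: Dict[int, float] = field(default_factory=dict)
    root_segment_start: Dict[int, float] = field(default_factory=dict)
    root_branch_start: Dict[Tuple[int, int], float] = field(default_factory=dict)
    heading: Optional[HeadingSchedule] = None
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (axis, rank), g in sorted(self.leaf_emerge.items()):
            rows.append((axis, "leaf", rank, "emerge", g))
        for (axis, rank), g in sorted(self.sheath_elongate.items()):
            rows.append((axis, "sheath", rank, "elongate", g))
        for (axis, rank), g in sorted(self.internode_elongate.items()):
            rows.append((axis, "internode", rank, "elongate", g))
        for node, g in sorted(self.tiller_emerge.items()):
            rows.append(("main", "tiller", node, "emerge", g))
        for rank, g in sorted(self.root_segment_start.items()):
            rows.append(("main", "root_segment", rank, "start", g))
        for (rank, order), g in sorted(self.root_branch_start.items()):
            rows.append(("main", "root_branch", rank, f"branch_order_{order}", g))
        return pd.DataFrame(rows, columns=["axis", "organ", "rank", "event", "gdd"])

    def export_csv(self, path: Union[str, Path], gdd: Optional[GDDSeries] = None) -> Path:
        df = self.to_frame()
        if gdd is not None:
            df["day"] = [gdd.day_at_gdd(g) for g in df["gdd"]]
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def build_schedule(params: CultivarParams, gdd: GDDSeries) -> EventSchedule:
    """Assemble the full event schedule for one plant.

    Applies the per-leaf synchrony rules at each main-stem leaf
    emergence time, schedules tiller first leaves at node ``n-3``
    exactly at the triggering leaf's emergence, and derives the heading
    window from the uppermost internode's elongation (scheduled one
    phyllochron after the flag leaf where the season allows).
    """
    emerg = leaf_emergence_schedule(params, gdd)
    sched = EventSchedule(truncated=emerg.truncated)
    for n, t in emerg.emergence.items():
        sched.leaf_emerge[("main", n)] = t
        for ev in synchrony_events(n, params):
            if ev.organ == "sheath":
                sched.sheath_elongate[("main", ev.rank)] = t
            elif ev.organ == "internode":
                sched.internode_elongate[("main", ev.rank)] = t
            elif ev.organ == "tiller" and ev.order == 1:
                sched.tiller_emerge[ev.rank] = t
            elif ev.organ == "root_segment":
                sched.root_segment_start[ev.rank] = t
            elif ev.organ == "root_branch":
                sched.root_branch_start[(ev.rank, ev.order)] = t
        # tiller leaves track the main stem: leaf k on the tiller at node v
        # appears with main-stem leaf v + 2 + k
        if n - 3 >= 1:
            node = n - 3
            for k in range(1, params.LN - node - 1):
                tk = emerg.emergence.get(node + 2 + k)
                if tk is not None:
                    sched.leaf_emerge[(f"tiller{node}", k)] = tk
    # uppermost internode: one leaf cycle after the flag leaf
    if params.LN in emerg.emergence:
        top_gdd = emerg.emergence[params.LN] + params.phyllochron
        if top_gdd <= gdd.total:
            sched.internode_elongate[("main", params.LN)] = top_gdd
            sched.heading = heading_schedule(top_gdd, gdd, params.heading_fix_days)
    return sched
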