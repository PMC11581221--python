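"""3D assembly: plant meshes, population scenes, LOD and OBJ export.

Coordinate convention: right-handed, +z up, ground plane z = 0, the
planting grid in the x-y plane, all coordinates in meters.  Organ
dimensions arrive from :mod:`oryzasim.organ_geometry` in cm and are
converted here.

A plant is assembled bottom-up from its event schedule: internode
cylinders stack into the culm, each node carries a sheath cylinder and
a leaf ribbon built from the blade's width profile, tillers are scaled
culms leaning out at a configurable angle, root-segment cylinders fan
out below the base with branch counts from the phenology rules, and a
tapered panicle appears once heading starts.  Population scenes place
varied plant instances on an exact grid with seeded parameter variation
in [M-d, M+d] and uniform random rotation about the vertical axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import trimesh

from oryzasim.organ_geometry import (
    cylinder_organ_dims,
    leaf_length_at,
    width_profile,
)
from oryzasim.params_config import CultivarParams, EnvironmentFactors
from oryzasim.phenology import EventSchedule
from oryzasim.tillering import allocate_tillers

__all__ = [
    "GrowthUnit",
    "PlantInstance",
    "PopulationScene",
    "build_plant",
    "build_population",
    "simplify_mesh",
    "lod_for_distance",
    "export_scene",
    "obj_object_names",
    "obj_vertex_count",
]

CM = 0.01  # cm -> m


def _cylinder(length_m: float, diameter_m: float, sections: int = 8) -> trimesh.Trimesh:
    """Upright cylinder with its base at the origin."""
    mesh = trimesh.creation.cylinder(
        radius=max(diameter_m / 2.0, 1e-6),
        height=max(length_m, 1e-6),
        sections=sections,
    )
    mesh.apply_translation([0.0, 0.0, length_m / 2.0])
    return mesh


def _leaf_ribbon(
    length_cm: float,
    width_fn,
    n_segments: int,
    inclination_deg: float,
) -> trimesh.Trimesh:
    """Flat triangulated blade along an inclined midrib, base at origin.

    Stations along the vein carry the full width from the profile
    (position measured from the tip); two triangles per station pair.
    """
    length = length_cm * CM
    incl = math.radians(inclination_deg)
    ts = np.linspace(0.0, 1.0, n_segments + 1)
    verts = []
    for t in ts:
        s = t * length_cm
        # width profile is indexed from the tip
        w = width_fn(length_cm - s) * CM
        x = t * length * math.sin(incl)
        z = t * length * math.cos(incl)
        verts.append([x, -w / 2.0, z])
        verts.append([x, w / 2.0, z])
    faces = []
    for i in range(n_segments):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        faces.append([a, b, c])
        faces.append([b, d, c])
    return trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)


@dataclass
class GrowthUnit:
    """One node's bundle of organ meshes on one axis."""

    axis: str
    rank: int
    node_position: np.ndarray
    meshes: Dict[str, trimesh.Trimesh] = field(default_factory=dict)


@dataclass
class PlantInstance:
    """A single plant's assembled growth units plus placement."""

    params: CultivarParams
    gdd_now: float
    growth_units: List[GrowthUnit]
    tiller_angles: Dict[int, float] = field(default_factory=dict)
    rotation_deg: float = 0.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    varied: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_organs(self) -> int:
        return sum(len(u.meshes) for u in self.growth_units)

    def organ_meshes(self) -> List[Tuple[str, str, int, trimesh.Trimesh]]:
        """(organ_class, axis, rank, mesh placed in world coordinates)."""
        rot = trimesh.transformations.rotation_matrix(
            math.radians(self.rotation_deg), [0, 0, 1]
        )
        out = []
        for unit in self.growth_units:
            for organ, mesh in unit.meshes.items():
                placed = mesh.copy()
                placed.apply_transform(rot)
                placed.apply_translation(self.position)
                out.append((organ, unit.axis, unit.rank, placed))
        return out

    def as_mesh(self) -> trimesh.Trimesh:
        meshes = [m for _, _, _, m in self.organ_meshes()]
        if not meshes:
            return trimesh.Trimesh(
                vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int),
                process=False,
            )
        return trimesh.util.concatenate(meshes)


def _build_axis(
    axis: str,
    leaf_ranks: Sequence[int],
    base: np.ndarray,
    lean_deg: float,
    params: CultivarParams,
    schedule: EventSchedule,
    gdd_now: float,
    env: EnvironmentFactors,
    rng: np.random.Generator,
    n_segments: int,
    scale: float = 1.0,
) -> List[GrowthUnit]:
    units: List[GrowthUnit] = []
    z = 0.0
    lean = math.radians(lean_deg)
    direction = np.array([math.sin(lean), 0.0, math.cos(lean)])
    for rank in leaf_ranks:
        meshes: Dict[str, trimesh.Trimesh] = {}
        node = base + z * direction

        ie_start = schedule.internode_elongate.get(("main", rank))
        if ie_start is not None and ie_start <= gdd_now:
            ilen, idia = cylinder_organ_dims(
                "internode", rank, gdd_now, params, start_gdd=ie_start
            )
            if ilen > 0:
                mesh = _cylinder(scale * ilen * CM, scale * idia * CM)
                mesh.apply_translation(node)
                meshes["internode"] = mesh
                z += scale * ilen * CM

        sh_start = schedule.sheath_elongate.get(("main", rank))
        if sh_start is not None and sh_start <= gdd_now:
            slen, sdia = cylinder_organ_dims(
                "sheath", rank, gdd_now, params, start_gdd=sh_start
            )
            if slen > 0:
                mesh = _cylinder(scale * slen * CM, scale * sdia * CM)
                mesh.apply_translation(base + z * direction)
                meshes["sheath"] = mesh

        length = scale * leaf_length_at(
            gdd_now,
            params.rank_params(rank),
            params.La,
            params.Lb,
            env,
            params.visibility_fraction,
        )
        if length > 0:
            # leaves alternate sides up the culm with a little azimuth jitter
            azimuth = (rank % 2) * 180.0 + float(rng.uniform(-15.0, 15.0))
            blade = _leaf_ribbon(length, width_profile(rank, params), n_segments, 35.0)
            blade.apply_transform(
                trimesh.transformations.rotation_matrix(
                    math.radians(azimuth), [0, 0, 1]
                )
            )
            blade.apply_translation(base + z * direction)
            meshes["leaf"] = blade

        if meshes:
            units.append(GrowthUnit(axis=axis, rank=rank, node_position=node, meshes=meshes))
    return units


def build_plant(
    params: CultivarParams,
    schedule: EventSchedule,
    gdd_now: float,
    seed: int,
    env: Optional[EnvironmentFactors] = None,
    n_segments: int = 10,
) -> PlantInstance:
    """Assemble one plant at thermal time ``gdd_now``.

    Includes exactly the organs whose scheduled emergence is at or
    before ``gdd_now``; organ dimensions come from the geometry module
    at ``gdd_now``.  Deterministic per seed.  Before the first leaf the
    plant has no growth units.
    """
    env = env or EnvironmentFactors()
    rng = np.random.default_rng(seed)
    units: List[GrowthUnit] = []
    origin = np.zeros(3)

    emerged = sorted(
        rank
        for (axis, rank), t in schedule.leaf_emerge.items()
        if axis == "main" and t <= gdd_now
    )
    units.extend(
        _build_axis(
            "main", emerged, origin, 0.0, params, schedule, gdd_now, env, rng, n_segments
        )
    )

    tiller_angles: Dict[int, float] = {}
    for node, t in sorted(schedule.tiller_emerge.items()):
        if t > gdd_now:
            continue
        angle = params.tiller_angle_deg + float(rng.uniform(-5.0, 5.0))
        tiller_angles[node] = angle
        azimuth = float(rng.uniform(0.0, 360.0))
        # tiller leaf k tracks main-stem leaf node + 2 + k
        t_ranks = [
            k
            for (axis, k), tk in schedule.leaf_emerge.items()
            if axis == f"tiller{node}" and tk <= gdd_now
        ]
        t_units = _build_axis(
            f"tiller{node}",
            sorted(t_ranks),
            origin,
            angle,
            params,
            schedule,
            gdd_now,
            env,
            rng,
            n_segments,
            scale=params.tiller_scale,
        )
        rot = trimesh.transformations.rotation_matrix(math.radians(azimuth), [0, 0, 1])
        for u in t_units:
            for mesh in u.meshes.values():
                mesh.apply_transform(rot)
        units.extend(t_units)

    # roots: one cylinder per started segment plus thinner branch cylinders
    for seg, t0 in sorted(schedule.root_segment_start.items()):
        if t0 > gdd_now:
            continue
        rlen, rdia = cylinder_organ_dims("root", seg, gdd_now, params, start_gdd=t0)
        if rlen <= 0:
            continue
        meshes: Dict[str, trimesh.Trimesh] = {}
        n_branches = sum(
            1
            for (s, order), tb in schedule.root_branch_start.items()
            if s == seg and tb <= gdd_now
        )
        polar = math.radians(120.0 + float(rng.uniform(-15.0, 15.0)))
        azim = float(rng.uniform(0.0, 2.0 * math.pi))
        root = _cylinder(rlen * CM, rdia * CM, sections=6)
        tilt = trimesh.transformations.rotation_matrix(polar, [math.cos(azim), math.sin(azim), 0])
        root.apply_transform(tilt)
        meshes["root"] = root
        for b in range(n_branches):
            blen, bdia = rlen * 0.4, rdia * 0.5
            branch = _cylinder(blen * CM, bdia * CM, sections=6)
            branch.apply_transform(
                trimesh.transformations.rotation_matrix(
                    polar + math.radians(20.0 * (b + 1)),
                    [math.cos(azim + b), math.sin(azim + b), 0],
                )
            )
            branch.apply_translation(root.vertices.mean(axis=0))
            meshes[f"root_branch{b + 1}"] = branch
        units.append(GrowthUnit(axis="root", rank=seg, node_position=np.zeros(3), meshes=meshes))

    # panicle: tapered cylinder at the top of the culm once heading begins
    if schedule.heading is not None and schedule.heading.start_gdd <= gdd_now:
        top_z = max(
            (float(u.node_position[2]) for u in units if u.axis == "main"), default=0.0
        )
        panicle = _cylinder(0.18, 0.004, sections=6)
        panicle.vertices[:, :2] *= np.linspace(
            1.0, 0.2, len(panicle.vertices)
        ).reshape(-1, 1)[: len(panicle.vertices)]
        panicle.apply_translation([0.0, 0.0, top_z + 0.05])
        units.append(
            GrowthUnit(
                axis="main",
                rank=params.LN + 1,
                node_position=np.array([0.0, 0.0, top_z]),
                meshes={"panicle": panicle},
            )
        )

    return PlantInstance(
        params=params,
        gdd_now=gdd_now,
        growth_units=units,
        tiller_angles=tiller_angles,
        seed=seed,
    )


@dataclass
class PopulationScene:
    """Grid of varied plant instances."""

    rows: int
    cols: int
    row_spacing: float
    col_spacing: float
    plants: List[PlantInstance]
    seed: int
    variation_halfwidth: Dict[str, float] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "row_spacing": self.row_spacing,
            "col_spacing": self.col_spacing,
            "seed": self.seed,
            "variation_halfwidth": self.variation_halfwidth,
            "plants": [
                {
                    "position": p.position.tolist(),
                    "rotation_deg": p.rotation_deg,
                    "seed": p.seed,
                    "varied": p.varied,
                }
                for p in self.plants
            ],
        }


_VARIABLE_FIELDS = {
    "P", "WLR", "WPd", "WPe", "Tv", "phyllochron", "tiller_angle_deg",
    "La", "Lb", "tiller_scale",
}


def build_population(
    params: CultivarParams,
    schedule: EventSchedule,
    gdd_now: float,
    rows: int,
    cols: int,
    spacing: Union[float, Tuple[float, float]] = 0.30,
    d_map: Optional[Dict[str, float]] = None,
    seed: int = 0,
    env: Optional[EnvironmentFactors] = None,
    n_segments: int = 10,
) -> PopulationScene:
    """Generate a rows x cols population on an exact grid.

    Each plant's varied parameters are drawn uniformly from
    ``[M - d, M + d]`` where ``M`` is the cultivar value and ``d`` the
    half-width from ``d_map`` (keys are scalar cultivar fields, plus
    ``leaf_length`` for an additive perturbation of every final leaf
    length in cm).  Every plant also gets a uniform random rotation
    about the vertical axis.  Fully reproducible per seed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if isinstance(spacing, (int, float)):
        row_sp = col_sp = float(spacing)
    else:
        row_sp, col_sp = spacing
    d_map = d_map or {}
    unknown = set(d_map) - _VARIABLE_FIELDS - {"leaf_length"}
    if unknown:
        raise ValueError(f"unknown varied parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    plants: List[PlantInstance] = []
    for i in range(rows):
        for j in range(cols):
            varied: Dict[str, float] = {}
            update: Dict[str, object] = {}
            for key, d in sorted(d_map.items()):
                if key == "leaf_length":
                    shift = float(rng.uniform(-d, d))
                    update["final_leaf_lengths"] = {
                        r: max(v + shift, 0.5)
                        for r, v in params.final_leaf_lengths.items()
                    }
                    varied[key] = shift
                else:
                    M = float(getattr(params, key))
                    val = float(rng.uniform(M - d, M + d))
                    update[key] = val
                    varied[key] = val
            p = params.model_copy(update=update) if update else params
            plant_seed = int(rng.integers(0, 2**31 - 1))
            plant = build_plant(p, schedule, gdd_now, plant_seed, env, n_segments)
            plant.rotation_deg = float(rng.uniform(0.0, 360.0))
            plant.position = np.array([row_sp * i, col_sp * j, 0.0])
            plant.varied = varied
            plants.append(plant)
    return PopulationScene(
        rows=rows,
        cols=cols,
        row_spacing=row_sp,
        col_spacing=col_sp,
        plants=plants,
        seed=seed,
        variation_halfwidth=dict(d_map),
    )


def simplify_mesh(
    mesh: trimesh.Trimesh, target_fraction: float, bbox_tolerance: float = 0.05
) -> trimesh.Trimesh:
    """Decimate a mesh by vertex clustering to a target face fraction.

    Vertices are snapped to a uniform grid and merged; the grid is
    refined from fine to coarse and the finest resolution whose face
    count is at most ``ceil(target_fraction * n_faces)`` wins, so the
    result keeps as much geometry as the budget allows and the face
    count never increases.  A degenerate input (no faces) is returned
    unchanged with a warning.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")
    if len(mesh.faces) == 0:
        warnings.warn("degenerate mesh: returned unchanged")
        return mesh.copy()
    if target_fraction == 1.0:
        return mesh.copy()
    target_faces = math.ceil(target_fraction * len(mesh.faces))
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces)
    lo = verts.min(axis=0)
    extent = max(float((verts.max(axis=0) - lo).max()), 1e-12)
    for divisions in (256, 192, 128, 96, 64, 48, 32, 24, 16, 12, 8, 6, 4, 3, 2, 1):
        cell = extent / divisions
        keys = np.floor((verts - lo) / cell).astype(np.int64)
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        n_clusters = inverse.max() + 1
        new_verts = np.zeros((n_clusters, 3))
        counts = np.bincount(inverse, minlength=n_clusters).astype(float)
        for k in range(3):
            new_verts[:, k] = np.bincount(inverse, weights=verts[:, k], minlength=n_clusters) / counts
        new_faces = inverse[faces]
        ok = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = np.unique(np.sort(new_faces[ok], axis=1), axis=0) if ok.any() else np.zeros((0, 3), dtype=int)
        if len(new_faces) <= target_faces:
            out = trimesh.Trimesh(vertices=new_verts, faces=new_faces, process=False)
            return out
    return mesh.copy()  # pragma: no cover - divisions=1 always collapses


DEFAULT_LOD_THRESHOLDS: Tuple[Tuple[float, float], ...] = (
    (2.0, 1.0),
    (5.0, 0.5),
    (10.0, 0.25),
)


def lod_for_distance(
    distance: float,
    thresholds: Sequence[Tuple[float, float]] = DEFAULT_LOD_THRESHOLDS,
    min_fraction: float = 0.1,
) -> float:
    """Level-of-detail face fraction for a viewpoint distance (m).

    Piecewise-constant and nonincreasing: within the first threshold
    distance full detail (1.0) is kept; beyond the last, the minimum
    fraction applies.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    fractions = [f for _, f in thresholds]
    if any(f2 > f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("threshold fractions must be nonincreasing")
    for max_dist, fraction in thresholds:
        if distance <= max_dist:
            return fraction
    return min_fraction


def export_scene(
    scene: PopulationScene, path: Union[str, Path], format: str = "obj"
) -> Path:
    """Write a population scene as ASCII Wavefront OBJ plus a manifest.

    One named ``o`` object per plant, one ``g`` group per organ class
    within it.  An empty scene produces a valid OBJ with zero objects.
    The manifest JSON (same stem, ``.manifest.json``) records
    positions, rotations and seeds sufficient to reproduce the scene.
    """
    if format != "obj":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    lines = ["# oryzasim population scene"]
    offset = 1
    for pi, plant in enumerate(scene.plants):
        lines.append(f"o plant_{pi:03d}")
        by_class: Dict[str, List[trimesh.Trimesh]] = {}
        for organ, _, _, mesh in plant.organ_meshes():
            organ_class = "root" if organ.startswith("root") else organ
            by_class.setdefault(organ_class, []).append(mesh)
        for organ_class in sorted(by_class):
            lines.append(f"g plant_{pi:03d}_{organ_class}")
            for mesh in by_class[organ_class]:
                for v in mesh.vertices:
                    lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
                for f in mesh.faces:
                    lines.append(
                        f"f {f[0] + offset} {f[1] + offset} {f[2] + offset}"
                    )
                offset += len(mesh.vertices)
    path.write_text("\n".join(lines) + "\n")
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(scene.manifest(), indent=2))
    return path


def obj_vertex_count(path: Union[str, Path]) -> int:
    """Count vertex records in an OBJ file."""
    return sum(
        1 for line in Path(path).read_text().splitlines() if line.startswith("v ")
    )


def obj_object_names(path: Union[str, Path]) -> List[str]:
    """Named top-level objects in an OBJ file, in order."""
    return [
        line.split(maxsplit=1)[1]
        for line in Path(path).read_text().splitlines()
        if line.startswith("o ")
    ]
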