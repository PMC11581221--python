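import numpy as np
import pytest
import trimesh

from oryzasim import (
    build_plant,
    build_population,
    build_schedule,
    export_scene,
    lod_for_distance,
    simplify_mesh,
)
from oryzasim.plant3d import obj_object_names, obj_vertex_count


@pytest.fixture(scope="module")
def schedule(cultivar, gdd_series):
    return build_schedule(cultivar, gdd_series)


class TestBuildPlant:
    def test_no_organs_before_first_event(self, cultivar, schedule):
        plant = build_plant(cultivar, schedule, gdd_now=0.0, seed=1)
        assert plant.growth_units == []

    def test_organ_count_nondecreasing_in_gdd(self, cultivar, schedule, gdd_series):
        gdds = np.linspace(0, gdd_series.total, 8)
        counts = [build_plant(cultivar, schedule, g, seed=1).n_organs for g in gdds]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_same_seed_gives_identical_mesh(self, cultivar, schedule):
        a = build_plant(cultivar, schedule, 1200.0, seed=7).as_mesh()
        b = build_plant(cultivar, schedule, 1200.0, seed=7).as_mesh()
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_mesh_is_finite_and_rooted_at_ground(self, cultivar, schedule):
        mesh = build_plant(cultivar, schedule, 1500.0, seed=3).as_mesh()
        assert np.all(np.isfinite(mesh.vertices))
        assert len(mesh.faces) > 0
        # shoot above ground, roots below
        assert mesh.vertices[:, 2].max() > 0
        assert mesh.vertices[:, 2].min() < 0

    def test_organ_dimensions_never_shrink_over_gdd(self, cultivar, schedule, gdd_series):
        # lifecycle appear -> expand -> fixed: bounding height is monotone
        heights = []
        for g in np.linspace(200, gdd_series.total, 6):
            mesh = build_plant(cultivar, schedule, g, seed=2).as_mesh()
            heights.append(mesh.vertices[:, 2].max() if len(mesh.vertices) else 0.0)
        assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))


class TestPopulation:
    def test_grid_positions_exact(self, cultivar, schedule):
        scene = build_population(cultivar, schedule, 800.0, rows=5, cols=5,
                                 spacing=0.30, seed=11)
        assert len(scene.plants) == 25
        positions = {tuple(np.round(p.position[:2], 9)) for p in scene.plants}
        expected = {(round(0.3 * i, 9), round(0.3 * j, 9)) for i in range(5) for j in range(5)}
        assert positions == expected

    def test_zero_halfwidth_gives_identical_parameters(self, cultivar, schedule):
        scene = build_population(
            cultivar, schedule, 800.0, rows=2, cols=2, seed=3,
            d_map={"phyllochron": 0.0, "Tv": 0.0},
        )
        for p in scene.plants:
            assert p.varied["phyllochron"] == cultivar.phyllochron
            assert p.varied["Tv"] == cultivar.Tv

    def test_varied_parameters_within_band(self, cultivar, schedule):
        d_map = {"phyllochron": 8.0, "tiller_angle_deg": 5.0}
        scene = build_population(cultivar, schedule, 800.0, rows=3, cols=3,
                                 seed=4, d_map=d_map)
        for p in scene.plants:
            for key, d in d_map.items():
                M = getattr(cultivar, key)
                assert M - d <= p.varied[key] <= M + d

    def test_rotations_sampled_and_reproducible(self, cultivar, schedule):
        s1 = build_population(cultivar, schedule, 800.0, 2, 2, seed=5)
        s2 = build_population(cultivar, schedule, 800.0, 2, 2, seed=5)
        rots = [p.rotation_deg for p in s1.plants]
        assert rots == [p.rotation_deg for p in s2.plants]
        assert len(set(rots)) > 1
        assert all(0 <= r < 360 for r in rots)

    def test_unknown_varied_parameter_rejected(self, cultivar, schedule):
        with pytest.raises(ValueError):
            build_population(cultivar, schedule, 800.0, 1, 1, d_map={"bogus": 1.0})


@pytest.fixture(scope="module")
def dense_mesh():
    return trimesh.creation.icosphere(subdivisions=3)  # 1280 faces


class TestSimplify:

    def test_identity_at_fraction_one(self, dense_mesh):
        out = simplify_mesh(dense_mesh, 1.0)
        assert len(out.faces) == len(dense_mesh.faces)

    @pytest.mark.parametrize("fraction", [0.5, 0.25, 0.1])
    def test_face_budget_respected(self, dense_mesh, fraction):
        out = simplify_mesh(dense_mesh, fraction)
        assert len(out.faces) <= np.ceil(fraction * len(dense_mesh.faces))
        assert len(out.faces) > 0

    def test_bounding_box_roughly_preserved(self, dense_mesh):
        out = simplify_mesh(dense_mesh, 0.5)
        orig = dense_mesh.bounds
        new = out.bounds
        diag = np.linalg.norm(orig[1] - orig[0])
        assert np.abs(new - orig).max() <= 0.1 * diag

    def test_degenerate_mesh_returned_unchanged_with_warning(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int),
                                process=False)
        with pytest.warns(UserWarning):
            out = simplify_mesh(empty, 0.5)
        assert len(out.faces) == 0

    def test_bad_fraction_rejected(self, dense_mesh):
        with pytest.raises(ValueError):
            simplify_mesh(dense_mesh, 0.0)


class TestLOD:
    def test_zero_distance_full_detail(self):
        assert lod_for_distance(0.0) == 1.0

    def test_monotone_nonincreasing(self):
        ds = np.linspace(0, 30, 40)
        fr = [lod_for_distance(d) for d in ds]
        assert all(b <= a for a, b in zip(fr, fr[1:]))

    def test_beyond_last_threshold_minimum(self):
        assert lod_for_distance(1e6) == 0.1


class TestExport:
    def test_empty_scene_valid_obj(self, cultivar, tmp_path):
        from oryzasim.plant3d import PopulationScene

        scene = PopulationScene(1, 1, 0.3, 0.3, [], seed=0)
        path = export_scene(scene, tmp_path / "empty.obj")
        assert obj_object_names(path) == []
        assert obj_vertex_count(path) == 0

    def test_round_trip_preserves_vertex_count(self, cultivar, schedule, tmp_path):
        scene = build_population(cultivar, schedule, 900.0, 2, 2, seed=1)
        path = export_scene(scene, tmp_path / "pop.obj")
        written = obj_vertex_count(path)
        loaded = trimesh.load(path, process=False, maintain_order=True)
        n_loaded = sum(len(g.vertices) for g in loaded.geometry.values()) \
            if isinstance(loaded, trimesh.Scene) else len(loaded.vertices)
        assert written == n_loaded > 0

    def test_one_named_object_per_plant(self, cultivar, schedule, tmp_path):
        scene = build_population(cultivar, schedule, 900.0, 5, 5, seed=2)
        path = export_scene(scene, tmp_path / "pop25.obj")
        names = obj_object_names(path)
        assert len(names) == 25
        assert names[0] == "plant_000"
        # manifest written alongside
        assert (tmp_path / "pop25.manifest.json").exists()
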