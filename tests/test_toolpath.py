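import math

import numpy as np
import pytest
import trimesh
from shapely.geometry import box

from woundpatch.core import SurfaceMesh
from woundpatch.toolpath import (ConfigError, PrintSettings, RegionModifier,
                                 generate_toolpath, make_perimeters,
                                 plan_gcode, rectilinear_infill, slice_mesh)


def cuboid(lx, ly, lz):
    tm = trimesh.creation.box(extents=[lx, ly, lz])
    tm.apply_translation([lx / 2, ly / 2, lz / 2])
    return SurfaceMesh.from_trimesh(tm, provenance="cuboid")


class TestSettings:
    def test_defaults_valid(self):
        PrintSettings().validate()

    @pytest.mark.parametrize("kw", [
        {"infill_density": 0.0}, {"infill_density": 1.5},
        {"layer_height": 0.5}, {"perimeters": -1},
        {"speed": 0.0},
    ])
    def test_invalid_settings(self, kw):
        with pytest.raises(ConfigError):
            PrintSettings(**kw).validate()

    def test_angle_alternates_by_default(self):
        s = PrintSettings()
        assert [s.angle_for_layer(k) for k in range(4)] == [0, 90, 0, 90]
        assert PrintSettings(infill_angle=45.0).angle_for_layer(3) == 45.0


class TestSlicing:
    def test_layer_count_and_midplane_heights(self):
        sliced = slice_mesh(cuboid(10, 10, 8.0), 0.16)
        assert len(sliced) == 50
        zs = [z for z, _ in sliced]
        assert zs[0] == pytest.approx(0.08)
        assert np.allclose(np.diff(zs), 0.16)

    def test_slice_areas_match_cross_section(self):
        sliced = slice_mesh(cuboid(10, 20, 2.0), 0.5)
        for _, polys in sliced:
            assert sum(p.area for p in polys) == pytest.approx(200.0)

    def test_open_mesh_rejected(self):
        tm = trimesh.creation.box()
        broken = SurfaceMesh(tm.vertices, tm.faces[:-1])
        from woundpatch.core import GeometryError
        with pytest.raises(GeometryError, match="watertight"):
            slice_mesh(broken, 0.16)


class TestPerimeters:
    def test_inset_positions(self):
        loops = make_perimeters(box(0, 0, 10, 10), count=2, width=0.4)
        assert len(loops) == 2
        b0 = np.asarray(loops[0].points)
        b1 = np.asarray(loops[1].points)
        assert b0.min() == pytest.approx(0.2) and b0.max() == pytest.approx(9.8)
        assert b1.min() == pytest.approx(0.6) and b1.max() == pytest.approx(9.4)

    def test_loops_are_closed(self):
        for loop in make_perimeters(box(0, 0, 5, 5), 2, 0.4):
            assert np.allclose(loop.points[0], loop.points[-1])

    def test_too_many_perimeters_vanish(self):
        # 1 mm square: the 0.2 mm inset fits but the 0.6 mm one does not
        loops = make_perimeters(box(0, 0, 1, 1), count=5, width=0.4)
        assert len(loops) == 1
        # region smaller than one line width yields nothing at all
        assert make_perimeters(box(0, 0, 0.3, 0.3), count=5, width=0.4) == []


class TestRectilinearInfill:
    def test_pitch_is_width_over_density(self):
        lines = rectilinear_infill(box(0, 0, 30, 20), density=0.4, angle=0.0,
                                   width=0.4, connect=False)
        ys = sorted({float(p.points[0][1]) for p in lines})
        assert np.allclose(np.diff(ys), 1.0)  # 0.4 / 0.4 = 1.000 mm exactly
        # phase anchored at the world origin: offsets are integer multiples
        assert all(abs(y - round(y)) < 1e-9 for y in ys)

    def test_angle_rotates_lines(self):
        lines = rectilinear_infill(box(0, 0, 30, 30), density=0.4, angle=45.0,
                                   width=0.4, connect=False)
        for p in lines:
            seg = np.diff(p.points, axis=0)
            ang = np.degrees(np.arctan2(seg[:, 1], seg[:, 0])) % 180.0
            assert np.allclose(ang, 45.0, atol=0.1)

    def test_connect_joins_into_serpentine(self):
        sep = rectilinear_infill(box(0, 0, 10, 10), 0.4, 0.0, 0.4, connect=False)
        joined = rectilinear_infill(box(0, 0, 10, 10), 0.4, 0.0, 0.4, connect=True)
        assert len(joined) < len(sep)
        assert sum(len(p.points) for p in joined) >= sum(len(p.points) for p in sep)

    def test_invalid_density(self):
        with pytest.raises(ConfigError):
            rectilinear_infill(box(0, 0, 5, 5), 0.0, 0.0, 0.4)

    def test_fill_fraction_on_cuboid(self):
        mesh = cuboid(30, 20, 8)
        settings = PrintSettings(perimeters=0, top_bottom_layers=0,
                                 infill_density=0.40)
        program, estimate = plan_gcode(generate_toolpath(mesh, settings))
        fraction = estimate.bioink_volume_ml * 1000.0 / mesh.volume()
        assert fraction == pytest.approx(0.40, abs=0.02)


class TestRegionModifiers:
    def test_empty_modifier_list_is_identity(self):
        mesh = cuboid(20, 10, 1.0)
        s = PrintSettings(perimeters=1, top_bottom_layers=0)
        a = generate_toolpath(mesh, s, [])
        b = generate_toolpath(mesh, s)
        pa = [p.points for layer in a.layers for p in layer.polylines]
        pb = [p.points for layer in b.layers for p in layer.polylines]
        assert len(pa) == len(pb)
        assert all(np.array_equal(x, y) for x, y in zip(pa, pb))

    def test_overlapping_modifiers_rejected(self):
        mesh = cuboid(30, 10, 1.0)
        mods = [RegionModifier(density=0.2, span=(0.0, 0.6)),
                RegionModifier(density=0.4, span=(0.5, 1.0))]
        with pytest.raises(ConfigError, match="overlap"):
            generate_toolpath(mesh, PrintSettings(), mods)

    def test_thirds_volume_ratio(self):
        # spec example: 20/30/40 % thirds along x give extruded volumes 2:3:4.
        # The cuboid must be large against the line pitch so that integer
        # scan-line counts approximate the continuous ratio.
        L, W = 150.0, 60.0
        mesh = cuboid(L, W, 0.64)
        s = PrintSettings(perimeters=0, top_bottom_layers=0,
                          infill_density=0.4, connect_infill=False)
        mods = [RegionModifier(density=0.2, span=(0.0, 1 / 3)),
                RegionModifier(density=0.3, span=(1 / 3, 2 / 3)),
                RegionModifier(density=0.4, span=(2 / 3, 1.0))]
        tp = generate_toolpath(mesh, s, mods)
        vols = np.zeros(3)
        for layer in tp.layers:
            for p in layer.polylines:
                seg = np.diff(p.points, axis=0)
                lens = np.linalg.norm(seg, axis=1)
                mids = (p.points[:-1] + p.points[1:]) / 2
                idx = np.clip((mids[:, 0] / (L / 3)).astype(int), 0, 2)
                np.add.at(vols, idx, lens)
        ratio = vols / vols[0]
        assert np.allclose(ratio, [1.0, 1.5, 2.0], rtol=0.05)

    def test_fixed_angle_everywhere(self):
        # spec example: fixed 45 deg angle -> all infill segments at 45 +- 0.1 deg
        mesh = cuboid(30, 20, 1.0)
        s = PrintSettings(perimeters=0, top_bottom_layers=0, infill_angle=45.0,
                          connect_infill=False)
        mods = [RegionModifier(density=0.2, angle=45.0, span=(0.0, 0.5)),
                RegionModifier(density=0.4, angle=45.0, span=(0.5, 1.0))]
        tp = generate_toolpath(mesh, s, mods)
        n = 0
        for layer in tp.layers:
            for p in layer.polylines:
                seg = np.diff(p.points, axis=0)
                ang = np.degrees(np.arctan2(seg[:, 1], seg[:, 0])) % 180.0
                assert np.allclose(ang, 45.0, atol=0.1)
                n += len(seg)
        assert n > 0

    def test_bad_span_rejected(self):
        mesh = cuboid(10, 10, 1.0)
        with pytest.raises(ConfigError, match="span"):
            generate_toolpath(mesh, PrintSettings(),
                              [RegionModifier(density=0.2, span=(0.7, 0.3))])


class TestGcodePlanning:
    def test_e_total_is_volume_formula(self):
        mesh = cuboid(20, 15, 2.0)
        settings = PrintSettings(perimeters=2, top_bottom_layers=1)
        toolpath = generate_toolpath(mesh, settings)
        program, estimate = plan_gcode(toolpath)
        h, flow = settings.layer_height, settings.flow
        expected = 0.0
        for layer in toolpath.layers:
            for p in layer.polylines:
                for a, b in zip(p.points[:-1], p.points[1:]):
                    seg = float(np.linalg.norm(b - a))
                    if seg > 0:
                        expected += seg * p.width * h * flow
        assert program.total_extruded_mm3 == expected  # bitwise: same order

    def test_estimate_roles_sum_to_total(self):
        mesh = cuboid(20, 15, 2.0)
        _, est = plan_gcode(generate_toolpath(mesh, PrintSettings()))
        assert est.bioink_volume_ml == pytest.approx(
            est.infill_volume_ml + est.perimeter_volume_ml + est.solid_volume_ml)
        assert est.print_time_s > 0

    def test_solid_layers_have_unit_density(self):
        mesh = cuboid(10, 10, 0.64)  # 4 layers
        s = PrintSettings(perimeters=0, top_bottom_layers=2)
        tp = generate_toolpath(mesh, s)
        for layer in tp.layers:
            roles = {p.role for p in layer.polylines}
            assert roles == {"solid"}

    def test_moves_monotone_e(self):
        mesh = cuboid(10, 10, 1.0)
        program, _ = plan_gcode(generate_toolpath(mesh, PrintSettings()))
        es = [m.e for m in program.moves]
        assert all(b >= a for a, b in zip(es, es[1:]))
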