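"""Sheet geometry, preferred directions and center-surround wiring."""

import numpy as np
import pytest

from gridcan.errors import ConfigurationError
from gridcan.params import load_tables
from gridcan.topology import (
    DIRECTION_VECTORS,
    PhaseMap,
    ScalePreset,
    SheetLayout,
    assign_preferred_directions,
    build_cs_connectivity,
    build_one_to_one,
    connectivity_stats,
    torus_distance,
)

TABLES = load_tables()
E2I = TABLES.synapse("MEC LII Stellate to EC LII AxoAxonic")
I2E = TABLES.synapse("EC LII AxoAxonic to MEC LII Stellate")


def small_preset(**over) -> ScalePreset:
    base = dict(
        name="tiny",
        stellate_sheet=(8, 8),
        in_counts=(16, 16, 16),
        bump_lattice=4.0,
        cs_inner=2.0,
        cs_outer=3.2,
        cs_disc_radius=1.2,
        direction_offset=0.8,
        spacing_cm=20.0,
        orientation_deg=0.0,
        gain={},
        drive={},
    )
    base.update(over)
    return ScalePreset(**base)


class TestDirections:
    @pytest.mark.parametrize("rows, cols", [(2, 2), (40, 40)])
    def test_each_direction_covers_a_quarter(self, rows, cols):
        layout = SheetLayout(rows=rows, cols=cols)
        d = assign_preferred_directions(layout)
        counts = d.counts()
        assert set(counts) == {"N", "E", "S", "W"}
        assert all(v == rows * cols // 4 for v in counts.values())

    def test_vector_sum_over_any_tile_vanishes(self):
        layout = SheetLayout(rows=4, cols=4)
        d = assign_preferred_directions(layout)
        np.testing.assert_allclose(d.vectors.sum(axis=0), [0.0, 0.0], atol=1e-12)
        total = sum(DIRECTION_VECTORS.values())
        np.testing.assert_allclose(total, [0.0, 0.0])

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ConfigurationError, match="even"):
            assign_preferred_directions(SheetLayout(rows=5, cols=4))


class TestOneToOne:
    def test_bijective_index_matched_edges(self):
        a = SheetLayout(rows=40, cols=40)
        g = build_one_to_one(a, SheetLayout(rows=40, cols=40), E2I)
        assert g.n_edges == 1600
        in_deg = np.bincount(g.post, minlength=1600)
        assert (in_deg == 1).all()
        np.testing.assert_array_equal(g.pre, g.post)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="equal sizes"):
            build_one_to_one(SheetLayout(rows=40, cols=40), SheetLayout(rows=40, cols=30), E2I)


class TestCenterSurround:
    def test_intermediate_degrees_match_printed_statistics(self):
        """Mean stellate->IN out-degree 12 (SD <= 2) and IN->stellate
        out-degree 142 (SD <= 66) at the intermediate scale."""
        preset = ScalePreset.from_tables("intermediate", TABLES)
        gl = preset.stellate_layout()
        il = preset.in_layout(0)
        dirs = assign_preferred_directions(gl)
        e2i, i2e = build_cs_connectivity(gl, il, preset, dirs, E2I, I2E)
        s_e2i = connectivity_stats(e2i)
        s_i2e = connectivity_stats(i2e)
        assert round(s_e2i.out_mean) == 12
        assert s_e2i.out_sd <= 2.0
        assert abs(s_i2e.out_mean - 142) <= 5
        assert s_i2e.out_sd <= 66.0

    def test_edges_match_brute_force_torus_enumeration(self):
        preset = small_preset()
        gl = SheetLayout(rows=8, cols=8)
        il = SheetLayout.for_count(16, span=8.0)
        dirs = assign_preferred_directions(gl)
        e2i, i2e = build_cs_connectivity(gl, il, preset, dirs, E2I, I2E)

        sp, ip = gl.positions(), il.positions()
        expected_i2e = set()
        for i in range(il.count):
            for s in range(gl.count):
                d = round(float(torus_distance(ip[i], sp[s], gl)), 9)
                if preset.cs_inner <= d < preset.cs_outer:
                    expected_i2e.add((i, s))
        assert set(zip(i2e.pre.tolist(), i2e.post.tolist())) == expected_i2e

        expected_e2i = set()
        for s in range(gl.count):
            center = sp[s] + preset.direction_offset * dirs.vectors[s]
            for i in range(il.count):
                if round(float(torus_distance(center, ip[i], gl)), 9) <= preset.cs_disc_radius:
                    expected_e2i.add((s, i))
        assert set(zip(e2i.pre.tolist(), e2i.post.tolist())) == expected_e2i

    def test_in_to_stellate_degree_translation_invariant_on_congruent_sheets(self):
        """With the IN sheet congruent to the stellate sheet the annulus
        sees the same relative lattice from every IN: identical out-degree."""
        preset = small_preset()
        gl = SheetLayout(rows=8, cols=8)
        il = SheetLayout(rows=8, cols=8)
        dirs = assign_preferred_directions(gl)
        _, i2e = build_cs_connectivity(gl, il, preset, dirs, E2I, I2E)
        out_deg = np.bincount(i2e.pre, minlength=il.count)
        assert out_deg.min() == out_deg.max()

    def test_degenerate_annulus_rejected(self):
        with pytest.raises(ConfigurationError, match="annulus"):
            small_preset(cs_inner=3.0, cs_outer=3.0)

    def test_stats_equal_raw_recount(self):
        preset = small_preset()
        gl = SheetLayout(rows=8, cols=8)
        il = SheetLayout.for_count(16, span=8.0)
        dirs = assign_preferred_directions(gl)
        _, i2e = build_cs_connectivity(gl, il, preset, dirs, E2I, I2E)
        stats = connectivity_stats(i2e)
        out = np.zeros(i2e.n_pre)
        inc = np.zeros(i2e.n_post)
        for p, q in zip(i2e.pre, i2e.post):
            out[p] += 1
            inc[q] += 1
        assert stats.out_mean == pytest.approx(out.mean())
        assert stats.out_sd == pytest.approx(out.std())
        assert stats.in_mean == pytest.approx(inc.mean())
        assert stats.n_edges == i2e.n_edges


class TestGeometry:
    def test_twisted_wrap_vectors_are_hexagonal(self):
        layout = SheetLayout(rows=20, cols=20)
        e1, e2 = layout.wrap_vectors()
        assert np.linalg.norm(e1) == pytest.approx(np.linalg.norm(e2))
        cos_angle = e1 @ e2 / (np.linalg.norm(e1) * np.linalg.norm(e2))
        assert cos_angle == pytest.approx(0.5)  # 60 degrees

    def test_plain_torus_wrap_vectors_are_square(self):
        layout = SheetLayout(rows=20, cols=20, twist=False)
        e1, e2 = layout.wrap_vectors()
        assert e1 @ e2 == pytest.approx(0.0)

    def test_torus_distance_symmetry_and_wrap(self):
        layout = SheetLayout(rows=10, cols=10)
        p = np.array([0.5, 0.5])
        q = np.array([9.5, 0.5])
        assert torus_distance(p, q, layout) == pytest.approx(torus_distance(q, p, layout))
        assert torus_distance(p, q, layout) < 2.0  # wraps around, not 9 apart

    def test_phase_map_scales_arena_spacing_to_bump_lattice(self):
        preset = ScalePreset.from_tables("desk", TABLES)
        layout = preset.stellate_layout()
        pm = PhaseMap(preset, layout)
        step = pm.to_sheet(np.array([preset.spacing_cm, 0.0])) - pm.to_sheet(np.array([0.0, 0.0]))
        assert np.linalg.norm(step) == pytest.approx(preset.bump_lattice)
        angle = np.degrees(np.arctan2(step[1], step[0]))
        assert angle == pytest.approx(preset.orientation_deg)

    def test_layout_count_must_fit_grid(self):
        with pytest.raises(ConfigurationError):
            SheetLayout(rows=3, cols=3, count=10)
        layout = SheetLayout.for_count(834, span=40.0)
        assert layout.count == 834
        assert layout.rows * layout.cols >= 834
        assert len(layout.positions()) == 834

    def test_unpopulated_coordinate_rejected(self):
        layout = SheetLayout(rows=4, cols=4, count=13)
        with pytest.raises(ConfigurationError):
            layout.index_of(3, 3)
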