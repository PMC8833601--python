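import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tilspatial as ts
from tilspatial.cell_table_io import SampleTable
from tilspatial.phenotyping import PANEL
from tilspatial.spatial_analysis import (
    MEASURE_A,
    MEASURE_B,
    EmptyReferenceError,
    ZoneScheme,
    bin_zones,
    convex_hull_area,
    nearest_reference_distance,
    zone_densities,
)
from tilspatial.synthetic_data import GradientSpec, SyntheticSlideConfig, generate_slide

from conftest import brute_force_distances, gift_wrap_hull_area_um2, make_table


def random_table(rng, n_ana=200, n_ref=50):
    rows = []
    for i in range(n_ref):
        rows.append((f"r{i}", rng.uniform(0, 500), rng.uniform(0, 500), "LIVER", "NONE", False, False))
    for i in range(n_ana):
        rows.append((f"a{i}", rng.uniform(0, 2000), rng.uniform(0, 1400), "TUMOR", "STROMAL", i % 2 == 0, False))
    return make_table(rows)


class TestNearestReferenceDistance:
    def test_three_four_five_triangle(self):
        t = make_table(
            [
                ("ref", 0.0, 0.0, "LIVER", "NONE", False, False),
                ("qry", 300.0, 400.0, "TUMOR", "STROMAL", False, False),
            ]
        )
        d = nearest_reference_distance(t, MEASURE_A)
        assert d.iloc[0] == pytest.approx(500.0)

    def test_coincident_cells_give_zero(self):
        t = make_table(
            [
                ("ref", 10.0, 10.0, "LIVER", "NONE", False, False),
                ("qry", 10.0, 10.0, "TUMOR", "STROMAL", False, False),
            ]
        )
        assert nearest_reference_distance(t, MEASURE_A).iloc[0] == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            t = random_table(rng)
            d = nearest_reference_distance(t, MEASURE_A)
            df = t.cells
            ref = df[df.tissue == "LIVER"][["x", "y"]].to_numpy()
            qry = df[df.tissue == "TUMOR"][["x", "y"]].to_numpy()
            expect = brute_force_distances(ref, qry)
            np.testing.assert_allclose(np.sort(d.to_numpy()), np.sort(expect), rtol=0, atol=0)

    def test_excluded_cells_ignored_both_sides(self):
        t = make_table(
            [
                ("r1", 0.0, 0.0, "EXCLUDED", "NONE", False, False),
                ("r2", 100.0, 0.0, "LIVER", "NONE", False, False),
                ("q", 0.0, 0.0, "TUMOR", "STROMAL", False, False),
            ]
        )
        # nearest non-excluded reference is 100 away, not the coincident excluded cell
        assert nearest_reference_distance(t, MEASURE_A).iloc[0] == pytest.approx(100.0)

    def test_empty_reference_raises_with_sample_and_scheme(self):
        t = make_table([("q", 0.0, 0.0, "TUMOR", "STROMAL", False, False)])
        with pytest.raises(EmptyReferenceError, match="toy.*Measure A"):
            nearest_reference_distance(t, MEASURE_A)

    def test_measure_b_distance_never_exceeds_measure_a(self, small_dhgp_slide):
        table, _ = small_dhgp_slide
        da = nearest_reference_distance(table, MEASURE_A)
        db = nearest_reference_distance(table, MEASURE_B)
        common = db.index  # tumor cells
        assert (db.loc[common] <= da.loc[common] + 1e-9).all()


class TestZoneBinning:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0), (50.0, 0), (100.0, 1), (199.999, 1), (200.0, 2), (400.0, 3), (599.9, 3)],
    )
    def test_half_open_convention(self, d, expected):
        z = bin_zones(pd.Series([d]), ZoneScheme())
        assert z.iloc[0] == expected

    def test_at_and_beyond_last_edge_unzoned(self):
        z = bin_zones(pd.Series([600.0, 1e4]), ZoneScheme())
        assert z.isna().all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bin_zones(pd.Series([-1.0]), ZoneScheme())

    def test_zone_scheme_validation(self):
        with pytest.raises(ValueError):
            ZoneScheme((0.0, 100.0, 100.0))
        with pytest.raises(ValueError):
            ZoneScheme((50.0, 100.0))


class TestConvexHullArea:
    def test_unit_square_mm(self):
        pts = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        assert convex_hull_area(np.array(pts)) == pytest.approx(1.0)

    def test_collinear_and_tiny_inputs_are_na(self):
        assert np.isnan(convex_hull_area(np.array([(0, 0), (1, 1), (2, 2)])))
        assert np.isnan(convex_hull_area(np.array([(0, 0), (5, 5)])))

    def test_non_finite_coordinate_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_area(np.array([(0.0, np.nan), (1, 0), (0, 1)]))

    def test_matches_gift_wrapping_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.uniform(0, 1500, size=(30, 2))
            got = convex_hull_area(pts)
            want = gift_wrap_hull_area_um2(pts) / 1e6
            assert got == pytest.approx(want, rel=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        pts=arrays(float, (12, 2), elements=st.floats(0, 2000)),
        extra=arrays(float, (2,), elements=st.floats(0, 2000)),
    )
    def test_adding_a_point_never_shrinks_the_hull(self, pts, extra):
        a0 = convex_hull_area(pts)
        a1 = convex_hull_area(np.vstack([pts, extra]))
        if not np.isnan(a0) and not np.isnan(a1):
            assert a1 >= a0 - 1e-12


class TestZoneDensities:
    def _one_zone_table(self):
        # four corner cells spanning exactly 1 mm², 2 of them CD8+,
        # all within the 0-100 µm zone of a reference line at x <= 0
        rows = [("ref%d" % i, -1.0, y, "LIVER", "NONE", False, False) for i, y in enumerate((0, 500, 1000))]
        # four corner cells spanning a 98 µm x 1000 µm rectangle, all at
        # measured distance < 100 µm from the reference line at x = -1
        rows += [
            ("c0", 0.0, 0.0, "TUMOR", "STROMAL", False, True),
            ("c1", 0.0, 1000.0, "TUMOR", "STROMAL", False, True),
            ("c2", 98.0, 0.0, "TUMOR", "STROMAL", False, False),
            ("c3", 98.0, 1000.0, "TUMOR", "STROMAL", False, False),
        ]
        return make_table(rows)

    def test_count_over_hull_arithmetic(self):
        t = self._one_zone_table()
        a = ts.classify_cells(t)
        z = zone_densities(t, a, MEASURE_A)
        cd8 = z[(z.subset == "CD8_total") & (z.zone == 0)].iloc[0]
        assert cd8["count"] == 2
        assert cd8["hull_area_mm2"] == pytest.approx(0.098, rel=1e-6)
        assert cd8["density_per_mm2"] == pytest.approx(2 / 0.098, rel=1e-6)

    def test_zero_count_subset_gets_zero_density_from_shared_hull(self):
        t = self._one_zone_table()
        a = ts.classify_cells(t)
        z = zone_densities(t, a, MEASURE_A)
        cd4 = z[(z.subset == "CD4_total") & (z.zone == 0)].iloc[0]
        assert cd4["count"] == 0
        assert cd4["density_per_mm2"] == 0.0

    def test_empty_zone_has_na_area_and_density(self):
        t = self._one_zone_table()
        a = ts.classify_cells(t)
        z = zone_densities(t, a, MEASURE_A)
        far = z[(z.subset == "CD8_total") & (z.zone == 3)].iloc[0]
        assert far["count"] == 0
        assert np.isnan(far["hull_area_mm2"]) and np.isnan(far["density_per_mm2"])

    def test_conservation_of_in_band_counts(self, small_dhgp_slide):
        table, _ = small_dhgp_slide
        a = ts.classify_cells(table)
        for scheme in (MEASURE_A, MEASURE_B):
            z = zone_densities(table, a, scheme)
            d = nearest_reference_distance(table, scheme)
            zb = bin_zones(d, ZoneScheme())
            inband = zb.dropna().index
            for subset in a.subsets:
                total = int(a.membership.loc[inband, subset].sum())
                assert z[z.subset == subset]["count"].sum() == total

    def test_per_subset_hull_scope_never_larger_than_shared(self, small_dhgp_slide):
        table, _ = small_dhgp_slide
        a = ts.classify_cells(table)
        shared = zone_densities(table, a, MEASURE_A, hull_scope="all")
        per = zone_densities(table, a, MEASURE_A, hull_scope="subset")
        m = shared.merge(per, on=["subset", "zone"], suffixes=("_all", "_sub"))
        ok = m.dropna(subset=["hull_area_mm2_all", "hull_area_mm2_sub"])
        assert (ok["hull_area_mm2_sub"] <= ok["hull_area_mm2_all"] + 1e-12).all()

    def test_gradient_slides_show_monotone_zone_decay(self):
        # exponential decay from the interface should produce decreasing
        # zone densities, here checked on 10 seeded slides
        for seed in range(10):
            cfg = SyntheticSlideConfig(
                hgp="ndHGP",
                reactive_stroma_fraction=0.0,
                structural_intensity=1500,
                gradients={"CD8": GradientSpec(lambda0=500, tau=150, base=0)},
                seed=seed,
            )
            table, _ = generate_slide(cfg)
            a = ts.classify_cells(table)
            z = zone_densities(table, a, MEASURE_A)
            dens = z[z.subset == "CD8_total"].sort_values("zone")["density_per_mm2"]
            assert dens.is_monotonic_decreasing
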