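"""Session reduction: averaging, background subtraction, mass conversion, TWA."""

import io
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from nanorisk import (
    MaterialSpec,
    SizeBinGrid,
    bin_midpoints,
    comparison_table,
    mass_concentration_monodisperse,
    mean_concentration,
    net_emission,
    number_to_mass,
    read_session_csv,
    reduce_sessions,
    twa_8h,
    write_session_csv,
)
from nanorisk.errors import (
    EmptyInputError,
    IncompatibleGridsError,
    InvalidDurationError,
    InvalidGridError,
    InvalidInputError,
)

from conftest import make_series


class TestBinMidpoints:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([10, 40], [20.0]),
            ([100, 400, 1600], [200.0, 800.0]),
        ],
    )
    def test_geometric_mean_of_edges(self, edges, expected):
        np.testing.assert_allclose(bin_midpoints(edges), expected)

    @pytest.mark.parametrize("edges", [[10, 10], [40, 10], [-5, 10], [0, 10], [10]])
    def test_degenerate_grids_rejected(self, edges):
        with pytest.raises(InvalidGridError):
            bin_midpoints(edges)

    def test_arithmetic_rule_option(self):
        np.testing.assert_allclose(
            bin_midpoints([10, 40], rule="arithmetic"), [25.0])

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=10, unique=True))
    def test_midpoints_strictly_inside_bins(self, edges):
        edges = sorted(edges)
        assume(all(hi / lo > 1.001 for lo, hi in zip(edges[:-1], edges[1:])))
        mids = bin_midpoints(edges)
        for lo, hi, m in zip(edges[:-1], edges[1:], mids):
            assert lo < m < hi


class TestGrids:
    def test_default_profiles_span_instrument_ranges(self):
        nano = SizeBinGrid.nanoscan()
        assert nano.bin_edges[0] == pytest.approx(10.0)
        assert nano.bin_edges[-1] == pytest.approx(420.0)
        ops = SizeBinGrid.ops()
        assert ops.bin_edges[0] == pytest.approx(300.0)
        assert ops.bin_edges[-1] == pytest.approx(10_000.0)

    def test_monodisperse_grid_midpoint_is_the_diameter(self):
        grid = SizeBinGrid.monodisperse(30.0)
        assert grid.bin_midpoints[0] == pytest.approx(30.0)


class TestMeanConcentration:
    def test_constant_series(self):
        per_bin, total = mean_concentration(make_series(np.full((4, 3), 500.0)))
        np.testing.assert_allclose(per_bin, [500, 500, 500])
        assert total == pytest.approx(1500.0)

    def test_single_bin_mean(self):
        per_bin, total = mean_concentration(make_series([[100.0], [300.0]]))
        assert per_bin[0] == total == pytest.approx(200.0)

    def test_two_bins_by_hand(self):
        per_bin, total = mean_concentration(make_series([[10, 30], [30, 30]]))
        # rows [10,30] and [30,30]: per-bin means [20, 30]
        np.testing.assert_allclose(per_bin, [20, 30])
        assert total == pytest.approx(50.0)

    def test_empty_session_rejected(self):
        series = make_series(np.zeros((1, 2)))
        series.values = np.zeros((0, 2))
        series.timestamps = series.timestamps[:0]
        with pytest.raises(EmptyInputError):
            mean_concentration(series)


class TestNetEmission:
    def test_identical_sessions_give_zero_everywhere(self):
        x = np.array([12.0, 7.0, 0.0])
        net = net_emission(x, x)
        np.testing.assert_array_equal(net.per_bin, 0.0)
        assert not net.clamped.any()

    def test_clamping_floors_negatives_and_flags(self):
        net = net_emission(np.array([100.0, 50.0]), np.array([40.0, 60.0]))
        np.testing.assert_allclose(net.per_bin, [60.0, 0.0])
        np.testing.assert_array_equal(net.clamped, [False, True])
        # raw difference retrievable
        np.testing.assert_allclose(net.raw_difference, [60.0, -10.0])
        assert net.total == pytest.approx(60.0)

    def test_zero_background_passthrough(self):
        net = net_emission(np.array([1.21e5]), np.array([0.0]))
        assert net.total == pytest.approx(1.21e5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(IncompatibleGridsError):
            net_emission(np.ones(3), np.ones(2))
        with pytest.raises(IncompatibleGridsError):
            net_emission(np.ones(13), np.ones(13),
                         emission_grid=SizeBinGrid.nanoscan(),
                         background_grid=SizeBinGrid("custom",
                                                     np.geomspace(10, 400, 14)))


class TestNumberToMass:
    def test_gold_session_total(self):
        # monodisperse 30 nm gold at the measured session total
        assert number_to_mass([7.56e3], [30.0], 19.3) == pytest.approx(
            2.06, rel=0.01)

    def test_silver_session_total(self):
        assert number_to_mass([1.21e5], [20.0], 10.49) == pytest.approx(
            5.32, rel=0.01)

    def test_empty_aerosol_is_zero(self):
        assert number_to_mass([0.0, 0.0], [20.0, 40.0], 10.49) == 0.0

    def test_additive_over_bins(self):
        single = number_to_mass([7.56e3], [30.0], 19.3) + \
            number_to_mass([2e3], [100.0], 19.3)
        combined = number_to_mass([7.56e3, 2e3], [30.0, 100.0], 19.3)
        assert combined == pytest.approx(single, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            number_to_mass([-1.0], [30.0], 19.3)

    @given(
        cn=st.lists(st.floats(0.0, 1e6), min_size=1, max_size=5),
        density=st.floats(0.5, 25.0),
        alpha=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_brute_force_oracle_and_linearity(self, cn, density, alpha):
        """Per-particle brute force with independent unit bookkeeping.

        Each particle of diameter d nm has volume (pi/6) d^3 nm^3 =
        (pi/6) d^3 * 1e-21 cm^3 and mass volume * rho g; per cm^3 of air
        that is CN * mass g/cm^3 = CN * mass * 1e6 * 1e6 ug/m^3.
        """
        d = np.geomspace(15.0, 400.0, len(cn))
        brute = 0.0
        for cni, di in zip(cn, d):
            vol_cm3 = (math.pi / 6.0) * di**3 * 1e-21
            mass_g = vol_cm3 * density
            brute += cni * mass_g * 1e6 * 1e6  # g/cm3-air -> ug/m3-air
        result = number_to_mass(cn, d, density)
        assert result == pytest.approx(brute, rel=1e-12, abs=1e-300)
        # homogeneity of degree 1 in CN and in rho
        assert number_to_mass(alpha * np.asarray(cn), d, density) == pytest.approx(
            alpha * result, rel=1e-9, abs=1e-280)
        assert number_to_mass(cn, d, alpha * density) == pytest.approx(
            alpha * result, rel=1e-9, abs=1e-280)


class TestTwa:
    @pytest.mark.parametrize(
        "mass, minutes, expected",
        [(5.32, 360, 3.99), (0.48, 360, 0.36), (7.0, 480, 7.0)],
    )
    def test_shift_scaling(self, mass, minutes, expected):
        assert twa_8h(mass, minutes) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("minutes", [0, -5, 481, 1e6])
    def test_invalid_durations_rejected(self, minutes):
        with pytest.raises(InvalidDurationError):
            twa_8h(1.0, minutes)

    @given(c=st.floats(0.0, 1e3), m1=st.floats(1.0, 479.0))
    @settings(max_examples=30)
    def test_monotone_in_both_arguments(self, c, m1):
        assert twa_8h(c, m1) <= twa_8h(c, m1 + 1.0)
        assert twa_8h(c, m1) <= twa_8h(c + 1.0, m1)
        assert twa_8h(c, 480.0) == pytest.approx(c)


class TestCsvRoundtrip:
    def test_roundtrip_preserves_values_and_profile(self):
        series = make_series(np.arange(26, dtype=float).reshape(2, 13),
                             grid=SizeBinGrid.nanoscan(), kind="background")
        buf = io.StringIO()
        write_session_csv(series, buf)
        back = read_session_csv(io.StringIO(buf.getvalue()))
        assert back.grid.instrument_profile == "nanoscan"
        assert back.session_kind == "background"
        np.testing.assert_allclose(back.values, series.values)
        np.testing.assert_allclose(back.grid.bin_edges, series.grid.bin_edges)

    def test_empty_file_rejected(self):
        with pytest.raises(EmptyInputError):
            read_session_csv(io.StringIO("# profile: nanoscan\ntimestamp,bin_10_40nm\n"))


class TestReductionReport:
    def test_reduction_and_verdicts(self, silver):
        bg = make_series(np.full((5, 1), 1e3), grid=SizeBinGrid.monodisperse(20.0))
        em = make_series(np.full((5, 1), 1.22e5), grid=SizeBinGrid.monodisperse(20.0))
        report = reduce_sessions(bg, em, silver, 360.0)
        assert report.total_number == pytest.approx(1.21e5)
        assert report.mass_conc == pytest.approx(5.32, rel=0.01)
        assert report.twa == pytest.approx(3.99, rel=0.01)
        assert report.exceeds_oel is True
        table = comparison_table([report])
        assert table.loc[0, "oel_verdict"] == "exceed"

    def test_monodisperse_shortcut_matches_reference_diameter(self, gold):
        assert mass_concentration_monodisperse(7.56e3, gold) == pytest.approx(
            2.06, rel=0.01)


class TestMaterialDefaults:
    def test_density_and_benchmark_defaults(self):
        from nanorisk import MATERIALS

        assert MATERIALS["silver"].density == 10.49
        assert MATERIALS["gold"].density == 19.3
        assert MATERIALS["mwcnt"].density == 1.5
        assert MATERIALS["graphene"].density == 1.0
        assert MATERIALS["silver"].oel_mass == 0.19
        assert MATERIALS["mwcnt"].oel_mass == 1.0
        assert MATERIALS["gold"].nrv_number == 20_000.0

    def test_invalid_material_rejected(self):
        with pytest.raises(InvalidInputError):
            MaterialSpec("x", density=-1.0, reference_diameter=20.0)
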