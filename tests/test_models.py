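"""Unit and property tests for the two analytical cochlear models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cochleaplan import (
    CochlearGeometry,
    ModelParams,
    eca_btl,
    eca_cdl,
    escude_cdl,
    generate_pbtl_table,
    invert_eca,
    invert_escude,
    pbtl,
    write_pbtl_table,
)

# hand-evaluated expected values, frozen before implementation
ESCUDE_A9_TH360 = 2.62 * 8.0 * math.log(1 + 360 / 235)  # 19.471334683774828
BTL_92_68 = 1.18 * 8.5 + 2.69 * 6.1 - math.sqrt(0.72 * 8.5 * 6.1)  # 20.329008...
PBTL_360 = 8.3e-8 * 360**3 - 2.4e-4 * 360**2 + 0.34 * 360 + 3.7  # 98.868448


class TestEscude:
    def test_zero_angle_gives_zero_length(self):
        assert escude_cdl(CochlearGeometry(9.0, 6.8), 0.0) == 0.0

    def test_hand_evaluated_value(self):
        got = escude_cdl(CochlearGeometry(9.0, 6.8), 360.0)
        assert got == pytest.approx(ESCUDE_A9_TH360, abs=1e-12)

    def test_monotone_in_angle_and_diameter(self):
        g = CochlearGeometry(9.0, 6.8)
        assert escude_cdl(g, 720.0) > escude_cdl(g, 360.0)
        assert escude_cdl(CochlearGeometry(9.4, 6.8), 360.0) > escude_cdl(g, 360.0)

    def test_nonpositive_effective_diameter_names_inputs(self):
        with pytest.raises(ValueError, match="A=0.9.*offset 0.5"):
            escude_cdl(CochlearGeometry(0.9, 0.5), 100.0)

    @pytest.mark.parametrize("theta", [90.0, 360.0, 630.0])
    def test_closed_form_inversion_roundtrip(self, theta):
        g = CochlearGeometry(9.0, 6.8)
        assert invert_escude(g, escude_cdl(g, theta)) == pytest.approx(theta, abs=1e-9)

    def test_inversion_of_known_length(self):
        g = CochlearGeometry(9.0, 6.8)
        assert invert_escude(g, ESCUDE_A9_TH360) == pytest.approx(360.0, abs=1e-9)
        assert invert_escude(g, 0.0) == 0.0

    def test_inversion_beyond_900_degrees_is_out_of_range(self):
        g = CochlearGeometry(7.2, 6.0)
        with pytest.raises(ValueError, match="exceeds the modelled duct"):
            invert_escude(g, 40.0)

    def test_smaller_offset_gives_longer_duct(self):
        # the 0.35-mm sensitivity variant lengthens the modelled path
        g = CochlearGeometry(9.0, 6.8)
        v035 = escude_cdl(g, 400.0, ModelParams(escude_offset=0.35))
        v050 = escude_cdl(g, 400.0, ModelParams(escude_offset=0.5))
        assert v035 > v050


class TestEcaBtl:
    def test_vanishes_when_offsets_consume_both_axes(self):
        assert eca_btl(CochlearGeometry(0.7000001, 0.7)) == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluated_value(self, geom):
        assert eca_btl(geom) == pytest.approx(BTL_92_68, abs=1e-12)

    def test_increasing_in_A_over_parameter_box(self):
        for a in np.linspace(7, 10.8, 8):
            for b in np.linspace(5, min(a - 0.3, 8), 6):
                g1 = CochlearGeometry(a, b)
                g2 = CochlearGeometry(a + 0.2, b)
                assert eca_btl(g2) > eca_btl(g1)
                assert eca_btl(g1) > 0

    def test_requires_B(self):
        with pytest.raises(ValueError, match="width B"):
            eca_btl(CochlearGeometry(9.2))


class TestPbtl:
    def test_round_window_value_is_constant_term(self):
        assert pbtl(0.0) == 3.7

    def test_hand_evaluated_value(self):
        assert pbtl(360.0) == pytest.approx(PBTL_360, rel=1e-12)

    def test_strictly_increasing_on_full_grid(self):
        vals = pbtl(np.arange(0, 901, dtype=float))
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("theta", [-1.0, 900.5, 1200.0])
    def test_out_of_range_angle_rejected(self, theta):
        with pytest.raises(ValueError, match="modelled range"):
            pbtl(theta)


class TestEcaCdl:
    def test_composition_of_oracles(self, geom):
        assert eca_cdl(geom, 360.0) == pytest.approx(PBTL_360 / 100 * BTL_92_68, rel=1e-12)

    def test_zero_btl_gives_zero_length(self):
        g = CochlearGeometry(0.7000001, 0.7)
        assert eca_cdl(g, 450.0) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_angle(self, geom):
        th = np.linspace(0, 900, 91)
        assert np.all(np.diff(eca_cdl(geom, th)) > 0)

    @pytest.mark.parametrize("theta", [45.0, 360.0, 700.0])
    def test_inversion_roundtrip(self, geom, theta):
        assert invert_eca(geom, eca_cdl(geom, theta)) == pytest.approx(theta, abs=1e-6)

    def test_inversion_below_round_window_length_raises(self, geom):
        # p_BTL(0) = 3.7 % of BTL, so zero length is not representable
        with pytest.raises(ValueError, match="minimum representable"):
            invert_eca(geom, 0.0)
        lo = eca_cdl(geom, 0.0)
        assert invert_eca(geom, lo) == pytest.approx(0.0, abs=1e-6)

    def test_inversion_beyond_apex_raises(self, geom):
        with pytest.raises(ValueError, match="exceeds the modelled duct"):
            invert_eca(geom, eca_cdl(geom, 900.0) + 0.01)

    def test_inversion_agrees_with_dense_table_lookup(self, geom):
        # independent oracle: linear interpolation of the 1-degree table
        table = generate_pbtl_table()
        thetas = np.concatenate([[0.0], table["theta_deg"].to_numpy()])
        pcts = np.concatenate([[3.7], table["pbtl_percent"].to_numpy()])
        btl = eca_btl(geom)
        for theta in range(10, 900, 10):
            length = eca_cdl(geom, float(theta))
            lookup = np.interp(length / btl * 100.0, pcts, thetas)
            assert invert_eca(geom, length) == pytest.approx(lookup, abs=0.01)


class TestRoundtripGrid:
    @pytest.mark.parametrize("A", [7.5, 9.0, 10.5])
    def test_both_models_roundtrip_whole_grid(self, A):
        g = CochlearGeometry(A, A * 0.72)
        for theta in range(10, 900, 10):
            L = escude_cdl(g, float(theta))
            if L <= escude_cdl(g, 900.0):
                assert abs(invert_escude(g, L) - theta) < 1e-9
            assert abs(invert_eca(g, eca_cdl(g, float(theta))) - theta) < 1e-6


class TestPbtlTable:
    def test_shape_and_first_row(self):
        t = generate_pbtl_table()
        assert len(t) == 900
        assert t["theta_deg"].iloc[0] == 1.0
        assert t["theta_deg"].iloc[-1] == 900.0
        assert t["pbtl_percent"].iloc[0] == pbtl(1.0)

    def test_strictly_increasing_down_the_rows(self):
        t = generate_pbtl_table()
        assert t["pbtl_percent"].is_monotonic_increasing
        assert np.all(np.diff(t["pbtl_percent"]) > 0)

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "pbtl.csv"
        write_pbtl_table(path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["theta_deg", "pbtl_percent"]
        assert len(back) == 900
        np.testing.assert_allclose(back["pbtl_percent"], generate_pbtl_table()["pbtl_percent"])


class TestGeometry:
    def test_positive_axes_required(self):
        with pytest.raises(ValueError):
            CochlearGeometry(-1.0, 5.0)
        with pytest.raises(ValueError):
            CochlearGeometry(9.0, 0.0)

    def test_width_exceeding_diameter_warns_by_default(self):
        with pytest.warns(UserWarning, match="A > width B"):
            CochlearGeometry(6.0, 6.5)

    def test_width_exceeding_diameter_raises_in_strict_mode(self):
        with pytest.raises(ValueError, match="A > width B"):
            CochlearGeometry(6.0, 6.5, strict=True)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    A=st.floats(7.0, 11.0),
    B_frac=st.floats(0.6, 0.85),
    theta=st.floats(1.0, 899.0),
)
def test_roundtrip_property(A, B_frac, theta):
    """Inversion undoes the forward map for any geometry in the clinical box."""
    g = CochlearGeometry(A, A * B_frac)
    L = escude_cdl(g, theta)
    if L <= escude_cdl(g, 900.0):
        assert abs(invert_escude(g, L) - theta) < 1e-9
    assert abs(invert_eca(g, eca_cdl(g, theta)) - theta) < 1e-6
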