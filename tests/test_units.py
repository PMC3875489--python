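import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrostoma.errors import DomainError, EmptyInputError, FormatError, UnitError
from hydrostoma.units import (
    average_by_leaf_hour,
    convert_units,
    read_gas_exchange_table,
    relative_humidity_from_D,
    saturation_vapor_pressure,
    scaled_vpd,
)

COND_UNITS = ["mol m-2 s-1", "mmol m-2 s-1", "m s-1", "s cm-1", "m2 s mol-1"]


class TestConvertUnits:
    @pytest.mark.parametrize(
        "value,src,dst,expected",
        [
            (250.0, "mmol m-2 s-1", "mol m-2 s-1", 0.25),
            (3.5, "hPa", "kPa", 0.35),
            (7.0, "mbar", "kPa", 0.70),
            # ideal gas: 0.01 m/s at 25 C, 101.325 kPa
            (0.01, "m s-1", "mol m-2 s-1", 0.01 * 101325 / (8.314 * 298.15)),
            (2.5, "m2 s mol-1", "mol m-2 s-1", 0.4),
        ],
    )
    def test_known_conversions(self, value, src, dst, expected):
        assert convert_units(value, src, dst, T=25.0, P=101.325) == pytest.approx(
            expected, rel=1e-6
        )

    @given(
        value=st.floats(0.01, 100.0),
        src=st.sampled_from(COND_UNITS),
        dst=st.sampled_from(COND_UNITS),
        T=st.floats(0.0, 45.0),
        P=st.floats(60.0, 105.0),
    )
    def test_involution(self, value, src, dst, T, P):
        back = convert_units(convert_units(value, src, dst, T, P), dst, src, T, P)
        assert back == pytest.approx(value, rel=1e-10)

    def test_pressure_involution(self):
        for src in ("kPa", "hPa", "mbar"):
            for dst in ("kPa", "hPa", "mbar"):
                assert convert_units(convert_units(2.2, src, dst), dst, src) == pytest.approx(
                    2.2, rel=1e-12
                )

    def test_unsupported_pair(self):
        with pytest.raises(UnitError):
            convert_units(1.0, "kPa", "mol m-2 s-1")


class TestScaledVpdAndHumidity:
    def test_favorable_corner_value(self):
        assert scaled_vpd(0.3546, 101.325) == pytest.approx(0.0035, abs=1e-6)

    def test_zero_vpd(self):
        assert scaled_vpd(0.0, 95.0) == 0.0

    def test_division(self):
        assert scaled_vpd(5.06625, 101.325) == pytest.approx(0.05, abs=1e-12)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(DomainError):
            scaled_vpd(1.0, 0.0)

    def test_near_saturated_air_is_91_percent(self):
        # D = 0.0035 at 30 C, sea level, Tetens saturation curve
        rh = relative_humidity_from_D(0.0035, T=30.0, P=101.325)
        assert rh == pytest.approx(0.916, abs=0.005)
        assert abs(rh - 0.91) < 0.01

    def test_zero_deficit_is_saturation(self):
        assert relative_humidity_from_D(0.0, T=20.0) == 1.0

    def test_excess_demand_clamped_with_warning(self):
        # Tetens oracle: 1 - 0.05*101.325/e_sat(30) = -0.19
        expected = 1 - 0.05 * 101.325 / saturation_vapor_pressure(30.0)
        assert expected == pytest.approx(-0.194, abs=0.01)
        with pytest.warns(UserWarning):
            assert relative_humidity_from_D(0.05, T=30.0, P=101.325) == 0.0


def _write_csv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


LICOR_COLS = ["Date", "HHMMSS", "Leaf", "Cond", "Photo", "Ci", "VpdL", "Press", "Tleaf"]


def _licor_row(gs=0.2, an=8.0, vpd=1.5, press=95.0, hour="10:30:00", leaf="A", date="2005-07-01"):
    return [date, hour, leaf, gs, an, 280.0, vpd, press, 28.0]


class TestReadGasExchangeTable:
    def test_identity_passthrough(self, tmp_path):
        f = tmp_path / "obs1.csv"
        _write_csv(f, [_licor_row(gs=g) for g in (0.2, 0.3, 0.4)], LICOR_COLS)
        table = read_gas_exchange_table(f)
        assert len(table) == 3
        assert sorted(table.data["gs_mol"]) == pytest.approx([0.2, 0.3, 0.4])
        assert table.days == ["2005-07-01"]

    def test_invalid_rows_dropped(self, tmp_path):
        f = tmp_path / "obs1.csv"
        _write_csv(f, [_licor_row(), _licor_row(vpd=-0.1), _licor_row(gs=-0.5)], LICOR_COLS)
        table = read_gas_exchange_table(f)
        assert len(table) == 1

    def test_resistance_dialect(self, tmp_path):
        f = tmp_path / "obs1.csv"
        cols = ["Date", "HHMMSS", "Leaf", "Rs", "Photo", "Ci", "VpdL", "Press", "Tleaf"]
        _write_csv(f, [["2005-07-01", "11:00:00", "A", 2.5, 8.0, 280.0, 1.5, 95.0, 28.0]], cols)
        table = read_gas_exchange_table(
            f, dialect={"gs": "Rs", "gs_unit": "m2 s mol-1"}
        )
        assert table.data["gs_mol"].iloc[0] == pytest.approx(0.4)

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "obs1.csv"
        _write_csv(f, [["2005-07-01", "11:00:00", "A", 8.0]], ["Date", "HHMMSS", "Leaf", "Photo"])
        with pytest.raises(FormatError, match="Cond"):
            read_gas_exchange_table(f)

    def test_empty_after_filter(self, tmp_path):
        f = tmp_path / "obs1.csv"
        _write_csv(f, [_licor_row(vpd=-1.0)], LICOR_COLS)
        with pytest.raises(EmptyInputError):
            read_gas_exchange_table(f)


class TestLeafHourAveraging:
    def _table(self, tmp_path, rows):
        f = tmp_path / "obs1.csv"
        _write_csv(f, rows, LICOR_COLS)
        return read_gas_exchange_table(f)

    def test_replicates_averaged(self, tmp_path):
        t = self._table(
            tmp_path, [_licor_row(gs=0.2, hour="10:05:00"), _licor_row(gs=0.4, hour="10:55:00")]
        )
        out = average_by_leaf_hour(t)
        assert len(out) == 1
        assert out.data["gs_mol"].iloc[0] == pytest.approx(0.3)

    def test_idempotent(self, tmp_path):
        t = self._table(tmp_path, [_licor_row(leaf=l) for l in "ABC"])
        once = average_by_leaf_hour(t)
        twice = average_by_leaf_hour(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_leaves_kept_separate(self, tmp_path):
        t = self._table(tmp_path, [_licor_row(leaf=l) for l in "ABC"])
        assert len(average_by_leaf_hour(t)) == 3

    def test_balanced_groups_preserve_global_mean(self, tmp_path):
        rows = [
            _licor_row(gs=g, leaf=l, hour=h)
            for l in "AB"
            for h, gs_pair in (("09:00:00", (0.1, 0.3)), ("10:00:00", (0.2, 0.6)))
            for g in gs_pair
        ]
        t = self._table(tmp_path, rows)
        out = average_by_leaf_hour(t)
        assert out.data["gs_mol"].mean() == pytest.approx(t.data["gs_mol"].mean())
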