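"""Equivalent-temperature solving: oracle agreement, signs, trends."""

import numpy as np
import pytest

from sowtherm import (
    IndexId,
    equivalence_table,
    equivalent_temperature_change,
    evaluate,
    solve_matched_temperature,
)
from sowtherm.equivalent import DEFAULT_TEMPS


def grid_scan_oracle(id, T1, RH1, RH2, v=1.0, step=0.001):
    """Brute-force matched temperature: argmin |index(T, RH2) - target|."""
    target = evaluate(id, T1, RH1, v)
    hi = min(T1 + 15.0, 42.0) if id is IndexId.ETIS else T1 + 15.0
    Ts = np.arange(T1 - 15.0, hi + step / 2, step)
    vals = np.array([evaluate(id, T, RH2, v) for T in Ts])
    return Ts[np.argmin(np.abs(vals - target))]


class TestSolver:
    @pytest.mark.parametrize("id", [IndexId.THI2, IndexId.ETIS, IndexId.H])
    def test_identity_when_humidity_unchanged(self, id):
        assert solve_matched_temperature(id, 25.0, 50.0, 50.0) == 25.0

    def test_thi7_matches_closed_form_inversion(self):
        # THI7(T, 0) = 0.45 T + 7.975, so T2 = (THI7(22,70) - 7.975)/0.45
        T2 = solve_matched_temperature(IndexId.THI7, 22.0, 70.0, 0.0)
        assert T2 == pytest.approx((20.7625 - 7.975) / 0.45, abs=1e-9)
        assert T2 == pytest.approx(28.4167, abs=1e-3)

    def test_enthalpy_example(self):
        T2 = solve_matched_temperature(IndexId.H, 25.0, 50.0, 60.0)
        assert T2 == pytest.approx(23.20, abs=0.01)

    def test_residual_below_tolerance(self):
        for id in IndexId:
            T2 = solve_matched_temperature(id, 30.0, 50.0, 60.0)
            assert abs(
                evaluate(id, T2, 60.0, 1.0) - evaluate(id, 30.0, 50.0, 1.0)
            ) < 1e-8

    @pytest.mark.parametrize("id", list(IndexId))
    @pytest.mark.parametrize("T1", DEFAULT_TEMPS)
    def test_agrees_with_grid_scan_oracle(self, id, T1):
        T2 = solve_matched_temperature(id, T1, 50.0, 60.0)
        assert abs(T2 - grid_scan_oracle(id, T1, 50.0, 60.0)) <= 0.002

    def test_unreachable_target_raises(self):
        # drying the air to RH 1 % cannot be compensated within +/-15 degC
        # for enthalpy: the humidity term carries too much of the value
        with pytest.raises(ValueError, match="no compensating temperature"):
            solve_matched_temperature(IndexId.H, 25.0, 50.0, 1.0)


class TestEquivalentChange:
    def test_enthalpy_bounds(self):
        # a 10-point RH rise acts like > 1.5 degC of warming at 25 degC
        # and > 1.73 degC at 30 degC
        assert equivalent_temperature_change(IndexId.H, 25, 50, 60) > 1.5
        assert equivalent_temperature_change(IndexId.H, 30, 50, 60) > 1.73

    @pytest.mark.parametrize("T1", DEFAULT_TEMPS)
    def test_thi6_negative_others_positive(self, T1):
        for id in IndexId:
            t_equ = equivalent_temperature_change(id, T1, 50.0, 60.0)
            if id is IndexId.THI6:
                assert t_equ < 0
            else:
                assert t_equ > 0

    @pytest.mark.parametrize("id", list(IndexId))
    def test_sign_matches_humidity_slope_at_solution(self, id):
        T1 = 30.0
        T2 = solve_matched_temperature(id, T1, 50.0, 60.0)
        dRH = evaluate(id, T2, 60.001, 1.0) - evaluate(id, T2, 59.999, 1.0)
        assert ((T1 - T2) > 0) == (dRH > 0)


@pytest.fixture(scope="module")
def table():
    return equivalence_table()


class TestTable:
    def test_cardinality(self, table):
        assert len(table) == 12 * 4
        assert (table.status == "ok").all()

    def test_etis_trend_grows_with_temperature(self, table):
        etis = table[table["index"] == "ETIS"].sort_values("T1_c")["T_equ_c"]
        assert etis.is_monotonic_increasing and etis.nunique() == 4

    def test_near_parallel_family(self, table):
        # THI1/THI3/THI5/ET trends stay within 1 degC of their own means
        for name in ("THI1", "THI3", "THI5", "ET"):
            col = table[table["index"] == name]["T_equ_c"]
            assert (col - col.mean()).abs().max() < 1.0

    def test_failures_flagged_not_dropped(self):
        t = equivalence_table(ids=[IndexId.H], temps=[25.0], RH2=1.0)
        assert len(t) == 1 and t.iloc[0]["status"].startswith("failed")
        assert np.isnan(t.iloc[0]["T2_c"])
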