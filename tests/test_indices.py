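"""The twelve index formulas, their printed values and threshold zones."""

import math

import numpy as np
import pytest

from sowtherm import (
    AirState,
    IndexId,
    classify,
    compute_all,
    compute_index,
    evaluate,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "id, T, RH, v, expected, tol",
        [
            # winter references printed in the source analyses
            (IndexId.ET, 10, 60, 0.0, 21.2, 0.05),
            (IndexId.ETIS, 10, 60, 0.0, 18.6, 0.1),
            # hand evaluations
            (IndexId.THI2, 22, 70, None, 69.32, 1e-9),
            (IndexId.THI7, 22, 70, None, 20.7625, 1e-9),
            (IndexId.THI8, 22, 70, None, 64.6911, 1e-3),
            (IndexId.H, 46, 0, None, 46.276, 1e-3),
            (IndexId.H, 22, 70, None, 46.2822, 1e-3),
        ],
    )
    def test_printed_values(self, id, T, RH, v, expected, tol):
        assert evaluate(id, T, RH, v) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("T", [10.0, 22.0, 35.0])
    def test_et_neutral_point(self, T):
        # at RH 50 % and v = 0.2 m/s both ET correction terms vanish
        assert evaluate(IndexId.ET, T, 50, 0.2) == pytest.approx(T, abs=1e-12)

    @pytest.mark.parametrize("RH", [0.0, 50.0, 100.0])
    def test_thi7_saturation_identity(self, RH):
        # coefficient (0.55 - 0.0055*100) = 0 at saturation
        if RH == 100.0:
            assert evaluate(IndexId.THI7, 33.0, RH) == pytest.approx(33.0)
        else:
            assert evaluate(IndexId.THI7, 33.0, RH) != pytest.approx(33.0)

    @pytest.mark.parametrize("u", [0.0, 0.5, 2.0, 4.0])
    def test_etis_velocity_independent_at_skin_temperature(self, u):
        ref = evaluate(IndexId.ETIS, 38.0, 60.0, 0.0)
        assert evaluate(IndexId.ETIS, 38.0, 60.0, u) == pytest.approx(ref)

    def test_thi4_is_thi7_in_fahrenheit(self):
        # same functional form, THI4 on the Fahrenheit scale (58 F = 14.44 C)
        T, RH = 30.0, 55.0
        thi4 = evaluate(IndexId.THI4, T, RH)
        Tf = 1.8 * T + 32
        assert thi4 == pytest.approx(Tf - (0.55 - 0.0055 * RH) * (Tf - 58))

    def test_velocity_required(self):
        with pytest.raises(ValueError, match="velocity"):
            evaluate(IndexId.ET, 25, 60)


class TestComputeAll:
    def test_full_state_yields_all_twelve(self):
        out = compute_all(AirState(T=22, RH=70, v=0.0))
        assert set(out) == set(IndexId)
        assert all(math.isfinite(iv.value) for iv in out.values())

    def test_velocity_free_state_omits_et_and_etis(self):
        out = compute_all(AirState(T=22, RH=70))
        assert set(out) == set(IndexId) - {IndexId.ET, IndexId.ETIS}

    def test_winter_state_contains_et_reference(self):
        out = compute_all(AirState(T=10, RH=60, v=0.0))
        assert out[IndexId.ET].value == pytest.approx(21.2, abs=0.05)

    def test_compute_index_round_trips_state(self):
        state = AirState(T=25, RH=55, v=1.0)
        iv = compute_index(IndexId.ETIS, state)
        assert iv.state is state and iv.id is IndexId.ETIS


class TestThresholds:
    @pytest.mark.parametrize(
        "id, value, label",
        [
            (IndexId.THI2, 73.9, "suitable"),
            (IndexId.THI2, 74.0, "mild"),
            (IndexId.THI2, 82.0, "severe"),
            (IndexId.THI6, 74.0, "suitable"),   # upper bound closed
            (IndexId.THI6, 74.01, "mild"),
            (IndexId.ETIS, 18.6, "suitable"),
            (IndexId.ETIS, 35.9, "severe"),
            (IndexId.THI3, 28.0, "heat stress"),
            (IndexId.THI3, 27.9, "unclassified"),
            (IndexId.THI5, 80.0, "unclassified"),  # printed gap 78-83
            (IndexId.THI5, 75.0, "moderate"),
            (IndexId.THI1, 61.0, "unclassified"),  # lower bound open
            (IndexId.THI1, 61.1, "thermal comfort"),
        ],
    )
    def test_zone_labels(self, id, value, label):
        assert classify(id, value) == label

    @pytest.mark.parametrize(
        "id", [IndexId.THI4, IndexId.THI7, IndexId.THI8, IndexId.BGHI, IndexId.ET, IndexId.H]
    )
    def test_indices_without_thresholds_raise(self, id):
        with pytest.raises(ValueError, match="no thresholds"):
            classify(id, 75.0)


class TestMonotonicity:
    """Grid-scan monotonicity structure shared by the comparison analyses."""

    @pytest.mark.parametrize("id", list(IndexId))
    @pytest.mark.parametrize("RH", [30.0, 60.0, 90.0])
    def test_strictly_increasing_in_temperature(self, id, RH):
        # ETIS evaluated at the 1 m/s comparison velocity, where it stays
        # monotone through 40 degC (its T-derivative turns only above ~41.5)
        v = 1.0 if id.uses_velocity else None
        Ts = np.arange(10.0, 40.0 + 1e-9, 0.25)
        vals = [evaluate(id, T, RH, v) for T in Ts]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("id", list(IndexId))
    def test_humidity_slope_sign_at_30C(self, id):
        v = 1.0 if id.uses_velocity else None
        d = evaluate(id, 30.0, 60.001, v) - evaluate(id, 30.0, 59.999, v)
        if id is IndexId.THI6:
            assert d < 0
        else:
            assert d > 0

    @pytest.mark.parametrize("T", [20.0, 30.0, 40.0])
    def test_thi6_humidity_slope_negative_above_58F(self, T):
        # the RH term of THI6 is a decreasing function once T > 14.4 degC
        d = evaluate(IndexId.THI6, T, 70.0) - evaluate(IndexId.THI6, T, 50.0)
        assert d < 0
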