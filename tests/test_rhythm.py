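"""Unit and property tests for the cosine activity model and circular
trait arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from chronoecol import (
    RhythmParams,
    activity_rate,
    circular_distance,
    circular_mean,
    expected_moves,
    inherit_traits,
    realize_moves,
    resource_energy,
)

angles = st.floats(min_value=0.0, max_value=359.999)
amplitudes = st.floats(min_value=0.0, max_value=1.0)


class TestActivityRate:
    @pytest.mark.parametrize(
        "amp, phase, t, expected",
        [
            (0.0, 0.0, 123.4, 20 / 360),   # flat profile
            (0.0, 271.0, 7.7, 20 / 360),
            (1.0, 90.0, 90.0, 40 / 360),   # peak doubles the flat rate
            (1.0, 90.0, 270.0, 0.0),       # trough of full-amplitude rhythm
        ],
    )
    def test_examples(self, amp, phase, t, expected):
        assert activity_rate(amp, phase, t) == pytest.approx(expected, abs=1e-12)

    @given(amplitudes, angles, st.floats(min_value=-720, max_value=720))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative(self, amp, phase, t):
        assert activity_rate(amp, phase, t) >= -1e-12


class TestExpectedMoves:
    def test_full_day_is_m_total_for_any_rhythm(self, rng):
        amp = rng.random(10_000)
        phase = rng.random(10_000) * 360
        m = expected_moves(amp, phase, 0.0, 360.0)
        assert np.max(np.abs(m - 20.0)) < 1e-9

    def test_flat_single_step(self):
        assert expected_moves(0.0, 0.0, 0.0, 36.0) == pytest.approx(2.0)

    def test_peak_step_matches_quadrature(self):
        closed = expected_moves(1.0, 0.0, -18.0, 18.0)
        quad, _ = integrate.quad(lambda t: activity_rate(1.0, 0.0, t), -18, 18)
        assert closed == pytest.approx(quad, abs=1e-6)
        assert closed == pytest.approx(3.9672632861, abs=1e-6)

    def test_random_intervals_match_quadrature(self, rng):
        for _ in range(100):
            amp, phase = rng.random(), rng.random() * 360
            t0 = rng.uniform(-360, 360)
            t1 = t0 + rng.uniform(1.0, 360.0)
            closed = expected_moves(amp, phase, t0, t1)
            quad, _ = integrate.quad(
                lambda t: activity_rate(amp, phase, t), t0, t1, limit=200
            )
            assert closed == pytest.approx(quad, abs=1e-6)

    @pytest.mark.parametrize("t0, t1", [(10.0, 10.0), (20.0, 10.0), (0.0, 400.0)])
    def test_rejects_bad_intervals(self, t0, t1):
        with pytest.raises(ValueError):
            expected_moves(0.5, 0.0, t0, t1)


class TestRealizeMoves:
    @pytest.mark.parametrize(
        "expected, credit, moves, new_credit",
        [(2.0, 0.0, 2, 0.0), (1.7, 0.5, 2, 0.2), (0.3, 0.3, 0, 0.6)],
    )
    def test_examples(self, expected, credit, moves, new_credit):
        m, c = realize_moves(expected, credit)
        assert m == moves
        assert c == pytest.approx(new_credit)

    @given(
        st.floats(min_value=0, max_value=50),
        st.floats(min_value=0, max_value=0.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_credit_conserved(self, expected, credit):
        m, c = realize_moves(expected, credit)
        assert m + c == pytest.approx(expected + credit, abs=1e-9)
        assert 0 <= c < 1

    def test_daily_total_telescopes_to_m_total(self):
        credit, total = 0.0, 0
        for s in range(10):
            m = expected_moves(1.0, 0.0, 36.0 * s, 36.0 * (s + 1))
            k, credit = realize_moves(m, credit)
            total += k
        assert total == 20
        assert credit < 1e-9

    def test_daily_total_within_one_of_m_total_for_any_start_credit(self, rng):
        for _ in range(50):
            amp, phase = rng.random(), rng.random() * 360
            credit = rng.random()
            total = 0
            for s in range(10):
                m = expected_moves(amp, phase, 36.0 * s, 36.0 * (s + 1))
                k, credit = realize_moves(m, credit)
                total += k
            assert total in (19, 20, 21)


class TestResourceEnergy:
    def test_specialization_examples(self):
        # 20% bonus at the circadian peak when S = 0.2
        assert resource_energy(0.2, 40.0, 40.0) == pytest.approx(0.6)
        assert resource_energy(0.0, 40.0, 123.0) == pytest.approx(0.5)
        # S = 0.75: seven-fold peak/trough efficiency ratio
        peak = resource_energy(0.75, 0.0, 0.0)
        trough = resource_energy(0.75, 0.0, 180.0)
        assert peak / trough == pytest.approx(7.0)


class TestCircularArithmetic:
    @pytest.mark.parametrize(
        "angles_, expected",
        [([350, 10], 0.0), ([90, 90], 90.0), ([0, 90], 45.0)],
    )
    def test_mean_examples(self, angles_, expected):
        assert circular_distance(circular_mean(angles_), expected) < 1e-9

    @given(
        st.lists(angles, min_size=1, max_size=20),
        st.floats(min_value=0, max_value=360),
    )
    @settings(max_examples=200, deadline=None)
    def test_mean_rotation_equivariant(self, angs, c):
        a = np.array(angs)
        base = circular_mean(a)
        rad = a * np.pi / 180
        # skip near-degenerate resultants, where the tie-break applies
        if np.hypot(np.cos(rad).sum(), np.sin(rad).sum()) / a.size < 1e-6:
            return
        rotated = circular_mean((a + c) % 360)
        assert circular_distance(rotated, (base + c) % 360) < 1e-6

    def test_mean_antipodal_tiebreak(self, rng):
        picks = {circular_mean([0.0, 180.0], rng=rng) for _ in range(200)}
        assert picks <= {0.0, 180.0}
        assert len(picks) == 2  # both parents chosen over repeated draws
        assert circular_mean([0.0, 180.0]) == 0.0  # deterministic without rng

    @pytest.mark.parametrize(
        "a, b, expected", [(0, 180, 180), (350, 10, 20), (90, 90, 0), (10, 350, 20)]
    )
    def test_distance_examples(self, a, b, expected):
        assert circular_distance(a, b) == pytest.approx(expected)


class TestInheritTraits:
    def test_zero_sd_is_deterministic_blend(self, rng):
        child = inherit_traits(
            RhythmParams(0.4, 350.0), RhythmParams(0.6, 10.0), 0.0, 0.0, rng
        )
        assert child.amplitude == pytest.approx(0.5)
        assert child.phase == pytest.approx(0.0, abs=1e-9)

    def test_identical_parents_fixed_point(self, rng):
        p = RhythmParams(1.0, 0.0)
        child = inherit_traits(p, p, 0.0, 0.0, rng)
        assert (child.amplitude, child.phase) == (1.0, 0.0)

    def test_amplitude_clamped_at_boundaries(self, rng):
        p = RhythmParams(1.0, 0.0)
        amps = [
            inherit_traits(p, p, 0.1, 0.0, rng).amplitude for _ in range(500)
        ]
        assert max(amps) == 1.0  # positive draws clamp to the boundary
        assert all(0.0 <= a <= 1.0 for a in amps)

    def test_phase_wrapped(self, rng):
        child = inherit_traits(
            RhythmParams(0.5, 359.0), RhythmParams(0.5, 359.0), 0.0, 0.05, rng
        )
        assert 0.0 <= child.phase < 360.0
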