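"""Cosine activity-rhythm model, time-of-day specialization, and circular
trait arithmetic.

Angles are degrees throughout the package: one simulated day spans 360
degrees (24 h, so 1 h = 15 degrees).  Conversion to radians happens only
inside trigonometric calls.  The daily activity profile of an organism is

    rate(t) = (M_total / 360) * (1 + A * cos(t - phi))

where ``A`` (amplitude, dimensionless in [0, 1]) sets how strongly activity
is concentrated around the phase angle ``phi`` (degrees, peak-activity time
of day).  ``A = 0`` is an arrhythmic (cathemeral) organism, ``A = 1`` a
fully rhythmic one whose activity falls to zero at the trough.  The
integral of the rate over any full day equals ``M_total`` regardless of
``A`` and ``phi``: total daily movement (and hence energy expenditure) is
held constant so that only the *timing* of activity can evolve.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEG_PER_DAY = 360.0
STEPS_PER_DAY = 10
DEG_PER_STEP = DEG_PER_DAY / STEPS_PER_DAY  # 36 degrees per time step
M_TOTAL = 20.0  # moves per organism per day
E_ORIG = 0.5  # baseline energy gained per consumed resource

_D2R = np.pi / 180.0
_R2D = 180.0 / np.pi
_TIE_TOL = 1e-9  # resultant-length threshold for the circular-mean tie-break


def wrap_phase(angle):
    """Wrap an angle (degrees) into [0, 360)."""
    return angle % 360.0


@dataclass(frozen=True)
class RhythmParams:
    """Heritable rhythm genotype of one organism.

    amplitude : dimensionless in [0, 1]
    phase     : degrees in [0, 360), time of day of peak activity
    """

    amplitude: float
    phase: float

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must lie in [0, 1], got {self.amplitude}")
        object.__setattr__(self, "phase", float(self.phase) % 360.0)


def activity_rate(amplitude, phase, t, m_total=M_TOTAL):
    """Instantaneous movement rate (moves per degree of day) at time ``t``."""
    return (m_total / DEG_PER_DAY) * (1.0 + amplitude * np.cos((t - phase) * _D2R))


def expected_moves(amplitude, phase, t0, t1, m_total=M_TOTAL):
    """Expected (real-valued) number of moves in the interval ``[t0, t1]``.

    Closed form of the integral of :func:`activity_rate`:

        m = (M_total/360) * [(t1 - t0) + A * (180/pi) * (sin(t1 - phi) - sin(t0 - phi))]

    The 180/pi factor converts the antiderivative of the degree-argument
    cosine back to degree units.  Over a full day (t1 - t0 = 360) the sine
    terms cancel and m = M_total exactly.
    """
    t0 = np.asarray(t0, dtype=float) if not np.isscalar(t0) else float(t0)
    t1 = np.asarray(t1, dtype=float) if not np.isscalar(t1) else float(t1)
    if np.any(np.asarray(t1 - t0) <= 0):
        raise ValueError("require t1 > t0")
    if np.any(np.asarray(t1 - t0) > DEG_PER_DAY):
        raise ValueError("interval may not exceed one day (360 degrees)")
    sine_term = np.sin((t1 - phase) * _D2R) - np.sin((t0 - phase) * _D2R)
    m = (m_total / DEG_PER_DAY) * ((t1 - t0) + amplitude * _R2D * sine_term)
    return np.maximum(m, 0.0)


def realize_moves(expected, credit):
    """Convert a real-valued move expectation into an integer move count.

    A deterministic fractional-credit accumulator: the carried ``credit``
    (in [0, 1)) is added to ``expected``, the floor is realized as whole
    moves and the remainder carried forward.  Credit is conserved (to the
    snapping tolerance below), so realized moves telescope to the integral
    of the activity profile.  Totals within 1e-9 of an integer are snapped
    to it so that an exactly-telescoping day realizes exactly ``M_total``
    moves despite floating-point residue in the sine terms.
    """
    if expected < 0:
        raise ValueError("expected moves must be non-negative")
    total = credit + expected
    moves = int(np.floor(total + 1e-9))
    return moves, max(total - moves, 0.0)


def resource_energy(s, phase, t, e_orig=E_ORIG):
    """Energy acquired from one resource, adjusted by specialization.

        E_adj = E_orig * (1 + S * cos(t - phi))

    ``S`` is the specialization value: S = 0.2 means the organism extracts
    20% more energy per resource at its circadian peak and 20% less at the
    trough.  The specialization wave shares the activity phase ``phi``.
    """
    return e_orig * (1.0 + s * np.cos((t - phase) * _D2R))


def circular_mean(angles, rng=None):
    """Circular mean of angles in degrees, wrapped to [0, 360).

    When the mean resultant vector is degenerate (length below 1e-9, e.g.
    two exactly antipodal parents) a deterministic answer would bias phase
    evolution, so one of the input angles is returned uniformly at random
    when ``rng`` is given; without an ``rng`` the first angle is returned.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("circular_mean of empty sequence")
    rad = a * _D2R
    x = np.cos(rad).sum()
    y = np.sin(rad).sum()
    if np.hypot(x, y) / a.size < _TIE_TOL:
        if rng is not None:
            return float(a[rng.integers(a.size)]) % 360.0
        return float(a[0]) % 360.0
    return float(np.arctan2(y, x) * _R2D) % 360.0


def circular_distance(a, b):
    """Shortest angular separation between two angles, in [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def inherit_traits(p1: RhythmParams, p2: RhythmParams,
                   amp_sd: float, phase_sd_frac: float, rng) -> RhythmParams:
    """Offspring rhythm genotype from two parents.

    amplitude = mean of parents + Normal(0, amp_sd), clamped to [0, 1]
    phase     = circular mean of parents + Normal(0, phase_sd_frac * 360),
                wrapped to [0, 360)

    With both SDs zero the traits are a pure (circular) blend of the
    parents; positive SDs are the mutation kernel on which selection acts.
    Clamping at the amplitude boundaries (rather than redrawing) keeps the
    effective kernel explicit.
    """
    amp = 0.5 * (p1.amplitude + p2.amplitude) + rng.normal(0.0, amp_sd)
    amp = min(1.0, max(0.0, amp))
    phase = circular_mean([p1.phase, p2.phase], rng=rng)
    phase = (phase + rng.normal(0.0, phase_sd_frac * DEG_PER_DAY)) % 360.0
    return RhythmParams(amp, phase)
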