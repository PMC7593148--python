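"""Mate-pair selection, offspring creation, and stabilized growth rates.

Matings occur throughout the day at a rate tuned so an undisturbed
population would grow 10% per day: each step every species accrues
``p * r_adj * 36/360`` expected progeny into a fractional birth ledger and
realizes the floor as actual matings.  Parents are drawn with probability
proportional to stored energy, so foraging success is fitness.  Each
mating produces one offspring to whom each parent donates one third of its
energy — energy is conserved exactly across the event — and whose rhythm
genotype blends the parents' with optional mutation noise.

Two optional layers sit on top:

* **Population stabilization** (two-species scenarios that are not testing
  competitive exclusion): the growth rate of each species is scaled by
  ``k * P_total / p`` so a species below its target share ``k`` of the
  community reproduces slightly more, and one above it slightly less.
* **Assortative mating by phase**: each organism can only mate inside a
  fixed-width window (default 135 degrees = 9 h) centred on its phase
  angle; the probability of a given pairing is proportional to the overlap
  of the two windows, falling linearly from 1 at zero phase difference to
  0 at a difference of one window width.
"""

from __future__ import annotations

import numpy as np

from . import rhythm
from .engine import Organism, SimConfig, SpeciesConfig, World

__all__ = [
    "adjusted_growth_rate",
    "expected_progeny",
    "mating_window_overlap",
    "select_pair",
    "select_community_pair",
    "mate",
    "reproduction_step",
]

_MAX_PARTNER_RETRIES = 10


def adjusted_growth_rate(r: float, k: float, p: int, p_total: int) -> float:
    """Stabilized per-day growth rate ``r_adj = r * k * P_total / p``.

    At the target ratio (p = k * P_total) this equals ``r``; below target
    it is larger, above target smaller.  An extinct species (p = 0) gets 0.
    """
    if p == 0:
        return 0.0
    return r * k * p_total / p


def expected_progeny(p: int, r_adj: float, dt: float = rhythm.DEG_PER_STEP) -> float:
    """Expected births for a species in one time interval of ``dt`` degrees:
    ``p * r_adj * dt / 360``.  Summed over a day this telescopes to
    ``p * r_adj``."""
    return p * r_adj * dt / rhythm.DEG_PER_DAY


def mating_window_overlap(phi1, phi2, width: float = 135.0):
    """Fractional overlap of two organisms' mating windows, in [0, 1].

    Each window is an arc of ``width`` degrees fixed relative to the
    organism's phase angle.  The overlap falls linearly from 1 at zero
    phase difference to 0 at a circular phase difference of ``width``
    degrees or more.  For windows wider than half the day the arcs also
    meet around the far side of the circle (so two full-circle windows
    always overlap completely, making the assortative filter inert).
    """
    d = rhythm.circular_distance(phi1, phi2)
    direct = np.maximum(0.0, width - d)
    wrapped = np.maximum(0.0, width - (360.0 - d))
    return np.minimum((direct + wrapped) / width, 1.0)


def _weighted_index(weights: np.ndarray, rng):
    """Index drawn with probability proportional to ``weights`` (cumsum +
    inverse-CDF); None if all weights are zero."""
    c = np.cumsum(weights)
    total = c[-1]
    if total <= 0.0:
        return None
    i = int(np.searchsorted(c, rng.random() * total, side="right"))
    return min(i, weights.size - 1)


def select_pair(energies: np.ndarray, phases: np.ndarray, rng,
                assortative: bool = False, width: float = 135.0):
    """Pick two distinct conspecific parents, or return None on failure.

    The first parent is drawn with probability proportional to energy.
    Non-assortative: the second is drawn proportional to energy among the
    rest.  Assortative: the second is drawn proportional to energy times
    mating-window overlap with the first; if no candidate overlaps, a
    fresh first parent is drawn, up to 10 attempts, after which the mating
    fails and the birth is forfeited.
    """
    n = energies.size
    if n < 2:
        return None
    attempts = _MAX_PARTNER_RETRIES if assortative else 1
    for _ in range(attempts):
        i = _weighted_index(energies, rng)
        if i is None:
            return None
        w = energies.copy()
        if assortative:
            w *= mating_window_overlap(phases[i], phases, width)
        w[i] = 0.0
        j = _weighted_index(w, rng)
        if j is not None:
            return i, j
        if not assortative:
            return None
    return None


def mate(parent1: Organism, parent2: Organism, species_cfg: SpeciesConfig,
         rng, offspring_id: int = -1) -> Organism:
    """Produce one offspring; each parent donates 1/3 of its energy.

    Parents' energies are reduced in place; total energy is conserved.
    The offspring starts at age 0 with zero move credit and traits from
    :func:`chronoecol.rhythm.inherit_traits`.
    """
    if parent1.species != parent2.species:
        raise ValueError("parents must be conspecific")
    e1, e2 = parent1.energy, parent2.energy
    child_energy = (e1 + e2) / 3.0
    parent1.energy = e1 * 2.0 / 3.0
    parent2.energy = e2 * 2.0 / 3.0
    traits = rhythm.inherit_traits(
        parent1.rhythm, parent2.rhythm,
        species_cfg.amp_sd, species_cfg.phase_sd_frac, rng,
    )
    return Organism(id=offspring_id, species=parent1.species,
                    rhythm=traits, energy=child_energy)


def select_community_pair(world: World, cfg: SimConfig, rng,
                          max_attempts: int = 20):
    """Energy-proportional pair from the whole community, rejected unless
    conspecific; returns (i, j) world indices or None.

    Used when population stabilization is off: matings are drawn at the
    community-wide rate and a candidate pair mates only if both members
    belong to the same species (cross-species pairs are redrawn).  A
    species holding a larger share of the community's stored energy
    therefore captures a more-than-proportional share of the matings —
    the frequency-dependent feedback behind competitive exclusion of
    temporally identical species.
    """
    if world.n_alive < 2:
        return None
    for _ in range(max_attempts):
        i = _weighted_index(world.energy, rng)
        if i is None:
            return None
        w = world.energy.copy()
        if cfg.assortative:
            w *= mating_window_overlap(world.phase[i], world.phase,
                                       cfg.window_width)
        w[i] = 0.0
        j = _weighted_index(w, rng)
        if j is not None and world.species[i] == world.species[j]:
            return i, j
    return None


def reproduction_step(world: World, cfg: SimConfig,
                      birth_credit: np.ndarray, rng) -> int:
    """Perform one time step's matings; returns the number of births.

    With stabilization on, each species carries its own fractional birth
    ledger accruing ``expected_progeny`` at the stabilized rate and
    realizes the floor as matings among its members.  With stabilization
    off, births accrue at the community rate ``P_total * r`` into a single
    ledger (slot 0) and each mating draws an energy-proportional pair from
    the whole community, redrawn until conspecific — so the share of
    births a species captures follows its share of stored energy rather
    than a fixed per-species quota.

    Newborns are appended to the world only after all of the step's
    matings, so they can neither mate nor be chosen as partners until the
    following step; parental energy donations, however, take effect
    immediately and are visible to later matings in the same step.
    Failed matings (assortative window empty, or no conspecific pair
    found) forfeit the birth: the ledger is still decremented.
    """
    p_total = world.n_alive
    if p_total == 0:
        return 0
    new_species, new_amp, new_phase, new_energy = [], [], [], []
    n_births = 0

    def do_mating(i: int, j: int) -> None:
        nonlocal n_births
        si = int(world.species[i])
        sp = cfg.species[si]
        e1, e2 = world.energy[i], world.energy[j]
        child_energy = (e1 + e2) / 3.0
        world.energy[i] = e1 * 2.0 / 3.0
        world.energy[j] = e2 * 2.0 / 3.0
        traits = rhythm.inherit_traits(
            rhythm.RhythmParams(world.amplitude[i], world.phase[i]),
            rhythm.RhythmParams(world.amplitude[j], world.phase[j]),
            sp.amp_sd, sp.phase_sd_frac, rng,
        )
        new_species.append(si)
        new_amp.append(traits.amplitude)
        new_phase.append(traits.phase)
        new_energy.append(child_energy)
        n_births += 1

    if cfg.stabilize:
        counts = world.species_counts(cfg.n_species)
        for si, sp in enumerate(cfg.species):
            p = int(counts[si])
            if p == 0:
                continue
            r_adj = adjusted_growth_rate(cfg.r, sp.k, p, p_total)
            birth_credit[si] += expected_progeny(p, r_adj, rhythm.DEG_PER_STEP)
            n_matings = int(birth_credit[si])
            if n_matings == 0:
                continue
            birth_credit[si] -= n_matings
            members = np.flatnonzero(world.species == si)
            for _ in range(n_matings):
                pair = select_pair(
                    world.energy[members], world.phase[members], rng,
                    assortative=cfg.assortative, width=cfg.window_width,
                )
                if pair is not None:
                    do_mating(int(members[pair[0]]), int(members[pair[1]]))
    else:
        birth_credit[0] += expected_progeny(p_total, cfg.r, rhythm.DEG_PER_STEP)
        n_matings = int(birth_credit[0])
        birth_credit[0] -= n_matings
        for _ in range(n_matings):
            pair = select_community_pair(world, cfg, rng)
            if pair is not None:
                do_mating(*pair)
    if n_births:
        nb = n_births
        world.species = np.concatenate([world.species, np.array(new_species, np.int64)])
        world.amplitude = np.concatenate([world.amplitude, np.array(new_amp)])
        world.phase = np.concatenate([world.phase, np.array(new_phase)])
        world.energy = np.concatenate([world.energy, np.array(new_energy)])
        world.age = np.concatenate([world.age, np.zeros(nb, np.int64)])
        world.move_credit = np.concatenate([world.move_credit, np.zeros(nb)])
        world.position = np.concatenate(
            [world.position, rng.integers(0, cfg.n_spaces, nb)]
        )
        world.births += nb
    return n_births
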