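"""Stateful simulation core: resource grid, movement and foraging,
metabolism, death, and the per-time-step scheduler.

The world is a ring of 60 undifferentiated spaces into which 600 resources
per day are dropped uniformly at random, in batches of 60 at the start of
each of the 10 daily time steps.  Organisms move by jumping to one of the
59 *other* spaces chosen uniformly; landing on a space holding at least one
resource consumes exactly one resource and credits the organism with
``resource_energy`` evaluated at the step's midpoint time.  Every organism
pays a flat 0.2 energy per step (2 per day) regardless of realized
movement, dies immediately when its energy reaches zero, and dies of old
age on the day boundary at which its age reaches ``max_age`` days.

The population is stored struct-of-arrays for speed; one entry per living
organism.  A conservation ledger (resources added/consumed, energy
gained/metabolized/removed with corpses) is maintained so tests can verify
the books balance exactly.

Event order within a step: resource input -> movement/foraging ->
metabolism -> energy cull -> reproduction -> (on day wrap) aging and age
cull.  Organisms therefore eat before being charged, and newborns cannot
forage in their birth step.  Within the movement phase the contention
order (who reaches a contested resource first) is reshuffled every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import rhythm
from .rhythm import (
    DEG_PER_DAY,
    DEG_PER_STEP,
    _D2R,
    _R2D,
)

__all__ = [
    "SpeciesConfig",
    "SimConfig",
    "Organism",
    "World",
    "init_world",
    "add_resources",
    "jump_and_forage",
    "apply_metabolism",
    "cull_energy_dead",
    "cull_age_dead",
    "step",
]


@dataclass
class SpeciesConfig:
    """Per-species initial conditions, mutation SDs and competition knobs.

    n0              initial population
    amplitude0      initial rhythm amplitude (all founders identical)
    phase0          initial phase angle, degrees
    amp_sd          mutation SD of offspring amplitude (0 = fixed trait)
    phase_sd_frac   mutation SD of offspring phase as a fraction of 360 deg
    s               specialization value (energy-efficiency modulation)
    k               target fraction of the total population (stabilization)
    init_phase_sd   SD (degrees) of per-founder scatter around phase0
    init_energy     founder stored energy
    """

    n0: int = 75
    amplitude0: float = 1.0
    phase0: float = 0.0
    amp_sd: float = 0.0
    phase_sd_frac: float = 0.0
    s: float = 0.0
    k: float = 0.5
    init_phase_sd: float = 0.0
    init_energy: float = 2.0


@dataclass
class SimConfig:
    """World constants and scenario switches.

    The defaults are the standard study conditions: a 60-space arena fed
    600 resources/day in 10 steps, organisms moving 20 times/day, paying 2
    energy/day, gaining 0.5 energy/resource, dying at age 12 days, and a
    baseline population growth rate of 10%/day.  The implied carrying
    capacity is 600 * 0.5 / 2 = 150 organisms.
    """

    species: list = field(default_factory=lambda: [SpeciesConfig()])
    n_spaces: int = 60
    resources_per_day: int = 600
    steps_per_day: int = 10
    m_total: float = 20.0
    daily_cost: float = 2.0
    e_orig: float = 0.5
    max_age: int = 12
    r: float = 0.1
    window_width: float = 135.0
    assortative: bool = False
    stabilize: bool = True
    horizon_days: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.species = [
            SpeciesConfig(**sp) if isinstance(sp, dict) else sp for sp in self.species
        ]
        if self.n_spaces < 2:
            raise ValueError("need at least two spaces for jumps")
        if self.resources_per_day < 0:
            raise ValueError("resources_per_day must be non-negative")
        for name in ("steps_per_day", "m_total", "daily_cost", "e_orig",
                     "max_age", "horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_width <= DEG_PER_DAY:
            raise ValueError("window_width must lie in (0, 360]")
        if self.stabilize and len(self.species) > 0:
            ktot = sum(sp.k for sp in self.species)
            if abs(ktot - 1.0) > 1e-9:
                raise ValueError("species target fractions k must sum to 1 "
                                 f"when stabilization is on (got {ktot})")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def resources_per_step(self) -> int:
        return self.resources_per_day // self.steps_per_day

    @property
    def cost_per_step(self) -> float:
        return self.daily_cost / self.steps_per_day

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Organism:
    """A single agent, used at the API surface (fixtures, scalar mating).

    The engine itself stores the population struct-of-arrays; this record
    mirrors one entry of those arrays.
    """

    id: int
    species: int
    rhythm: rhythm.RhythmParams
    energy: float
    age: int = 0
    move_credit: float = 0.0


@dataclass
class World:
    """The resource grid plus the living population at one simulated time.

    Population arrays are parallel: entry ``i`` of each describes one
    living organism.  ``grid[s]`` is the resource count in space ``s``.
    """

    grid: np.ndarray
    species: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    energy: np.ndarray
    age: np.ndarray
    move_credit: np.ndarray
    position: np.ndarray
    day: int = 0
    step_in_day: int = 0
    # conservation ledger
    res_added: int = 0
    res_consumed: int = 0
    energy_initial: float = 0.0
    energy_gained: float = 0.0
    energy_metabolized: float = 0.0
    energy_removed_dead: float = 0.0
    births: int = 0
    deaths_energy: int = 0
    deaths_age: int = 0

    @property
    def n_alive(self) -> int:
        return self.energy.size

    def species_counts(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species)

    def keep(self, mask: np.ndarray) -> None:
        """Drop organisms where ``mask`` is False (no ledger accounting)."""
        for name in ("species", "amplitude", "phase", "energy", "age",
                     "move_credit", "position"):
            setattr(self, name, getattr(self, name)[mask])


def init_world(config: SimConfig, rng) -> World:
    """Found the population described by ``config`` on an empty grid.

    Founders carry the species' exact initial traits (optionally scattered
    in phase by ``init_phase_sd``), one day's worth of stored energy by
    default, ages uniform on 0..max_age-1 (avoiding a synchronized old-age
    die-off), zero move credit, and uniform-random positions.
    """
    species, amplitude, phase, energy, age, position = [], [], [], [], [], []
    for si, sp in enumerate(config.species):
        n = sp.n0
        species.append(np.full(n, si, dtype=np.int64))
        amplitude.append(np.full(n, float(sp.amplitude0)))
        ph = np.full(n, float(sp.phase0))
        if sp.init_phase_sd > 0:
            ph = (ph + rng.normal(0.0, sp.init_phase_sd, n)) % DEG_PER_DAY
        phase.append(ph)
        energy.append(np.full(n, float(sp.init_energy)))
        age.append(rng.integers(0, config.max_age, n))
        position.append(rng.integers(0, config.n_spaces, n))
    cat = lambda parts, dt: (np.concatenate(parts).astype(dt) if parts
                             else np.empty(0, dtype=dt))
    world = World(
        grid=np.zeros(config.n_spaces, dtype=np.int64),
        species=cat(species, np.int64),
        amplitude=cat(amplitude, float),
        phase=cat(phase, float),
        energy=cat(energy, float),
        age=cat(age, np.int64),
        move_credit=np.zeros(sum(sp.n0 for sp in config.species)),
        position=cat(position, np.int64),
    )
    world.energy_initial = float(world.energy.sum())
    return world


def add_resources(world: World, n: int, rng) -> None:
    """Drop ``n`` resources, each into an independently uniform space."""
    if n < 0:
        raise ValueError("resource count must be non-negative")
    if n == 0:
        return
    dest = rng.integers(0, world.grid.size, n)
    np.add.at(world.grid, dest, 1)
    world.res_added += n


def jump_and_forage(world: World, i: int, t: float, s: float, rng,
                    e_orig: float = rhythm.E_ORIG) -> float:
    """One jump of organism ``i`` at time-of-day ``t``; returns energy gained.

    The destination is uniform over the 59 spaces other than the current
    one.  If it holds a resource, one resource is consumed and the
    organism gains ``resource_energy(s, phase_i, t)``.
    """
    n_spaces = world.grid.size
    d = int(rng.integers(0, n_spaces - 1))
    if d >= world.position[i]:
        d += 1
    world.position[i] = d
    if world.grid[d] > 0:
        world.grid[d] -= 1
        world.res_consumed += 1
        gain = float(rhythm.resource_energy(s, world.phase[i], t, e_orig))
        world.energy[i] += gain
        world.energy_gained += gain
        return gain
    return 0.0


def apply_metabolism(world: World, cost: float) -> None:
    """Charge every living organism a flat ``cost`` of energy."""
    world.energy -= cost
    world.energy_metabolized += cost * world.n_alive


def cull_energy_dead(world: World) -> int:
    """Remove organisms whose energy has reached zero; returns removals."""
    dead = world.energy <= 0.0
    n = int(dead.sum())
    if n:
        world.energy_removed_dead += float(world.energy[dead].sum())
        world.deaths_energy += n
        world.keep(~dead)
    return n


def cull_age_dead(world: World, max_age: int) -> int:
    """Remove organisms that have reached ``max_age`` days; returns removals."""
    dead = world.age >= max_age
    n = int(dead.sum())
    if n:
        world.energy_removed_dead += float(world.energy[dead].sum())
        world.deaths_age += n
        world.keep(~dead)
    return n


def _forage_phase(world: World, cfg: SimConfig, rng) -> None:
    """Vectorized movement-and-foraging phase for one time step.

    Each organism's expected moves over the step are accumulated into its
    fractional-move credit and the floor realized as whole jumps.  All of
    a step's jumps are foraged at the step midpoint time.  Contention for
    scarce resources is resolved in a freshly shuffled organism order,
    each organism taking its jumps consecutively: arrivals at a space
    consume its stock first-come first-served.
    """
    n = world.n_alive
    if n == 0:
        return
    t0 = world.step_in_day * DEG_PER_STEP
    t1 = t0 + DEG_PER_STEP
    t_mid = t0 + 0.5 * DEG_PER_STEP

    sine_term = np.sin((t1 - world.phase) * _D2R) - np.sin((t0 - world.phase) * _D2R)
    expected = (cfg.m_total / DEG_PER_DAY) * (
        DEG_PER_STEP + world.amplitude * _R2D * sine_term
    )
    np.maximum(expected, 0.0, out=expected)
    total = world.move_credit + expected
    k = np.floor(total + 1e-9).astype(np.int64)  # snap near-integer totals
    world.move_credit = np.maximum(total - k, 0.0)

    kmax = int(k.max())
    if kmax == 0:
        return
    # Contention priority: a fresh shuffle of the organisms each step.
    order = rng.permutation(n)
    # Destinations round by round so each jump excludes the space the
    # organism currently occupies.
    dest_rounds = np.zeros((kmax, n), dtype=np.int64)
    pos = world.position.copy()
    for j in range(kmax):
        active = np.flatnonzero(k > j)
        d = rng.integers(0, cfg.n_spaces - 1, active.size)
        d += d >= pos[active]
        pos[active] = d
        dest_rounds[j, active] = d
    world.position = pos

    # Arrival sequence: organisms in shuffled order, each taking its own
    # jumps consecutively.
    ks = k[order]
    seq_org = np.repeat(order, ks)
    tot = seq_org.size
    starts = np.concatenate(([0], np.cumsum(ks)[:-1]))
    round_idx = np.arange(tot) - np.repeat(starts, ks)
    seq_dest = dest_rounds[round_idx, seq_org]

    # First-come first-served: within each space, the first `stock` arrivals
    # in sequence order consume a resource.
    sorter = np.argsort(seq_dest, kind="stable")
    sorted_dest = seq_dest[sorter]
    first_at = np.searchsorted(sorted_dest, sorted_dest, side="left")
    rank = np.arange(tot) - first_at
    eats = rank < world.grid[sorted_dest]

    consumed = np.bincount(sorted_dest[eats], minlength=cfg.n_spaces)
    world.grid -= consumed
    world.res_consumed += int(consumed.sum())

    n_eaten = np.bincount(seq_org[sorter[eats]], minlength=n)
    s_per_org = np.array([sp.s for sp in cfg.species])[world.species]
    gain_per_resource = cfg.e_orig * (
        1.0 + s_per_org * np.cos((t_mid - world.phase) * _D2R)
    )
    gains = n_eaten * gain_per_resource
    world.energy += gains
    world.energy_gained += float(gains.sum())


def step(world: World, cfg: SimConfig, rng, birth_credit: np.ndarray) -> None:
    """Advance the world by one time step (1/10 of a day), in place.

    ``birth_credit`` is the per-species fractional-progeny ledger carried
    between steps by the reproduction module.
    """
    from . import reproduction  # local import to avoid a cycle

    add_resources(world, cfg.resources_per_step, rng)
    _forage_phase(world, cfg, rng)
    apply_metabolism(world, cfg.cost_per_step)
    cull_energy_dead(world)
    reproduction.reproduction_step(world, cfg, birth_credit, rng)
    world.step_in_day += 1
    if world.step_in_day >= cfg.steps_per_day:
        world.step_in_day = 0
        world.day += 1
        world.age += 1
        cull_age_dead(world, cfg.max_age)
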