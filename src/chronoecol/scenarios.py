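"""Scenario presets, trial/batch runners, fixture generation and output
writing.

Each preset fully determines a :class:`~chronoecol.engine.SimConfig` given
a seed, and corresponds to one of the standard experiments:

``exclusion_arrhythmic``    two arrhythmic species (A = 0), no trait
                            evolution, stabilization off — competitive
                            exclusion of one species is expected.
``exclusion_inphase``       two fully rhythmic species (A = 1) sharing a
                            phase — same expectation.
``coexist_antiphase``       two fully rhythmic species 180 deg apart —
                            temporal niche partitioning lets both persist.
``character_displacement``  both species start at the same phase with
                            phase free to evolve (amplitude fixed at 1);
                            their phases diverge to 180 deg apart.
``single_species``          one species with both traits evolving and a
                            chosen specialization S; intraspecific
                            competition drives amplitude toward 0 unless S
                            is large.
``two_species``             two evolving species stabilized at a target
                            population ratio (1:1, 2:1 or 9:1) with a
                            small specialization; interspecific
                            competition lets amplitude rise, more so for
                            the rarer species.
``speciation``              one species with assortative mating by phase;
                            disruptive selection can split it into two
                            reproductively isolated groups (CGM < 0.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, metrics, rhythm
from .engine import Organism, SimConfig, SpeciesConfig

__all__ = [
    "PRESETS",
    "build_scenario",
    "run_trial",
    "run_batch",
    "BatchSummary",
    "table1_sweep",
    "generate_fixture_population",
    "write_outputs",
]

_HORIZON = 2000  # days; the standard trial length

# Number of trailing recorded days over which "equilibrium" summaries
# (final amplitudes, final phase difference) are averaged.
EQUILIBRIUM_WINDOW = 200


def _two_species(amplitude0, phases, amp_sd=0.0, phase_sd_frac=0.0, s=0.0,
                 ks=(0.5, 0.5), n0=(75, 75), stabilize=True, **kw) -> SimConfig:
    species = [
        SpeciesConfig(n0=n0[i], amplitude0=amplitude0, phase0=phases[i],
                      amp_sd=amp_sd, phase_sd_frac=phase_sd_frac,
                      s=s, k=ks[i])
        for i in range(2)
    ]
    kw.setdefault("horizon_days", _HORIZON)
    return SimConfig(species=species, stabilize=stabilize, **kw)


def _preset_exclusion_arrhythmic(**p) -> SimConfig:
    return _two_species(amplitude0=0.0, phases=(0.0, 0.0), stabilize=False, **p)


def _preset_exclusion_inphase(**p) -> SimConfig:
    return _two_species(amplitude0=1.0, phases=(0.0, 0.0), stabilize=False, **p)


def _preset_coexist_antiphase(**p) -> SimConfig:
    return _two_species(amplitude0=1.0, phases=(0.0, 180.0), stabilize=False, **p)


def _preset_character_displacement(phase_sd=0.04, **p) -> SimConfig:
    return _two_species(amplitude0=1.0, phases=(0.0, 0.0),
                        phase_sd_frac=phase_sd, stabilize=True, **p)


def _preset_single_species(s=0.0, amp_sd=0.04, phase_sd=0.04,
                           amplitude0=0.5, n0=150, **p) -> SimConfig:
    sp = SpeciesConfig(n0=n0, amplitude0=amplitude0, phase0=0.0,
                       amp_sd=amp_sd, phase_sd_frac=phase_sd, s=s, k=1.0)
    p.setdefault("horizon_days", _HORIZON)
    return SimConfig(species=[sp], stabilize=True, **p)


def _preset_two_species(s=0.2, ratio=(1, 1), amp_sd=0.04, phase_sd=0.04,
                        amplitude0=0.5, **p) -> SimConfig:
    total = ratio[0] + ratio[1]
    ks = (ratio[0] / total, ratio[1] / total)
    return _two_species(amplitude0=amplitude0, phases=(0.0, 180.0),
                        amp_sd=amp_sd, phase_sd_frac=phase_sd, s=s,
                        ks=ks, stabilize=True, **p)


def _preset_speciation(phase_sd=0.05, amp_sd=0.02, n0=150, **p) -> SimConfig:
    sp = SpeciesConfig(n0=n0, amplitude0=1.0, phase0=0.0,
                       amp_sd=amp_sd, phase_sd_frac=phase_sd, s=0.0, k=1.0)
    p.setdefault("horizon_days", _HORIZON)
    return SimConfig(species=[sp], assortative=True, stabilize=True, **p)


PRESETS = {
    "exclusion_arrhythmic": _preset_exclusion_arrhythmic,
    "exclusion_inphase": _preset_exclusion_inphase,
    "coexist_antiphase": _preset_coexist_antiphase,
    "character_displacement": _preset_character_displacement,
    "single_species": _preset_single_species,
    "two_species": _preset_two_species,
    "speciation": _preset_speciation,
}


def build_scenario(name: str, **overrides) -> SimConfig:
    """Build the named preset, applying overrides.

    Preset-specific keywords (``s``, ``ratio``, ``phase_sd``, ``amp_sd``,
    ``amplitude0``, ``n0`` where applicable) are consumed by the preset;
    remaining keywords must be :class:`SimConfig` fields, or
    ``species<i>_<field>`` to override one species' configuration.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(PRESETS)}")
    builder = PRESETS[name]
    import inspect

    sig = inspect.signature(builder)
    preset_kw = {k: overrides.pop(k) for k in list(overrides)
                 if k in sig.parameters and k != "p"}
    sim_kw = {k: overrides.pop(k) for k in list(overrides)
              if k in SimConfig.__dataclass_fields__ and k != "species"}
    cfg = builder(**preset_kw, **sim_kw)
    for key, value in overrides.items():
        if key.startswith("species") and "_" in key:
            idx_str, _, fld = key[len("species"):].partition("_")
            try:
                idx = int(idx_str)
            except ValueError:
                raise ValueError(f"bad species override {key!r}") from None
            if idx >= len(cfg.species) or fld not in SpeciesConfig.__dataclass_fields__:
                raise ValueError(f"bad species override {key!r}")
            cfg.species[idx] = replace(cfg.species[idx], **{fld: value})
        else:
            raise ValueError(f"unknown override {key!r}")
    cfg.__post_init__()  # re-validate after overrides
    return cfg


def _day_rows(world: engine.World, cfg: SimConfig, day: int,
              cgm_value, res_bins: np.ndarray) -> list[dict]:
    rows = []
    for si in range(cfg.n_species):
        mask = world.species == si
        p = int(mask.sum())
        row = {
            "day": day,
            "species": si,
            "population": p,
            "mean_amplitude": float(world.amplitude[mask].mean()) if p else np.nan,
            "phase_mean": rhythm.circular_mean(world.phase[mask]) if p else np.nan,
            "phase_sd": metrics.circular_sd(world.phase[mask]) if p >= 2 else np.nan,
            "cgm": np.nan if cgm_value is None else float(cgm_value),
        }
        for b in range(cfg.steps_per_day):
            row[f"res_bin_{b}"] = int(res_bins[b])
        rows.append(row)
    return rows


def run_trial(config: SimConfig, seed: int, stop_after=None,
              record_organisms: bool = False,
              speciation_threshold: float = 0.1) -> metrics.TrialRecord:
    """Run one trial of ``config`` for its horizon; deterministic in
    (config, seed).

    Two independent RNG streams are derived from ``seed``: one drives the
    dynamics, one the recording layer (k-means initialisation inside the
    daily CGM), so observation cadence cannot perturb the trajectory.

    ``stop_after`` ends the trial early once its outcome is decided:
    ``"exclusion"`` (a species' population reached 0), ``"speciation"``
    (daily CGM fell below ``speciation_threshold``), or a callable
    receiving the day's rows and returning True.  The CGM is computed once
    per day, on the full living population, in assortative scenarios only.
    """
    ss = np.random.SeedSequence(seed)
    dyn_ss, met_ss = ss.spawn(2)
    rng = np.random.default_rng(dyn_ss)
    metrics_rng = np.random.default_rng(met_ss)

    world = engine.init_world(config, rng)
    birth_credit = np.zeros(config.n_species)
    exclusion_day = {str(si): None for si in range(config.n_species)}
    speciation_day = None

    def observe(day, res_bins):
        nonlocal speciation_day
        cgm_value = None
        if config.assortative and world.n_alive >= 2:
            cgm_value = metrics.cgm(world.phase, metrics_rng,
                                    width=config.window_width)
        rows = _day_rows(world, config, day, cgm_value, res_bins)
        for row in rows:
            if row["population"] == 0 and exclusion_day[str(row["species"])] is None:
                exclusion_day[str(row["species"])] = day
        if (speciation_day is None and cgm_value is not None
                and cgm_value < speciation_threshold):
            speciation_day = day
        return rows

    all_rows = observe(0, np.zeros(config.steps_per_day, dtype=np.int64))
    last_day = 0
    for day in range(1, config.horizon_days + 1):
        res_bins = np.zeros(config.steps_per_day, dtype=np.int64)
        for s in range(config.steps_per_day):
            engine.step(world, config, rng, birth_credit)
            res_bins[s] = int(world.grid.sum())
        rows = observe(day, res_bins)
        all_rows.extend(rows)
        last_day = day
        if stop_after == "exclusion":
            if any(v is not None for v in exclusion_day.values()):
                break
        elif stop_after == "speciation":
            if speciation_day is not None:
                break
        elif callable(stop_after):
            if stop_after(rows):
                break

    organisms = None
    if record_organisms:
        org_rows = []
        for si in range(config.n_species):
            mask = world.species == si
            if not mask.any():
                continue
            mu = rhythm.circular_mean(world.phase[mask])
            rel = (world.phase[mask] - mu + 180.0) % 360.0 - 180.0
            for r_, e_ in zip(rel, world.energy[mask]):
                org_rows.append({"species": si, "rel_phase": float(r_),
                                 "energy": float(e_)})
        organisms = pd.DataFrame(org_rows)

    events = {
        "exclusion_day": exclusion_day,
        "speciation_day": speciation_day,
        "last_day": last_day,
        "horizon_reached": last_day == config.horizon_days,
    }
    return metrics.TrialRecord(df=pd.DataFrame(all_rows), events=events,
                               config=config.to_dict(), seed=int(seed),
                               organisms=organisms)


def summarize_trial(record: metrics.TrialRecord) -> dict:
    """Flat per-trial summary row used by batch aggregation."""
    df = record.df
    n_species = df["species"].nunique()
    events = record.events
    exclusion_days = [v for v in events["exclusion_day"].values() if v is not None]
    last = df[df["day"] == df["day"].max()]
    out = {
        "seed": record.seed,
        "last_day": events["last_day"],
        "horizon_reached": events["horizon_reached"],
        "excluded": len(exclusion_days) > 0,
        "exclusion_day": min(exclusion_days) if exclusion_days else np.nan,
        "all_surviving": bool((last["population"] > 0).all()),
        "speciated": events["speciation_day"] is not None,
        "speciation_day": (np.nan if events["speciation_day"] is None
                           else events["speciation_day"]),
    }
    tail_start = df["day"].max() - EQUILIBRIUM_WINDOW
    tail = df[df["day"] > tail_start]
    for si in range(n_species):
        sp_last = last[last["species"] == si]
        sp_tail = tail[tail["species"] == si]
        out[f"final_population_s{si}"] = int(sp_last["population"].iloc[0])
        amps = sp_tail["mean_amplitude"].dropna()
        out[f"eq_amplitude_s{si}"] = float(amps.mean()) if len(amps) else np.nan
    if n_species == 2:
        a = tail[tail["species"] == 0].set_index("day")["phase_mean"]
        b = tail[tail["species"] == 1].set_index("day")["phase_mean"]
        d = (np.abs(a - b) % 360.0).dropna()
        out["eq_phase_difference"] = (
            float(np.minimum(d, 360.0 - d).mean()) if len(d) else np.nan
        )
    return out


@dataclass
class BatchSummary:
    """Aggregates over independent trials of one scenario."""

    trials: pd.DataFrame
    aggregates: dict
    records: list | None = None

    def write(self, out_dir, stem: str = "batch") -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        self.trials.to_csv(csv_path, index=False, float_format="%.17g")
        json_path = out_dir / f"{stem}.json"
        json_path.write_text(json.dumps(self.aggregates, indent=2, default=float))
        return {"csv": csv_path, "json": json_path}


def run_batch(config: SimConfig, n_trials: int, base_seed: int,
              n_workers: int = 1, stop_after=None,
              keep_records: bool = False, progress: bool = False) -> BatchSummary:
    """Run ``n_trials`` independent trials with seeds base_seed + 0..n-1.

    Results are deterministic and independent of ``n_workers`` because
    every trial is seeded individually.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    seeds = [base_seed + i for i in range(n_trials)]
    if n_workers > 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_workers)(
            delayed(run_trial)(config, s, stop_after=stop_after) for s in seeds
        )
    else:
        records = []
        it = seeds
        if progress:
            import click

            it = click.progressbar(seeds, label="trials")
        if progress:
            with it as bar:
                for s in bar:
                    records.append(run_trial(config, s, stop_after=stop_after))
        else:
            for s in it:
                records.append(run_trial(config, s, stop_after=stop_after))
    trials = pd.DataFrame([summarize_trial(r) for r in records])

    def _median(col):  # median of the trials that reached the event
        vals = trials[col].dropna()
        return float(vals.median()) if len(vals) else float("nan")

    aggregates = {
        "n_trials": n_trials,
        "base_seed": int(base_seed),
        "config_hash": metrics.config_hash(config.to_dict()),
        "fraction_excluded": float(trials["excluded"].mean()),
        "fraction_all_surviving": float(trials["all_surviving"].mean()),
        "fraction_speciated": float(trials["speciated"].mean()),
        "median_exclusion_day": _median("exclusion_day"),
        "median_speciation_day": _median("speciation_day"),
    }
    return BatchSummary(trials=trials, aggregates=aggregates,
                        records=records if keep_records else None)


def table1_sweep(trials_per_cell: int = 20, base_seed: int = 0,
                 phase_sds=(0.04, 0.045, 0.05, 0.055),
                 amp_sds=(0.02, 0.03, 0.04, 0.05),
                 horizon_days: int = _HORIZON, n_workers: int = 1,
                 progress: bool = False) -> pd.DataFrame:
    """Grid of speciation counts over phase/amplitude mutation SDs.

    Returns a frame indexed by phase SD with one column per amplitude SD;
    each cell is the number of trials (out of ``trials_per_cell``) whose
    CGM fell below 0.1 within the horizon.
    """
    table = {}
    for amp_sd in amp_sds:
        col = []
        for i, phase_sd in enumerate(phase_sds):
            cfg = build_scenario("speciation", phase_sd=phase_sd,
                                 amp_sd=amp_sd, horizon_days=horizon_days)
            cell_seed = base_seed + 10_000 * len(table) + 1_000 * i
            batch = run_batch(cfg, trials_per_cell, cell_seed,
                              n_workers=n_workers, stop_after="speciation",
                              progress=progress)
            col.append(int(batch.trials["speciated"].sum()))
        table[amp_sd] = col
    return pd.DataFrame(table, index=pd.Index(list(phase_sds), name="phase_sd"))


def generate_fixture_population(n: int, phase_spec, amplitude_spec,
                                seed: int) -> list[Organism]:
    """Synthetic population with a requested phase/amplitude structure.

    ``phase_spec`` / ``amplitude_spec`` are either a scalar (a point mass)
    or a list of mixture components, each a dict with keys ``kind``
    ("point" or "normal"; phase normals are wrapped to [0, 360)), ``loc``,
    ``scale`` (for normals) and optional ``weight``.  Energies are drawn
    Gamma(shape=2, scale=1) — positive with a long right tail, loosely
    resembling the stationary stored-energy distribution.
    """
    rng = np.random.default_rng(seed)

    def draw(spec, wrap):
        if np.isscalar(spec):
            vals = np.full(n, float(spec))
        else:
            weights = np.array([c.get("weight", 1.0) for c in spec], float)
            comp = rng.choice(len(spec), size=n, p=weights / weights.sum())
            vals = np.empty(n)
            for ci, c in enumerate(spec):
                m = comp == ci
                if c["kind"] == "point":
                    vals[m] = c["loc"]
                elif c["kind"] == "normal":
                    vals[m] = rng.normal(c["loc"], c["scale"], m.sum())
                else:
                    raise ValueError(f"unknown component kind {c['kind']!r}")
        if wrap:
            return vals % 360.0
        return np.clip(vals, 0.0, 1.0)

    phases = draw(phase_spec, wrap=True)
    amplitudes = draw(amplitude_spec, wrap=False)
    energies = rng.gamma(shape=2.0, scale=1.0, size=n)
    return [
        Organism(id=i, species=0,
                 rhythm=rhythm.RhythmParams(amplitudes[i], phases[i]),
                 energy=float(energies[i]))
        for i in range(n)
    ]


def write_outputs(obj, out_dir, stem: str | None = None) -> dict:
    """Write a TrialRecord or BatchSummary to ``out_dir`` (CSV + JSON)."""
    if isinstance(obj, metrics.TrialRecord):
        return obj.write(out_dir, stem or "trial")
    if isinstance(obj, BatchSummary):
        return obj.write(out_dir, stem or "batch")
    raise TypeError(f"cannot write object of type {type(obj).__name__}")
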