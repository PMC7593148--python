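"""Tests of scenario presets, trial/batch runners, fixture generation
and output round-trips."""

import numpy as np
import pytest

from chronoecol import (
    build_scenario,
    cgm,
    generate_fixture_population,
    run_batch,
    run_trial,
)
from chronoecol.metrics import TrialRecord, config_hash
from chronoecol.scenarios import PRESETS, summarize_trial


class TestBuildScenario:
    def test_coexist_antiphase_fields(self):
        cfg = build_scenario("coexist_antiphase")
        assert [sp.amplitude0 for sp in cfg.species] == [1.0, 1.0]
        assert [sp.phase0 for sp in cfg.species] == [0.0, 180.0]
        assert all(sp.amp_sd == 0 and sp.phase_sd_frac == 0 for sp in cfg.species)
        assert not cfg.stabilize
        assert cfg.horizon_days == 2000

    def test_speciation_fields(self):
        cfg = build_scenario("speciation", phase_sd=0.05, amp_sd=0.02)
        assert cfg.assortative
        assert cfg.window_width == 135.0
        (sp,) = cfg.species
        assert sp.phase_sd_frac == 0.05
        assert sp.amp_sd == 0.02
        assert sp.amplitude0 == 1.0

    def test_two_species_ratio(self):
        cfg = build_scenario("two_species", ratio=(9, 1))
        assert [sp.k for sp in cfg.species] == [0.9, 0.1]
        assert cfg.stabilize

    def test_character_displacement_fields(self):
        cfg = build_scenario("character_displacement")
        assert all(sp.amplitude0 == 1.0 and sp.amp_sd == 0.0 for sp in cfg.species)
        assert all(sp.phase0 == 0.0 for sp in cfg.species)
        assert all(sp.phase_sd_frac == 0.04 for sp in cfg.species)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("nonsense")

    def test_overrides(self):
        cfg = build_scenario("single_species", s=0.75, horizon_days=100,
                             species0_n0=42)
        assert cfg.species[0].s == 0.75
        assert cfg.horizon_days == 100
        assert cfg.species[0].n0 == 42

    def test_bad_override_rejected(self):
        with pytest.raises(ValueError):
            build_scenario("single_species", bogus_field=1)
        with pytest.raises(ValueError):
            build_scenario("single_species", species9_n0=5)

    def test_every_preset_builds(self):
        for name in PRESETS:
            cfg = build_scenario(name)
            assert cfg.horizon_days == 2000


class TestRunTrial:
    def test_deterministic_given_config_and_seed(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=20)
        r1 = run_trial(cfg, seed=5)
        r2 = run_trial(cfg, seed=5)
        assert r1.df.equals(r2.df)
        assert r1.events == r2.events

    def test_one_row_per_day_per_species(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=15)
        rec = run_trial(cfg, seed=1)
        assert len(rec.df) == 16 * 2
        assert sorted(rec.df["day"].unique()) == list(range(16))

    def test_stop_after_exclusion(self):
        cfg = build_scenario("exclusion_arrhythmic")
        rec = run_trial(cfg, seed=0, stop_after="exclusion")
        days = [v for v in rec.events["exclusion_day"].values() if v is not None]
        assert days and rec.events["last_day"] == min(days)
        assert not rec.events["horizon_reached"]

    def test_stop_after_callable(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=50)
        rec = run_trial(cfg, seed=1, stop_after=lambda rows: rows[0]["day"] >= 7)
        assert rec.events["last_day"] == 7


class TestRunBatch:
    def test_single_trial_batch_equals_trial(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=10)
        batch = run_batch(cfg, n_trials=1, base_seed=3)
        trial = summarize_trial(run_trial(cfg, 3))
        row = batch.trials.iloc[0].to_dict()
        for key, val in trial.items():
            assert row[key] == val or (np.isnan(val) and np.isnan(row[key]))
        assert batch.aggregates["n_trials"] == 1

    def test_worker_count_does_not_change_results(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=10)
        b1 = run_batch(cfg, n_trials=3, base_seed=0, n_workers=1)
        b2 = run_batch(cfg, n_trials=3, base_seed=0, n_workers=2)
        assert b1.trials.equals(b2.trials)

    def test_rejects_empty_batch(self):
        cfg = build_scenario("coexist_antiphase", horizon_days=10)
        with pytest.raises(ValueError):
            run_batch(cfg, n_trials=0, base_seed=0)


class TestFixturePopulation:
    def test_antiphase_point_masses_feed_cgm_zero(self, rng):
        pop = generate_fixture_population(
            20,
            [{"kind": "point", "loc": 0.0}, {"kind": "point", "loc": 180.0}],
            1.0,
            seed=1,
        )
        phases = [o.rhythm.phase for o in pop]
        assert cgm(phases, rng) == pytest.approx(0.0)

    def test_single_point_mass_feeds_cgm_one(self, rng):
        pop = generate_fixture_population(15, 90.0, 0.5, seed=2)
        assert cgm([o.rhythm.phase for o in pop], rng) == pytest.approx(1.0)

    def test_reproducible_and_positive_energies(self):
        spec = [{"kind": "normal", "loc": 0.0, "scale": 10.0},
                {"kind": "normal", "loc": 160.0, "scale": 10.0}]
        p1 = generate_fixture_population(12, spec, 1.0, seed=9)
        p2 = generate_fixture_population(12, spec, 1.0, seed=9)
        assert [o.rhythm.phase for o in p1] == [o.rhythm.phase for o in p2]
        assert all(o.energy > 0 for o in p1)
        assert all(0 <= o.rhythm.phase < 360 for o in p1)


class TestOutputs:
    def test_trial_round_trip_bit_exact(self, tmp_path):
        cfg = build_scenario("speciation", horizon_days=5)
        rec = run_trial(cfg, seed=2, record_organisms=True)
        rec.write(tmp_path, stem="t")
        back = TrialRecord.read(tmp_path, stem="t")
        assert back.df.equals(rec.df)
        assert back.events == rec.events
        assert back.seed == rec.seed
        assert back.config_hash == rec.config_hash
        assert back.organisms.equals(rec.organisms)

    def test_config_hash_changes_iff_config_changes(self):
        c1 = build_scenario("coexist_antiphase")
        c2 = build_scenario("coexist_antiphase")
        c3 = build_scenario("coexist_antiphase", horizon_days=1999)
        assert config_hash(c1.to_dict()) == config_hash(c2.to_dict())
        assert config_hash(c1.to_dict()) != config_hash(c3.to_dict())

    def test_batch_outputs(self, tmp_path):
        cfg = build_scenario("coexist_antiphase", horizon_days=5)
        batch = run_batch(cfg, n_trials=3, base_seed=0)
        paths = batch.write(tmp_path)
        import pandas as pd

        written = pd.read_csv(paths["csv"])
        assert len(written) == 3


class TestResourceProfiles:
    def test_shared_phase_carves_trough_antiphase_flattens(self):
        """Temporally aligned competitors deplete their common peak hours;
        antiphase competitors flatten the daily resource profile."""
        from chronoecol.metrics import resource_time_histogram

        inphase = build_scenario("exclusion_inphase", horizon_days=25)
        anti = build_scenario("coexist_antiphase", horizon_days=25)
        spans = {}
        for name, cfg in (("inphase", inphase), ("anti", anti)):
            rec = run_trial(cfg, seed=4)
            hist = resource_time_histogram(rec).loc[15:].mean(axis=0)
            spans[name] = (hist.max() - hist.min()) / hist.mean()
        assert spans["inphase"] > 2 * spans["anti"]
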