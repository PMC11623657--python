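"""Behavioral tests of the GC->PC simulation engine."""

import io

import numpy as np
import pandas as pd
import pytest

from pcmat import ScheduledIntervention, SimulationConfig, run_simulation
from pcmat.config import (
    ANTI_CD40L,
    ConfigError,
    DEC_OVA,
    DOXYCYCLINE,
    TACI_IG,
    TAMOXIFEN_S1PR2,
)
from pcmat.io import FLOAT_FORMAT
from pcmat.simulate import Simulation


def _tsv_bytes(df: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return buf.getvalue().encode()


class TestBasics:
    def test_zero_horizon_keeps_founders(self):
        cfg = SimulationConfig(seed=1, horizon_steps=0, snapshot_steps=(0,))
        out = run_simulation(cfg)
        assert len(out.cells) == cfg.n_founders
        assert set(out.cells.compartment) == {"GC_LZ"}
        assert (out.cells.total_divisions == 0).all()

    def test_invalid_config_lists_all_violations(self):
        cfg = SimulationConfig(mutation_rate=2.0, capture_K=-1.0, pc_death_rate=5.0)
        with pytest.raises(ConfigError) as err:
            run_simulation(cfg)
        msg = str(err.value)
        assert "mutation_rate" in msg and "capture_K" in msg and "pc_death_rate" in msg

    def test_forced_export(self, quiet_config):
        cfg = quiet_config.replace(pc_export_prob=1.0)
        sim = Simulation(cfg)
        sim.step_once()
        prepc = [c for c in sim.state.cells if c.compartment == "PREPC"]
        assert len(prepc) == 1

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=42, horizon_steps=12, snapshot_steps=(12,))
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert _tsv_bytes(a.repertoire) == _tsv_bytes(b.repertoire)
        assert _tsv_bytes(a.serum_df) == _tsv_bytes(b.serum_df)
        assert _tsv_bytes(a.event_log) == _tsv_bytes(b.event_log)

    def test_different_seeds_differ(self):
        a = run_simulation(SimulationConfig(seed=1, horizon_steps=12))
        b = run_simulation(SimulationConfig(seed=2, horizon_steps=12))
        assert _tsv_bytes(a.repertoire) != _tsv_bytes(b.repertoire)


class TestConservationAndLabels:
    def test_cell_conservation(self):
        cfg = SimulationConfig(seed=3, horizon_steps=16)
        sim = Simulation(cfg)
        for _ in range(cfg.horizon_steps):
            sim.step_once()
            st = sim.state
            n_tracked = len(st.cells) + st.n_dead
            assert n_tracked == st.n_created
            ev = st.event_log[-1]
            assert ev["n_live"] + ev["n_dying"] + ev["n_dead"] == st.n_created

    def test_zsg_label_inherited_by_all_descendants(self):
        # label every founder at step 0 with no later influx: every cell
        # in the node must stay labeled forever
        cfg = SimulationConfig(
            seed=4,
            founder_influx_rate=0.0,
            horizon_steps=16,
            snapshot_steps=(8, 16),
            interventions=(ScheduledIntervention(TAMOXIFEN_S1PR2, 0),),
        )
        out = run_simulation(cfg)
        assert out.cells.zsg.all()

    def test_blimp1_labels_only_pcs(self):
        cfg = SimulationConfig(
            seed=5,
            horizon_steps=20,
            snapshot_steps=(20,),
            interventions=(ScheduledIntervention("TAMOXIFEN_BLIMP1", 14),),
        )
        out = run_simulation(cfg)
        gc = out.cells[out.cells.celltype == "GC"]
        assert not gc.zsg.any()
        pcs = out.cells[out.cells.celltype == "PC"]
        assert pcs.zsg.any()

    def test_mcherry_exact_halving_without_noise(self):
        cfg = SimulationConfig(
            seed=6,
            label_noise_sigma=0.0,
            horizon_steps=24,
            snapshot_steps=(24,),
            interventions=(ScheduledIntervention(DOXYCYCLINE, 12),),
        )
        out = run_simulation(cfg)
        f0 = cfg.mcherry_f0
        expected = f0 * np.power(0.5, out.cells.divisions_since_label)
        assert np.allclose(out.cells.mcherry, expected)
        assert np.allclose(out.cells.mcherry_true, expected)

    def test_mcherry_constant_without_doxycycline(self):
        cfg = SimulationConfig(seed=7, label_noise_sigma=0.0, horizon_steps=12)
        out = run_simulation(cfg)
        assert np.allclose(out.cells.mcherry, cfg.mcherry_f0)
        assert (out.cells.divisions_since_label == 0).all()


class TestDivisionArithmetic:
    def test_single_export_expands_two_to_the_budget(self, quiet_config):
        # one cell exported with a deterministic budget of 3 -> 8 PCs
        cfg = quiet_config.replace(
            pc_export_prob=1.0,
            myc_k=0.0,
            myc_m0=1.0,
            division_beta=3.0,
            il21_scale=1.0,
            horizon_steps=6,
            snapshot_steps=(6,),
        )
        out = run_simulation(cfg)
        pcs = out.cells[out.cells.celltype == "PC"]
        assert len(pcs) == 8
        assert (pcs.budget == 0).all()

    def test_coupled_run_divides_more_than_null(self):
        base = SimulationConfig(seed=8, horizon_steps=24, snapshot_steps=(24,))
        coupled = run_simulation(base)
        null = run_simulation(base.replace(myc_k=0.0))

        def mean_pc_div(out):
            pc = out.cells[(out.cells.celltype == "PC") & (out.cells.state == "LIVE")]
            return pc.total_divisions.mean()

        assert mean_pc_div(coupled) > mean_pc_div(null)


class TestInterventions:
    def test_anti_cd40l_ablates_gc(self):
        cfg = SimulationConfig(
            seed=9,
            horizon_steps=32,
            interventions=(ScheduledIntervention(ANTI_CD40L, 20, delay_steps=4),),
        )
        out = run_simulation(cfg)
        ev = out.event_log
        before = ev[ev.step <= 20]
        assert (before.n_gc_lz + before.n_gc_dz).iloc[-1] > 0
        after = ev[ev.step >= 24]  # two days after treatment
        assert ((after.n_gc_lz + after.n_gc_dz) == 0).all()
        assert (after.n_prepc == 0).all()

    def test_taci_ig_depletes_live_pcs_within_two_steps(self):
        cfg = SimulationConfig(
            seed=10,
            horizon_steps=24,
            interventions=(ScheduledIntervention(TACI_IG, 20),),
        )
        out = run_simulation(cfg)
        ev = out.event_log
        assert ev.loc[ev.step == 19, "n_pc"].iloc[0] > 0
        assert (ev.loc[ev.step >= 21, "n_pc"] == 0).all()

    def test_dec_zero_dose_gives_baseline_myc(self):
        cfg = SimulationConfig(
            seed=11,
            horizon_steps=16,
            snapshot_steps=(16,),
            dec_wt_fraction=0.5,
            interventions=(ScheduledIntervention(DEC_OVA, 10, dose_fraction=0.0),),
        )
        out = run_simulation(cfg)
        used = out.cells[out.cells.dec_override_used & out.cells.dec_targetable]
        assert len(used) > 0
        assert np.allclose(used.dec_myc, cfg.myc_m0)

    def test_serum_frozen_after_taci(self):
        cfg = SimulationConfig(
            seed=12,
            horizon_steps=30,
            interventions=(ScheduledIntervention(TACI_IG, 20),),
        )
        out = run_simulation(cfg)
        totals = out.serum_df.groupby("timepoint").concentration.sum()
        assert totals.loc[30] == pytest.approx(totals.loc[22])


class TestSerumAccounting:
    def test_kd_is_kd0_over_affinity(self, default_run):
        df = default_run.serum_df
        assert (df.kd > 0).all()
        # species from the high-affinity analog carry sub-unit kd
        assert df.kd.min() < default_run.config.kd0

    def test_no_pcs_no_serum(self, quiet_config):
        cfg = quiet_config.replace(horizon_steps=4, snapshot_steps=(4,))
        out = run_simulation(cfg)
        assert out.serum_df.empty or (out.serum_df.concentration == 0).all()

    def test_secretion_additive_per_live_pc(self, quiet_config):
        # one export, budget 1 -> 2 identical PCs secreting 2*rate per step
        cfg = quiet_config.replace(
            pc_export_prob=1.0,
            myc_k=0.0,
            myc_m0=1.0,
            division_beta=1.0,
            il21_scale=1.0,
            horizon_steps=4,
        )
        out = run_simulation(cfg)
        totals = out.serum_df.groupby("timepoint").concentration.sum()
        # maturation at step 2, division at step 2 (budget 1): 2 PCs secrete
        # from step 2 onward
        assert totals.loc[3] - totals.loc[2] == pytest.approx(2 * cfg.secretion_rate)
        species = out.serum[-1].species
        assert len(species) == 1  # identical clone+affinity aggregates


class TestExportPermissiveness:
    def test_export_log_matches_lz_pool(self, default_run):
        el = default_run.export_log
        assert len(el) > 50
        pooled_export = el.affinity.mean()
        pooled_lz = el.lz_mean_affinity.mean()
        # single run: generous band; the 20-seed acceptance check is tighter
        assert pooled_export / pooled_lz == pytest.approx(1.0, abs=0.25)
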