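"""Agent-based, discrete-time simulator of the GC-to-plasma-cell response.

One step is half a simulated day by default.  Each step runs, in order:
prePC maturation; light-zone (LZ) competition for T-cell help; dark-zone
(DZ) division with somatic hypermutation; affinity-independent export of LZ
cells to the prePC pool (each exported cell records the help it last
received, which fixes its division budget); inertial PC division without
further mutation; death; antibody secretion.  Interventions (anti-CD40L,
TACI-Ig, tamoxifen fate-labeling, doxycycline label shut-off, FTY720,
DEC205-targeted antigen) modify these phases on schedule.

The model's central asymmetry: *who* leaves the GC is affinity-independent
(permissive export), but *how much* each emigrant subsequently divides is
proportional to the help it captured, so the PC pool becomes enriched for
high-affinity cells by differential division alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ANTI_CD40L,
    DEC_OVA,
    DOXYCYCLINE,
    FTY720,
    TACI_IG,
    TAMOXIFEN_BLIMP1,
    TAMOXIFEN_S1PR2,
    SimulationConfig,
)
from .germline import HEAVY_J, LIGHT_J, AMINO_ACIDS, germline_of
from .model import LETHAL, antigen_capture, division_budget, mutate_chains, myc_level

# compartments
GC_LZ = "GC_LZ"
GC_DZ = "GC_DZ"
PREPC = "PREPC"
PC = "PC"
EGRESSED = "EGRESSED"

# live states
LIVE = "LIVE"
DYING = "DYING"
DEAD = "DEAD"

_CELLTYPE = {GC_LZ: "GC", GC_DZ: "GC", PREPC: "PREPC", PC: "PC", EGRESSED: "PC"}


class Cell:
    """One B-lineage cell. Mutable; mutated in place as it divides."""

    __slots__ = (
        "cell_id",
        "clone_id",
        "compartment",
        "v_call_h",
        "j_call_h",
        "v_call_l",
        "j_call_l",
        "heavy_seq",
        "light_seq",
        "junction_h",
        "junction_l",
        "affinity",
        "captured",
        "myc",
        "budget",
        "divisions_since_label",
        "total_divisions",
        "zsg",
        "mcherry",
        "state",
        "last_division_step",
        "dec_targetable",
        "pending_capture",
        "dec_override_used",
        "dec_myc",
        "dec_used_at",
        "prepc_since",
        "events",
    )

    def __init__(self, **kw):
        for k in self.__slots__:
            setattr(self, k, kw[k])


@dataclass
class SerumSample:
    """Cumulative serum antibody mixture at one timepoint."""

    timepoint: int
    species: list[tuple[float, float, int]]  # (concentration, kd, clone_id)


@dataclass
class SimState:
    cells: list[Cell] = field(default_factory=list)
    step: int = 0
    serum: dict[tuple[int, float], float] = field(default_factory=dict)
    serum_series: list[SerumSample] = field(default_factory=list)
    export_log: list[tuple[int, float, float]] = field(default_factory=list)
    event_log: list[dict] = field(default_factory=list)
    snapshot_rows: list[dict] = field(default_factory=list)
    mutation_log: dict[str, tuple] = field(default_factory=dict)
    n_created: int = 0
    n_dead: int = 0


@dataclass
class SimulationOutput:
    """Everything a simulation produces, as analysis-ready tables."""

    config: SimulationConfig
    animal: str
    cells: pd.DataFrame
    repertoire: pd.DataFrame
    serum: list[SerumSample]
    serum_df: pd.DataFrame
    export_log: pd.DataFrame
    event_log: pd.DataFrame
    mutation_log: dict[str, tuple]


class Simulation:
    """Stateful simulator; ``run_simulation`` is the one-shot wrapper."""

    def __init__(self, config: SimulationConfig, animal: str = "m1"):
        config.require_valid()
        self.config = config
        self.animal = animal
        seed = config.seed
        self.rng_founders = np.random.default_rng([seed, 1])
        self.rng_selection = np.random.default_rng([seed, 2])
        self.rng_budget = np.random.default_rng([seed, 3])
        self.rng_mutation = np.random.default_rng([seed, 4])
        self.rng_export = np.random.default_rng([seed, 5])
        self.rng_death = np.random.default_rng([seed, 6])
        self.rng_measure = np.random.default_rng([seed, 7])
        self.state = SimState()
        self._n_clones = 0
        self._founders()

    # -- intervention queries ------------------------------------------------

    def _active(self, kind: str, t: int) -> bool:
        return any(
            iv.kind == kind and iv.start_step <= t for iv in self.config.interventions
        )

    def _starting(self, kind: str, t: int):
        return [
            iv
            for iv in self.config.interventions
            if iv.kind == kind and iv.start_step == t
        ]

    def _cd40l_blocked(self, t: int) -> bool:
        return self._active(ANTI_CD40L, t)

    def _cd40l_lethal(self, t: int) -> bool:
        # GC death completes delay_steps after treatment: the state recorded
        # at step start+delay (end of step index start+delay-1) has no GC
        return any(
            iv.kind == ANTI_CD40L and t + 1 >= iv.start_step + iv.delay_steps
            for iv in self.config.interventions
        )

    def _egress_rate(self, t: int) -> float:
        if self._active(FTY720, t):
            return 0.0
        return self.config.pc_egress_rate

    # -- construction --------------------------------------------------------

    def _founders(self) -> None:
        for _ in range(self.config.n_founders):
            self._new_founder()

    def _new_founder(self) -> None:
        cfg = self.config
        rng = self.rng_founders
        v_names = list(cfg.v_gene_pool)
        v_probs = np.array([cfg.v_gene_pool[v] for v in v_names], dtype=float)
        v_probs = v_probs / v_probs.sum()
        l_names = list(cfg.light_v_pool)
        l_probs = np.array([cfg.light_v_pool[v] for v in l_names], dtype=float)
        l_probs = l_probs / l_probs.sum()
        if True:
            clone = self._n_clones
            self._n_clones += 1
            v_h = v_names[int(rng.choice(len(v_names), p=v_probs))]
            v_l = l_names[int(rng.choice(len(l_names), p=l_probs))]
            j_h = HEAVY_J[int(rng.integers(len(HEAVY_J)))]
            j_l = LIGHT_J[int(rng.integers(len(LIGHT_J)))]
            jlen_h = int(rng.integers(10, 15))
            jlen_l = int(rng.integers(9, 12))
            junc_h = "".join(
                AMINO_ACIDS[int(i)] for i in rng.integers(len(AMINO_ACIDS), size=jlen_h)
            )
            junc_l = "".join(
                AMINO_ACIDS[int(i)] for i in rng.integers(len(AMINO_ACIDS), size=jlen_l)
            )
            aff = cfg.baseline_affinity[v_h]
            if cfg.founder_affinity_sigma > 0:
                aff *= float(
                    np.exp(rng.normal(0.0, cfg.founder_affinity_sigma))
                )
            dec_wt = bool(rng.random() < cfg.dec_wt_fraction)
            f0 = cfg.mcherry_f0
            if cfg.label_noise_sigma > 0:
                f0 *= float(np.exp(rng.normal(0.0, cfg.label_noise_sigma)))
            self._new_cell(
                clone_id=clone,
                compartment=GC_LZ,
                v_call_h=v_h,
                j_call_h=j_h,
                v_call_l=v_l,
                j_call_l=j_l,
                heavy_seq=germline_of(v_h),
                light_seq=germline_of(v_l),
                junction_h=junc_h,
                junction_l=junc_l,
                affinity=aff,
                mcherry=f0,
                dec_targetable=dec_wt,
            )

    def _new_cell(self, **kw) -> Cell:
        st = self.state
        cell = Cell(
            cell_id=st.n_created,
            clone_id=kw["clone_id"],
            compartment=kw["compartment"],
            v_call_h=kw["v_call_h"],
            j_call_h=kw["j_call_h"],
            v_call_l=kw["v_call_l"],
            j_call_l=kw["j_call_l"],
            heavy_seq=kw["heavy_seq"],
            light_seq=kw["light_seq"],
            junction_h=kw["junction_h"],
            junction_l=kw["junction_l"],
            affinity=kw["affinity"],
            captured=kw.get("captured", 0.0),
            myc=kw.get("myc", 0.0),
            budget=kw.get("budget", 0),
            divisions_since_label=kw.get("divisions_since_label", 0),
            total_divisions=kw.get("total_divisions", 0),
            zsg=kw.get("zsg", False),
            mcherry=kw["mcherry"],
            state=LIVE,
            last_division_step=kw.get("last_division_step", -1),
            dec_targetable=kw["dec_targetable"],
            pending_capture=kw.get("pending_capture", None),
            dec_override_used=kw.get("dec_override_used", False),
            dec_myc=kw.get("dec_myc", float("nan")),
            dec_used_at=kw.get("dec_used_at", ""),
            prepc_since=kw.get("prepc_since", -1),
            events=kw.get("events", ()),
        )
        st.cells.append(cell)
        st.n_created += 1
        return cell

    # -- help assignment -----------------------------------------------------

    def _captured(self, cell: Cell) -> float:
        cfg = self.config
        if cell.pending_capture is not None:
            return cell.pending_capture
        return antigen_capture(cell.affinity, cfg.capture_cmax, cfg.capture_K)

    def _assign_help(self, cell: Cell, il21: float = 1.0, where: str = "selection") -> None:
        """Fix captured antigen, Myc and the division budget on one cell.

        ``il21`` scales the budget; it is 1 for dark-zone re-entry and
        ``il21_scale`` for GC export, because IL-21 from extrafollicular
        T-cell foci amplifies post-GC plasma-cell expansion specifically.
        A pending DEC205 antigen load overrides BCR capture for this one
        assignment; the Myc it induces is frozen in ``dec_myc`` for the
        dose-response readout.
        """
        cfg = self.config
        was_pending = cell.pending_capture is not None
        if was_pending:
            cell.dec_override_used = True
        cell.captured = self._captured(cell)
        cell.pending_capture = None  # DEC load is spent at first use
        cell.myc = myc_level(cell.captured, cfg.myc_m0, cfg.myc_k)
        if was_pending and not cell.dec_used_at:
            cell.dec_myc = cell.myc
            cell.dec_used_at = where
        cell.budget = division_budget(
            cell.myc,
            cfg.division_beta,
            il21,
            mode=cfg.budget_mode,
            rng=self.rng_budget,
            cap=cfg.budget_cap,
        )

    # -- division ------------------------------------------------------------

    def _divide(self, cell: Cell, t: int, mutate: bool, dox: bool) -> None:
        """One division: the parent becomes daughter A, daughter B is new."""
        cfg = self.config
        cell.budget -= 1
        cell.total_divisions += 1
        cell.last_division_step = t
        if dox:
            cell.divisions_since_label += 1
            cell.mcherry *= 0.5
        daughter = self._new_cell(
            clone_id=cell.clone_id,
            compartment=cell.compartment,
            v_call_h=cell.v_call_h,
            j_call_h=cell.j_call_h,
            v_call_l=cell.v_call_l,
            j_call_l=cell.j_call_l,
            heavy_seq=cell.heavy_seq,
            light_seq=cell.light_seq,
            junction_h=cell.junction_h,
            junction_l=cell.junction_l,
            affinity=cell.affinity,
            captured=cell.captured,
            myc=cell.myc,
            budget=cell.budget,
            divisions_since_label=cell.divisions_since_label,
            total_divisions=cell.total_divisions,
            zsg=cell.zsg,
            mcherry=cell.mcherry,
            last_division_step=t,
            dec_targetable=cell.dec_targetable,
            pending_capture=cell.pending_capture,
            dec_override_used=cell.dec_override_used,
            dec_myc=cell.dec_myc,
            dec_used_at=cell.dec_used_at,
            events=cell.events,
        )
        if mutate:
            for d in (cell, daughter):
                out = mutate_chains(
                    d.heavy_seq, d.light_seq, d.affinity, cfg, self.rng_mutation
                )
                d.heavy_seq = out.heavy_seq
                d.light_seq = out.light_seq
                d.affinity = out.affinity
                d.events = d.events + out.events
                if out.fate == LETHAL:
                    d.state = DEAD
        return daughter

    # -- one step ------------------------------------------------------------

    def step_once(self) -> None:
        cfg = self.config
        st = self.state
        t = st.step

        # phase 0: instantaneous interventions taking effect now
        for _ in self._starting(TAMOXIFEN_S1PR2, t):
            for c in st.cells:
                if c.state == LIVE and c.compartment in (GC_LZ, GC_DZ, PREPC):
                    c.zsg = True
        for _ in self._starting(TAMOXIFEN_BLIMP1, t):
            for c in st.cells:
                if c.state == LIVE and c.compartment == PC:
                    c.zsg = True
        for iv in self._starting(DEC_OVA, t):
            for c in st.cells:
                if (
                    c.state == LIVE
                    and c.compartment in (GC_LZ, GC_DZ)
                    and c.dec_targetable
                ):
                    c.pending_capture = iv.dose_fraction * cfg.capture_cmax

        dox = self._active(DOXYCYCLINE, t)
        blocked = self._cd40l_blocked(t)

        # ongoing GC diversification: naive founder influx (stops with
        # CD40L blockade, which also kills activated precursors)
        if cfg.founder_influx_rate > 0 and not blocked:
            for _ in range(int(self.rng_founders.poisson(cfg.founder_influx_rate))):
                self._new_founder()

        # phase 1: prePC maturation (one full step in the prePC state)
        for c in st.cells:
            if c.state == LIVE and c.compartment == PREPC and c.prepc_since < t:
                c.compartment = PC

        # phase 2: LZ competition for help
        if not blocked:
            lz = [c for c in st.cells if c.state == LIVE and c.compartment == GC_LZ]
            if lz:
                captured = np.array([self._captured(c) for c in lz])
                w = np.where(
                    captured > 0,
                    np.power(np.maximum(captured, 1e-300), cfg.selection_temperature),
                    0.0,
                )
                total = w.sum()
                if total > 0:
                    n_sel = cfg.selection_fraction * len(lz)
                    p = np.minimum(1.0, n_sel * w / total)
                    draws = self.rng_selection.random(len(lz))
                    for c, pi, u in zip(lz, p, draws):
                        if u < pi:
                            self._assign_help(c)
                            c.compartment = GC_DZ

        # phase 3: DZ burst division (blocked GCs stop cycling).  DZ
        # inter-division time is short relative to the step, so a selected
        # cell spends its whole budget within the step and returns to the
        # LZ on the next one; the LZ census therefore tracks the GC census.
        if not blocked:
            for c in list(st.cells):
                if c.state == LIVE and c.compartment == GC_DZ:
                    if c.budget > 0:
                        queue = [c]
                        while queue:
                            x = queue.pop()
                            while x.state == LIVE and x.budget > 0:
                                d = self._divide(x, t, mutate=True, dox=dox)
                                if d.state == LIVE and d.budget > 0:
                                    queue.append(d)
                    else:
                        c.compartment = GC_LZ

        # phase 4: affinity-independent export to the prePC pool
        if not blocked:
            lz = [c for c in st.cells if c.state == LIVE and c.compartment == GC_LZ]
            if lz and cfg.pc_export_prob > 0:
                lz_mean = float(np.mean([c.affinity for c in lz]))
                draws = self.rng_export.random(len(lz))
                for c, u in zip(lz, draws):
                    if u < cfg.pc_export_prob:
                        # historic help signal is fixed at export
                        self._assign_help(c, il21=cfg.il21_scale, where="export")
                        c.compartment = PREPC
                        c.prepc_since = t
                        st.export_log.append(
                            (t, c.affinity, lz_mean, c.budget, c.v_call_h, c.heavy_seq)
                        )

        # phase 5: inertial PC division, no further mutation
        for c in list(st.cells):
            if c.state == LIVE and c.compartment == PC and c.budget > 0:
                self._divide(c, t, mutate=False, dox=dox)

        # phase 6: death
        for c in st.cells:
            if c.state == DYING:
                c.state = DEAD
        taci = self._active(TACI_IG, t)
        cd40l_kill = self._cd40l_lethal(t)
        egress = self._egress_rate(t)
        for c in st.cells:
            if c.state != LIVE:
                continue
            if c.compartment == PC:
                hazard = 1.0 if taci else cfg.pc_death_rate
                if hazard >= 1.0 or self.rng_death.random() < hazard:
                    c.state = DYING
                elif egress > 0 and self.rng_death.random() < egress:
                    c.compartment = EGRESSED
            elif c.compartment in (GC_LZ, GC_DZ, PREPC):
                if cd40l_kill:
                    c.state = DYING
                elif cfg.gc_death_rate > 0 and self.rng_death.random() < cfg.gc_death_rate:
                    c.state = DYING
        gc_live = [
            c for c in st.cells if c.state == LIVE and c.compartment in (GC_LZ, GC_DZ)
        ]
        excess = len(gc_live) - cfg.gc_capacity
        if excess > 0:
            idx = self.rng_death.choice(len(gc_live), size=excess, replace=False)
            for i in sorted(int(i) for i in idx):
                gc_live[i].state = DYING

        # phase 7: secretion into serum
        if cfg.serum_decay > 0:
            for k in st.serum:
                st.serum[k] *= 1.0 - cfg.serum_decay
        for c in st.cells:
            if c.state == LIVE and c.compartment == PC:
                key = (c.clone_id, c.affinity)
                st.serum[key] = st.serum.get(key, 0.0) + cfg.secretion_rate

        st.step = t + 1
        self._record()

    def _record(self) -> None:
        st = self.state
        cfg = self.config
        # drop DEAD cells from the working list; the counter preserves the
        # conservation invariant (live + dying + dead == ever created)
        st.n_dead += sum(1 for c in st.cells if c.state == DEAD)
        st.cells = [c for c in st.cells if c.state != DEAD]
        counts = {GC_LZ: 0, GC_DZ: 0, PREPC: 0, PC: 0, EGRESSED: 0}
        n_live = n_dying = 0
        n_dead = st.n_dead
        for c in st.cells:
            if c.state == LIVE:
                n_live += 1
                counts[c.compartment] += 1
            elif c.state == DYING:
                n_dying += 1
        st.event_log.append(
            {
                "step": st.step,
                "day": cfg.day(st.step),
                "n_gc_lz": counts[GC_LZ],
                "n_gc_dz": counts[GC_DZ],
                "n_prepc": counts[PREPC],
                "n_pc": counts[PC],
                "n_egressed": counts[EGRESSED],
                "n_live": n_live,
                "n_dying": n_dying,
                "n_dead": n_dead,
                "serum_total": float(sum(st.serum.values())),
            }
        )
        st.serum_series.append(
            SerumSample(
                timepoint=st.step,
                species=[
                    (conc, cfg.kd0 / aff, clone)
                    for (clone, aff), conc in sorted(st.serum.items())
                ],
            )
        )

    # -- snapshots -----------------------------------------------------------

    def snapshot(self) -> None:
        """Record every live or dying cell at the current step."""
        st = self.state
        cfg = self.config
        t = st.step
        for c in st.cells:
            if c.state not in (LIVE, DYING) or c.compartment == EGRESSED:
                continue
            meas = c.mcherry
            if cfg.label_noise_sigma > 0:
                meas *= float(
                    np.exp(self.rng_measure.normal(0.0, cfg.label_noise_sigma))
                )
            rid = f"{self.animal}.t{t}.{c.cell_id}"
            st.snapshot_rows.append(
                {
                    "cell_id": rid,
                    "internal_id": c.cell_id,
                    "timepoint_step": t,
                    "timepoint_day": cfg.day(t),
                    "clone_id": c.clone_id,
                    "compartment": c.compartment,
                    "celltype": _CELLTYPE[c.compartment],
                    "state": c.state,
                    "v_call_h": c.v_call_h,
                    "j_call_h": c.j_call_h,
                    "v_call_l": c.v_call_l,
                    "j_call_l": c.j_call_l,
                    "heavy_seq": c.heavy_seq,
                    "light_seq": c.light_seq,
                    "junction_h": c.junction_h,
                    "junction_l": c.junction_l,
                    "affinity": c.affinity,
                    "captured": c.captured,
                    "myc": c.myc,
                    "budget": c.budget,
                    "divisions_since_label": c.divisions_since_label,
                    "total_divisions": c.total_divisions,
                    "zsg": c.zsg,
                    "mcherry": meas,
                    "mcherry_true": c.mcherry,
                    "dec_targetable": c.dec_targetable,
                    "dec_override_used": c.dec_override_used,
                    "dec_myc": c.dec_myc,
                    "dec_used_at": c.dec_used_at,
                    "animal": self.animal,
                }
            )
            st.mutation_log[rid] = c.events

    def run(self) -> SimulationOutput:
        snaps = set(self.config.resolved_snapshots())
        if 0 in snaps:
            self.snapshot()
        for _ in range(self.config.horizon_steps):
            self.step_once()
            if self.state.step in snaps:
                self.snapshot()
        return self._output()

    def _output(self) -> SimulationOutput:
        st = self.state
        cells = pd.DataFrame(st.snapshot_rows)
        repertoire = _repertoire_table(cells)
        serum_rows = [
            {
                "timepoint": s.timepoint,
                "clone_id": clone,
                "concentration": conc,
                "kd": kd,
            }
            for s in st.serum_series
            for (conc, kd, clone) in s.species
        ]
        serum_df = pd.DataFrame(
            serum_rows, columns=["timepoint", "clone_id", "concentration", "kd"]
        )
        export_log = pd.DataFrame(
            st.export_log,
            columns=["step", "affinity", "lz_mean_affinity", "budget", "v_call_h", "heavy_seq"],
        )
        event_log = pd.DataFrame(st.event_log)
        return SimulationOutput(
            config=self.config,
            animal=self.animal,
            cells=cells,
            repertoire=repertoire,
            serum=st.serum_series,
            serum_df=serum_df,
            export_log=export_log,
            event_log=event_log,
            mutation_log=dict(st.mutation_log),
        )


AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "sequence_alignment",
    "germline_alignment",
    "junction_aa",
    "c_celltype",
    "c_zsg",
    "c_mcherry",
    "c_live_state",
    "c_timepoint",
    "c_animal",
]


def _repertoire_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Explode per-cell snapshots into an AIRR-style paired-chain table."""
    if cells.empty:
        return pd.DataFrame(columns=AIRR_COLUMNS)
    rows = []
    for r in cells.itertuples(index=False):
        common = {
            "cell_id": r.cell_id,
            "c_celltype": r.celltype,
            "c_zsg": r.zsg,
            "c_mcherry": r.mcherry,
            "c_live_state": r.state,
            "c_timepoint": r.timepoint_step,
            "c_animal": r.animal,
        }
        rows.append(
            {
                "locus": "IGH",
                "v_call": r.v_call_h,
                "j_call": r.j_call_h,
                "sequence_alignment": r.heavy_seq,
                "germline_alignment": germline_of(r.v_call_h),
                "junction_aa": r.junction_h,
                **common,
            }
        )
        rows.append(
            {
                "locus": "IGK",
                "v_call": r.v_call_l,
                "j_call": r.j_call_l,
                "sequence_alignment": r.light_seq,
                "germline_alignment": germline_of(r.v_call_l),
                "junction_aa": r.junction_l,
                **common,
            }
        )
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def run_simulation(config: SimulationConfig, animal: str = "m1") -> SimulationOutput:
    """Run a full simulation; identical (config, seed) gives identical output."""
    return Simulation(config, animal=animal).run()
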