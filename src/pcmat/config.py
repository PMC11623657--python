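"""Simulation configuration: parameters, intervention schedule, TOML loading.

All tunables of the germinal-center (GC) to plasma-cell (PC) model live here.
Time is discrete; one step is ``step_hours`` of simulated time (default 12 h,
so 2 steps per day).  Affinities are dimensionless multiples of a reference
clone; antigen capture, Myc and division budgets are dimensionless too.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Any

from .germline import HEAVY_V, LIGHT_V


class ConfigError(ValueError):
    """Raised for an invalid configuration; message lists every violation."""


# intervention kinds
TAMOXIFEN_S1PR2 = "TAMOXIFEN_S1PR2"
TAMOXIFEN_BLIMP1 = "TAMOXIFEN_BLIMP1"
DOXYCYCLINE = "DOXYCYCLINE"
ANTI_CD40L = "ANTI_CD40L"
TACI_IG = "TACI_IG"
FTY720 = "FTY720"
DEC_OVA = "DEC_OVA"

INTERVENTION_KINDS = {
    TAMOXIFEN_S1PR2,
    TAMOXIFEN_BLIMP1,
    DOXYCYCLINE,
    ANTI_CD40L,
    TACI_IG,
    FTY720,
    DEC_OVA,
}


@dataclass(frozen=True)
class AffinitySite:
    """One designated affinity-enhancing substitution.

    ``chain`` is "heavy" or "light"; ``position`` is 1-based in germline
    coordinates; the factor multiplies the cell's affinity when the
    substitution ``from_res`` -> ``to_res`` occurs at that position.
    """

    chain: str
    position: int
    from_res: str
    to_res: str
    factor: float

    @property
    def label(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


# canonical affinity-enhancing substitutions of the IGHV1-72 anti-NP response
DEFAULT_AFFINITY_SITES = (
    AffinitySite("heavy", 33, "W", "L", 8.0),
    AffinitySite("heavy", 59, "K", "R", 2.0),
    AffinitySite("heavy", 99, "Y", "G", 2.0),
)


@dataclass(frozen=True)
class ScheduledIntervention:
    """One scheduled treatment.

    ``start_step`` is the step during which the treatment takes effect
    (labeling is instantaneous; blockades act from that step onward).
    ``delay_steps`` is the latency before full effect (used by ANTI_CD40L:
    help stops at ``start_step``, GC cells die at ``start_step +
    delay_steps``).  ``dose_fraction`` applies to DEC_OVA only and is the
    delivered antigen dose as a fraction of saturating capture.
    """

    kind: str
    start_step: int
    dose_fraction: float | None = None
    delay_steps: int = 4


@dataclass
class SimulationConfig:
    """All parameters of the GC->PC simulation.

    Defaults emulate an NP-OVA-like primary response in one draining lymph
    node: a modest founder pool in which one V gene (the IGHV1-72 analog)
    confers several-fold higher baseline hapten affinity, somatic mutation
    at a fraction of a substitution per chain per division, and
    help-proportional ("inertial") division budgets assigned at selection
    and at GC export.
    """

    # founders and receptors
    n_founders: int = 40
    v_gene_pool: dict[str, float] = field(
        default_factory=lambda: {v: 0.25 for v in HEAVY_V}
    )
    light_v_pool: dict[str, float] = field(
        default_factory=lambda: {v: 1.0 / len(LIGHT_V) for v in LIGHT_V}
    )
    high_affinity_v: str = "IGHV1-72*01"
    baseline_affinity: dict[str, float] = field(
        default_factory=lambda: {
            "IGHV1-72*01": 3.0,
            "IGHV1-53*01": 1.0,
            "IGHV9-3*01": 1.0,
            "IGHV5-17*01": 1.0,
        }
    )
    founder_affinity_sigma: float = 0.25  # lognormal clone-to-clone spread

    # somatic hypermutation
    mutation_rate: float = 0.2  # substitutions per chain per division
    affinity_site_table: tuple[AffinitySite, ...] = DEFAULT_AFFINITY_SITES
    hotspot_weight: float = 30.0  # mutability of affinity-site positions
    site_target_bias: float = 0.9  # P(designated residue | mutation at a site)
    lethal_fraction: float = 0.3
    deleterious_fraction: float = 0.4
    deleterious_factor: float = 0.7

    # help: capture -> Myc -> division budget
    capture_cmax: float = 1.0
    capture_K: float = 4.0
    myc_m0: float = 0.3
    myc_k: float = 1.0
    division_beta: float = 2.0
    budget_mode: str = "deterministic"  # or "poisson"
    budget_cap: int = 9
    il21_scale: float = 3.5

    # GC dynamics
    selection_fraction: float = 0.2  # mean fraction of LZ selected per step
    selection_temperature: float = 0.3
    gc_capacity: int = 300
    gc_death_rate: float = 0.04  # per-step background hazard, GC cells
    founder_influx_rate: float = 10.0  # naive clones entering the GC per step

    # export, PC fate
    pc_export_prob: float = 0.05  # per LZ cell per step, affinity-independent
    pc_death_rate: float = 0.12  # per-step hazard, affinity-independent
    pc_egress_rate: float = 0.16  # lymph-node egress; FTY720 forces 0

    # serum
    secretion_rate: float = 1.0
    kd0: float = 50.0  # dissociation constant at affinity 1
    serum_decay: float = 0.0  # per-step first-order clearance

    # division label (H2B-mCherry)
    mcherry_f0: float = 1000.0
    label_noise_sigma: float = 0.15  # lognormal, on F0 and on measurement

    # DEC205 targeting
    dec_wt_fraction: float = 0.1  # fraction of founders that are DEC205-wt

    # time
    step_hours: float = 12.0
    horizon_steps: int = 28
    snapshot_steps: tuple[int, ...] | None = None  # default: (horizon_steps,)

    interventions: tuple[ScheduledIntervention, ...] = ()
    seed: int = 0

    # -- helpers ------------------------------------------------------------

    def resolved_snapshots(self) -> tuple[int, ...]:
        if self.snapshot_steps is None:
            return (self.horizon_steps,)
        return tuple(sorted(set(self.snapshot_steps)))

    def day(self, step: int) -> float:
        return step * self.step_hours / 24.0

    def step_of_day(self, day: float) -> int:
        return int(round(day * 24.0 / self.step_hours))

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty when valid)."""
        errs: list[str] = []

        def prob(name: str, v: float) -> None:
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {v}")

        if self.n_founders < 1:
            errs.append("n_founders must be >= 1")
        if self.founder_influx_rate < 0:
            errs.append("founder_influx_rate must be >= 0")
        if self.horizon_steps < 0:
            errs.append("horizon_steps must be >= 0")
        if self.capture_K <= 0:
            errs.append("capture_K must be > 0")
        if self.capture_cmax <= 0:
            errs.append("capture_cmax must be > 0")
        if self.division_beta < 0:
            errs.append("division_beta must be >= 0")
        if self.il21_scale < 0:
            errs.append("il21_scale must be >= 0")
        if self.kd0 <= 0:
            errs.append("kd0 must be > 0")
        if self.budget_mode not in ("poisson", "deterministic"):
            errs.append(f"unknown budget_mode {self.budget_mode!r}")
        prob("mutation_rate", self.mutation_rate)
        prob("lethal_fraction", self.lethal_fraction)
        prob("deleterious_fraction", self.deleterious_fraction)
        if self.lethal_fraction + self.deleterious_fraction > 1.0:
            errs.append("lethal_fraction + deleterious_fraction must be <= 1")
        if not 0 < self.deleterious_factor <= 1:
            errs.append("deleterious_factor must be in (0, 1]")
        prob("pc_export_prob", self.pc_export_prob)
        prob("pc_death_rate", self.pc_death_rate)
        prob("gc_death_rate", self.gc_death_rate)
        prob("pc_egress_rate", self.pc_egress_rate)
        prob("serum_decay", self.serum_decay)
        for site in self.affinity_site_table:
            if site.factor <= 0:
                errs.append(f"affinity factor for {site.label} must be > 0")
        for v in self.baseline_affinity.values():
            if v <= 0:
                errs.append("baseline_affinity values must be > 0")
        if self.high_affinity_v not in self.v_gene_pool:
            errs.append(f"high_affinity_v {self.high_affinity_v!r} not in v_gene_pool")
        for iv in self.interventions:
            if iv.kind not in INTERVENTION_KINDS:
                errs.append(f"unknown intervention kind {iv.kind!r}")
            if not 0 <= iv.start_step <= self.horizon_steps:
                errs.append(
                    f"intervention {iv.kind} start_step {iv.start_step} outside horizon"
                )
            if iv.kind == DEC_OVA:
                if iv.dose_fraction is None or not 0.0 <= iv.dose_fraction <= 1.0:
                    errs.append("DEC_OVA requires dose_fraction in [0, 1]")
            elif iv.dose_fraction is not None:
                errs.append(f"dose_fraction only applies to DEC_OVA, not {iv.kind}")
        return errs

    def require_valid(self) -> None:
        errs = self.validate()
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _parse_interventions(items: list[dict[str, Any]]) -> tuple[ScheduledIntervention, ...]:
    out = []
    for item in items:
        out.append(
            ScheduledIntervention(
                kind=item["kind"],
                start_step=int(item["start_step"]),
                dose_fraction=item.get("dose_fraction"),
                delay_steps=int(item.get("delay_steps", 4)),
            )
        )
    return tuple(out)


def load_config(path: str, seed: int | None = None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a TOML file.

    TOML keys mirror the dataclass field names; unknown keys are rejected.
    Affinity sites are given as ``[[affinity_site_table]]`` tables with
    chain/position/from_res/to_res/factor keys; interventions as
    ``[[interventions]]`` tables.  A ``seed`` argument overrides the file.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "interventions" in raw:
        raw["interventions"] = _parse_interventions(raw["interventions"])
    if "affinity_site_table" in raw:
        raw["affinity_site_table"] = tuple(
            AffinitySite(
                chain=s["chain"],
                position=int(s["position"]),
                from_res=s["from_res"],
                to_res=s["to_res"],
                factor=float(s["factor"]),
            )
            for s in raw["affinity_site_table"]
        )
    if "snapshot_steps" in raw:
        raw["snapshot_steps"] = tuple(int(s) for s in raw["snapshot_steps"])
    if seed is not None:
        raw["seed"] = int(seed)
    cfg = SimulationConfig(**raw)
    cfg.require_valid()
    return cfg
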