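"""Core mechanistic primitives of the help-proportional division model.

The causal chain is:

    affinity --(saturating capture)--> antigen captured
             --(affine response)-----> Myc proxy
             --(beta, IL-21 scale)---> division budget (integer)

The budget is set once, at selection in the light zone or at GC export, and
is then spent by "inertial" divisions that need no further T-cell input.
Somatic hypermutation acts on aligned amino-acid strings; a small table of
designated substitutions (W33L/K59R/Y99G analogs on the high-affinity V)
multiplies affinity, all other substitutions are lethal, deleterious or
neutral with configured fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AffinitySite, SimulationConfig
from .germline import AMINO_ACIDS

OK = "OK"
LETHAL = "LETHAL"


def antigen_capture(affinity: float, cmax: float, K: float) -> float:
    """Antigen captured by a B cell with the given BCR affinity.

    Saturating (Michaelis-Menten) in affinity: ``cmax * a / (a + K)``.
    ``K`` is the affinity at half-saturating capture.
    """
    if K <= 0:
        raise ValueError(f"capture_K must be > 0, got {K}")
    if cmax <= 0:
        raise ValueError(f"capture_cmax must be > 0, got {cmax}")
    if affinity < 0:
        raise ValueError(f"affinity must be >= 0, got {affinity}")
    return cmax * affinity / (affinity + K)


def myc_level(captured: float, m0: float, k: float) -> float:
    """Myc proxy induced at selection: affine in antigen captured."""
    if captured < 0:
        raise ValueError(f"captured must be >= 0, got {captured}")
    return m0 + k * captured


def division_budget(
    myc: float,
    beta: float,
    il21_scale: float = 1.0,
    mode: str = "deterministic",
    rng: np.random.Generator | None = None,
    cap: int | None = None,
) -> int:
    """Number of inertial divisions licensed by a Myc level.

    Deterministic mode rounds ``beta * il21_scale * myc``; poisson mode
    draws with that mean.  ``cap`` truncates the heavy Poisson tail.
    """
    if myc < 0 or beta < 0 or il21_scale < 0:
        raise ValueError("myc, beta and il21_scale must all be >= 0")
    mean = beta * il21_scale * myc
    if mode == "deterministic":
        b = int(round(mean))
    elif mode == "poisson":
        if rng is None:
            raise ValueError("poisson mode requires an rng")
        b = int(rng.poisson(mean))
    else:
        raise ValueError(f"unknown budget mode {mode!r}")
    if cap is not None:
        b = min(b, cap)
    return b


@dataclass
class MutationOutcome:
    """Result of one round of per-chain somatic hypermutation."""

    heavy_seq: str
    light_seq: str
    affinity: float
    fate: str  # OK or LETHAL
    events: tuple[tuple[str, int, str, str], ...]  # (chain, pos, from, to)


def _position_weights(
    length: int, chain: str, sites: tuple[AffinitySite, ...], hotspot_weight: float
) -> np.ndarray:
    w = np.ones(length)
    for s in sites:
        if s.chain == chain and 1 <= s.position <= length:
            w[s.position - 1] = hotspot_weight
    return w / w.sum()


def mutate_chains(
    heavy_seq: str,
    light_seq: str,
    affinity: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> MutationOutcome:
    """Apply one division's worth of hypermutation to a paired BCR.

    Each chain independently acquires, with probability ``mutation_rate``,
    a single substitution at a hotspot-weighted random position.  A
    substitution matching the affinity-site table multiplies affinity by
    its factor; any other substitution is lethal, deleterious or neutral
    with the configured fractions.  Germline strings are never touched.
    """
    site_index = {
        (s.chain, s.position, s.from_res, s.to_res): s.factor
        for s in config.affinity_site_table
    }
    seqs = {"heavy": heavy_seq, "light": light_seq}
    events: list[tuple[str, int, str, str]] = []
    fate = OK
    for chain in ("heavy", "light"):
        if rng.random() >= config.mutation_rate:
            continue
        seq = seqs[chain]
        weights = _position_weights(
            len(seq), chain, config.affinity_site_table, config.hotspot_weight
        )
        pos = int(rng.choice(len(seq), p=weights)) + 1  # 1-based
        old = seq[pos - 1]
        # designated substitutions are recurrent: at a site position still
        # carrying the germline residue, the replacement is biased toward
        # the site's target residue (site_target_bias), else uniform
        site_here = next(
            (
                s
                for s in config.affinity_site_table
                if s.chain == chain and s.position == pos and s.from_res == old
            ),
            None,
        )
        if site_here is not None and rng.random() < config.site_target_bias:
            new = site_here.to_res
        else:
            candidates = [a for a in AMINO_ACIDS if a != old]
            new = candidates[int(rng.integers(len(candidates)))]
        seqs[chain] = seq[: pos - 1] + new + seq[pos:]
        events.append((chain, pos, old, new))
        factor = site_index.get((chain, pos, old, new))
        if factor is not None:
            affinity *= factor
        else:
            u = rng.random()
            if u < config.lethal_fraction:
                fate = LETHAL
            elif u < config.lethal_fraction + config.deleterious_fraction:
                affinity *= config.deleterious_factor
            # else neutral
    return MutationOutcome(
        heavy_seq=seqs["heavy"],
        light_seq=seqs["light"],
        affinity=affinity,
        fate=fate,
        events=tuple(events),
    )
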