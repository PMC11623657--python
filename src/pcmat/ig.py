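"""Paired-chain repertoire processing.

Turns a chain-level AIRR-style table into annotated, clonally grouped
paired records: strict 1 heavy + 1 light pairing, amino-acid mutation
calling against aligned germlines, scoring of designated affinity-enhancing
substitutions (presence-based by default), and V/J/junction single-linkage
clonal grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

GAP_CHARS = frozenset(".-X")

# default site set: canonical IGHV1-72 affinity-enhancing substitutions
DEFAULT_TARGET_V = "IGHV1-72*01"
DEFAULT_SITES = frozenset({"W33L", "K59R", "Y99G"})

HEAVY_LOCI = {"IGH"}
LIGHT_LOCI = {"IGK", "IGL"}

NO_HEAVY = "NO_HEAVY"
NO_LIGHT = "NO_LIGHT"
MULTI_HEAVY = "MULTI_HEAVY"
MULTI_LIGHT = "MULTI_LIGHT"


class Mutation(NamedTuple):
    """One amino-acid substitution in 1-based germline coordinates."""

    chain: str  # "heavy" | "light"
    position: int
    from_res: str
    to_res: str

    @property
    def label(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


@dataclass
class PairingResult:
    paired: pd.DataFrame  # one row per kept cell, heavy_*/light_* columns
    discarded: pd.DataFrame  # cell_id, reason
    n_deduplicated: int


def pair_chains(chains: pd.DataFrame) -> PairingResult:
    """Keep cells with exactly one heavy and exactly one light chain.

    Exact duplicate (cell_id, chain) rows are dropped with a counted
    warning before the 1xIgH + 1xIgL rule is applied.  Everything else is
    discarded with a reason: NO_HEAVY, NO_LIGHT, MULTI_HEAVY or
    MULTI_LIGHT (checked in that order).
    """
    if "cell_id" not in chains.columns:
        raise ValueError("chain table must carry cell_id")
    dedup_keys = [
        c
        for c in ("cell_id", "locus", "v_call", "j_call", "sequence_alignment")
        if c in chains.columns
    ]
    before = len(chains)
    chains = chains.drop_duplicates(subset=dedup_keys, keep="first")
    n_dedup = before - len(chains)
    if n_dedup:
        warnings.warn(f"dropped {n_dedup} duplicate chain rows", stacklevel=2)

    is_heavy = chains["locus"].isin(HEAVY_LOCI)
    n_heavy = is_heavy.groupby(chains["cell_id"]).sum()
    n_light = (~is_heavy).groupby(chains["cell_id"]).sum()
    reason = pd.Series(index=n_heavy.index, dtype=object)
    reason[n_heavy == 0] = NO_HEAVY
    reason[(n_heavy > 0) & (n_light == 0)] = NO_LIGHT
    reason[(n_heavy > 1) & (n_light > 0)] = MULTI_HEAVY
    reason[(n_heavy == 1) & (n_light > 1)] = MULTI_LIGHT
    disc = (
        reason.dropna()
        .rename("reason")
        .reset_index()
        .sort_values("cell_id", kind="mergesort")
        .reset_index(drop=True)
    )
    kept_ids = reason[reason.isna()].index

    def side(mask: pd.Series, prefix: str, with_custom: bool) -> pd.DataFrame:
        cols = {
            f"{prefix}_locus": chains.loc[mask, "locus"],
            f"{prefix}_v_call": chains.loc[mask, "v_call"],
            f"{prefix}_j_call": chains.loc[mask, "j_call"]
            if "j_call" in chains.columns
            else "",
            f"{prefix}_seq": chains.loc[mask, "sequence_alignment"],
            f"{prefix}_germline": chains.loc[mask, "germline_alignment"],
            f"{prefix}_junction": chains.loc[mask, "junction_aa"]
            if "junction_aa" in chains.columns
            else "",
        }
        df = pd.DataFrame(cols)
        df.insert(0, "cell_id", chains.loc[mask, "cell_id"])
        if with_custom:  # per-cell custom columns ride on the heavy row
            for col in chains.columns:
                if col.startswith("c_"):
                    df[col] = chains.loc[mask, col]
        return df[df["cell_id"].isin(kept_ids)]

    heavy_df = side(is_heavy, "heavy", with_custom=True)
    light_df = side(~is_heavy, "light", with_custom=False)
    paired = heavy_df.merge(light_df, on="cell_id", how="inner")
    paired = paired.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    return PairingResult(paired=paired, discarded=disc, n_deduplicated=n_dedup)


def call_mutations(
    observed: str, germline: str, chain: str = "heavy", cell_id: str = ""
) -> list[Mutation]:
    """Diff an aligned chain against its germline.

    One Mutation per differing position, 1-based; positions where either
    side is a gap or ambiguity character ('.', '-', 'X') are skipped.
    """
    if len(observed) != len(germline):
        raise ValueError(
            f"alignment length mismatch for cell {cell_id or '?'}: "
            f"{len(observed)} vs germline {len(germline)}"
        )
    muts = []
    for i, (o, g) in enumerate(zip(observed, germline), start=1):
        if o == g or o in GAP_CHARS or g in GAP_CHARS:
            continue
        muts.append(Mutation(chain, i, g, o))
    return muts


def call_paired_mutations(row: pd.Series) -> list[Mutation]:
    return call_mutations(
        row["heavy_seq"], row["heavy_germline"], "heavy", str(row["cell_id"])
    ) + call_mutations(
        row["light_seq"], row["light_germline"], "light", str(row["cell_id"])
    )


def mutation_load(mutations: Iterable[Mutation]) -> int:
    """Total VH+VL substitution count."""
    return sum(1 for _ in mutations)


def is_affinity_enhancing(
    heavy_v_call: str,
    mutations: Iterable[Mutation],
    target_v: str = DEFAULT_TARGET_V,
    site_set: frozenset[str] = DEFAULT_SITES,
    rule: str = "any",
) -> tuple[bool, frozenset[str]]:
    """Flag a cell carrying designated affinity-enhancing substitutions.

    The definition is V-restricted: only cells whose heavy V call equals
    ``target_v`` can be flagged.  ``rule="any"`` requires at least one site
    of ``site_set`` among the heavy-chain mutations, ``rule="all"``
    requires every site.  Returns (flag, matched sites).
    """
    if not site_set:
        raise ValueError("site_set must be non-empty")
    if rule not in ("any", "all"):
        raise ValueError(f"rule must be 'any' or 'all', got {rule!r}")
    hits = frozenset(
        m.label for m in mutations if m.chain == "heavy" and m.label in site_set
    )
    if heavy_v_call != target_v:
        return False, frozenset()
    if rule == "any":
        return (len(hits) > 0), hits
    return (hits == site_set), hits


def _junction_identity(a: str, b: str) -> float:
    # only called on equal-length junctions
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a) if a else 1.0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assign_clones(paired: pd.DataFrame, cdr3_identity_min: float = 0.85) -> pd.Series:
    """Single-linkage clonal grouping on heavy V, J, junction.

    Cells share a clone iff same heavy v_call and j_call, same heavy
    junction length, and junction identity >= ``cdr3_identity_min`` under
    single linkage.  Clone ids are deterministic: cells are canonically
    sorted before linkage, and clones are numbered by first appearance in
    that sort.  Returns a clone_id Series aligned to ``paired``.
    """
    if paired.empty:
        return pd.Series([], dtype=int, name="clone_id")
    order = paired[["heavy_v_call", "heavy_j_call", "heavy_junction", "cell_id"]].copy()
    order["jlen"] = order["heavy_junction"].str.len()
    order = order.sort_values(
        ["heavy_v_call", "heavy_j_call", "jlen", "heavy_junction", "cell_id"],
        kind="mergesort",
    )
    clone_of: dict = {}
    next_clone = 0
    for _, grp in order.groupby(["heavy_v_call", "heavy_j_call", "jlen"], sort=True):
        idx = list(grp.index)
        juncs = list(grp["heavy_junction"])
        uf = _UnionFind(len(idx))
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if _junction_identity(juncs[i], juncs[j]) >= cdr3_identity_min:
                    uf.union(i, j)
        roots: dict[int, int] = {}
        for i in range(len(idx)):
            r = uf.find(i)
            if r not in roots:
                roots[r] = next_clone
                next_clone += 1
            clone_of[idx[i]] = roots[r]
    return pd.Series(
        [clone_of[i] for i in paired.index], index=paired.index, name="clone_id"
    )


def annotate(
    chains: pd.DataFrame,
    target_v: str = DEFAULT_TARGET_V,
    site_set: frozenset[str] = DEFAULT_SITES,
    rule: str = "any",
    cdr3_identity_min: float = 0.85,
) -> pd.DataFrame:
    """Full pipeline: pair, call mutations, flag, group into clones.

    Returns one row per kept cell with mutation list, mutation_count,
    target_v_flag (heavy V equals the target), affinity_flag, hit string
    and clone_id; custom ``c_`` columns are carried through.
    """
    pairing = pair_chains(chains)
    paired = pairing.paired
    if paired.empty:
        return paired
    muts = paired.apply(call_paired_mutations, axis=1)
    paired = paired.assign(
        mutations=muts,
        mutation_count=[mutation_load(m) for m in muts],
    )
    flags, hit_strs = [], []
    for v, m in zip(paired["heavy_v_call"], paired["mutations"]):
        flag, hits = is_affinity_enhancing(v, m, target_v, site_set, rule)
        flags.append(flag)
        hit_strs.append(";".join(sorted(hits)))
    paired = paired.assign(
        target_v_flag=paired["heavy_v_call"] == target_v,
        affinity_flag=flags,
        affinity_hits=hit_strs,
    )
    paired = paired.assign(clone_id=assign_clones(paired, cdr3_identity_min))
    return paired


ANNOTATED_LIST_COLUMNS = ("mutations",)


def write_annotated(paired: pd.DataFrame, path: str) -> None:
    """Write the annotated table as TSV (mutation lists as W33L;K59R strings)."""
    out = paired.copy()
    if "mutations" in out.columns:
        out["mutations"] = [
            ";".join(f"{m.chain[0].upper()}:{m.label}" for m in ms)
            for ms in out["mutations"]
        ]
    out.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def read_annotated(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str}, keep_default_na=False,
                     na_values=[""])
    if "mutations" in df.columns:
        def parse(s):
            if not isinstance(s, str) or not s:
                return []
            out = []
            for tok in s.split(";"):
                chain, lab = tok.split(":")
                out.append(
                    Mutation(
                        "heavy" if chain == "H" else "light",
                        int(lab[1:-1]),
                        lab[0],
                        lab[-1],
                    )
                )
            return out

        df["mutations"] = [parse(s) for s in df["mutations"]]
    return df
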