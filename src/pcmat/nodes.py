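"""Genotype-node collapsing and node-level statistics.

A *genotype node* is the set of cells within one clone that share an
identical paired heavy+light amino-acid sequence.  Nodes are classified by
member composition (GC only, PC only, or mixed), and summarized per animal:
node counts and size distributions by composition, the fraction of nodes
carrying affinity-enhancing mutations, and the cell-level frequency of
those mutations among GC cells versus PCs.  A minimum-distance lineage
export serializes each clone's nodes as a germline-rooted newick tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GC_ONLY = "GC_ONLY"
PC_ONLY = "PC_ONLY"
MIXED = "MIXED"

COMPOSITIONS = (GC_ONLY, PC_ONLY, MIXED)


def _node_celltype(celltype: str, prepc_as: str = "GC") -> str:
    """Map a cell type onto the binary GC/PC node-classification scheme."""
    if celltype in ("GC", "PC"):
        return celltype
    if celltype == "PREPC":
        if prepc_as not in ("GC", "PC", "PREPC"):
            raise ValueError(f"prepc_as must be GC, PC or PREPC, got {prepc_as!r}")
        return prepc_as
    raise ValueError(f"unknown cell type {celltype!r}")


def classify_node(n_gc: int, n_pc: int) -> str:
    """GC_ONLY / PC_ONLY / MIXED by member composition."""
    if n_gc > 0 and n_pc == 0:
        return GC_ONLY
    if n_pc > 0 and n_gc == 0:
        return PC_ONLY
    if n_gc > 0 and n_pc > 0:
        return MIXED
    raise ValueError("node with no GC and no PC members")


def collapse_genotypes(annotated: pd.DataFrame, prepc_as: str = "GC") -> pd.DataFrame:
    """Collapse annotated cells into genotype nodes.

    One node per distinct (clone_id, heavy_seq, light_seq); node ids are
    deterministic (canonical sort by clone then sequences).  Requires
    columns clone_id, heavy_seq, light_seq, c_celltype, cell_id and (if
    present) affinity_flag, which is constant within a node by
    construction.
    """
    if annotated.empty:
        return pd.DataFrame(
            columns=[
                "clone_id",
                "node_id",
                "heavy_seq",
                "light_seq",
                "size",
                "n_gc",
                "n_pc",
                "composition",
                "affinity_flag",
                "member_cells",
            ]
        )
    df = annotated.copy()
    df["_node_type"] = [_node_celltype(t, prepc_as) for t in df["c_celltype"]]
    rows = []
    grouped = df.groupby(["clone_id", "heavy_seq", "light_seq"], sort=True)
    for node_idx, ((clone, h, l), grp) in enumerate(grouped):
        n_gc = int((grp["_node_type"] == "GC").sum())
        n_pc = int((grp["_node_type"] == "PC").sum())
        rows.append(
            {
                "clone_id": clone,
                "node_id": node_idx,
                "heavy_seq": h,
                "light_seq": l,
                "size": len(grp),
                "n_gc": n_gc,
                "n_pc": n_pc,
                "composition": classify_node(n_gc, n_pc),
                "affinity_flag": bool(grp["affinity_flag"].iloc[0])
                if "affinity_flag" in grp.columns
                else False,
                "member_cells": tuple(sorted(grp["cell_id"])),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NodeSummary:
    """Node- and cell-level summaries behind the clonal-tree statistics."""

    node_counts: pd.DataFrame  # animal x composition counts (+ pooled)
    node_sizes: pd.DataFrame  # per node: composition, size, n_gc, n_pc
    flagged_fraction: pd.DataFrame  # per composition group: fraction flagged
    cell_flag_freq: pd.DataFrame  # per animal & pooled: GC vs PC flag freq


def node_summary(nodes: pd.DataFrame, annotated: pd.DataFrame) -> NodeSummary:
    """Summarize classified, affinity-flagged nodes and their member cells."""
    ann = annotated.copy()
    animal_col = "c_animal" if "c_animal" in ann.columns else None

    # node counts by composition, pooled (node tables are per-animal inputs)
    counts = (
        nodes.groupby("composition").size().reindex(COMPOSITIONS, fill_value=0)
        if not nodes.empty
        else pd.Series(0, index=list(COMPOSITIONS))
    )
    node_counts = counts.rename_axis("composition").reset_index(name="n_nodes")

    node_sizes = (
        nodes[["clone_id", "node_id", "composition", "size", "n_gc", "n_pc"]].copy()
        if not nodes.empty
        else pd.DataFrame(
            columns=["clone_id", "node_id", "composition", "size", "n_gc", "n_pc"]
        )
    )

    if nodes.empty:
        flagged = pd.DataFrame(columns=["group", "n_nodes", "n_flagged", "fraction"])
    else:
        rows = []
        groups = {
            GC_ONLY: nodes[nodes.composition == GC_ONLY],
            PC_ONLY: nodes[nodes.composition == PC_ONLY],
            MIXED: nodes[nodes.composition == MIXED],
            "PC_CONTAINING": nodes[nodes.composition.isin((PC_ONLY, MIXED))],
            "ALL": nodes,
        }
        for name, grp in groups.items():
            n = len(grp)
            f = int(grp["affinity_flag"].sum()) if n else 0
            rows.append(
                {
                    "group": name,
                    "n_nodes": n,
                    "n_flagged": f,
                    "fraction": f / n if n else float("nan"),
                }
            )
        flagged = pd.DataFrame(rows)

    # cell-level affinity-mutation frequency, GC vs PC, per animal and pooled
    ann["_node_type"] = [_node_celltype(t) for t in ann["c_celltype"]]
    rows = []

    def freq_rows(label: str, sub: pd.DataFrame) -> None:
        for ct in ("GC", "PC"):
            cells = sub[sub["_node_type"] == ct]
            n = len(cells)
            f = int(cells["affinity_flag"].sum()) if n else 0
            rows.append(
                {
                    "animal": label,
                    "celltype": ct,
                    "n_cells": n,
                    "n_flagged": f,
                    "frequency": f / n if n else float("nan"),
                }
            )

    if animal_col:
        for animal, sub in ann.groupby(animal_col, sort=True):
            freq_rows(str(animal), sub)
    freq_rows("pooled", ann)
    cell_flag_freq = pd.DataFrame(rows)

    return NodeSummary(
        node_counts=node_counts,
        node_sizes=node_sizes,
        flagged_fraction=flagged,
        cell_flag_freq=cell_flag_freq,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def export_lineage(clone_nodes: pd.DataFrame, germline_heavy: str, germline_light: str) -> str:
    """Serialize one clone's genotype nodes as a germline-rooted newick tree.

    Each node attaches to its minimum-Hamming-distance candidate ancestor,
    where candidates are the germline plus every node strictly closer to
    germline; ties prefer the candidate with fewer mutations from germline,
    then lexicographic sequence order.  Branch lengths are Hamming
    distances; labels carry node id and size.
    """
    germ = germline_heavy + germline_light
    if clone_nodes.empty:
        return "germline;"
    info = []
    for r in clone_nodes.itertuples(index=False):
        seq = r.heavy_seq + r.light_seq
        info.append(
            {
                "node_id": r.node_id,
                "seq": seq,
                "size": r.size,
                "dist_germ": _hamming(seq, germ),
            }
        )
    info.sort(key=lambda d: (d["dist_germ"], d["seq"]))
    children: dict[object, list[tuple[dict, int]]] = {"germline": []}
    for i, node in enumerate(info):
        best = None  # (dist, cand_dist_germ, cand_seq, key)
        for cand in info[:i]:
            if cand["dist_germ"] >= node["dist_germ"]:
                continue
            d = _hamming(node["seq"], cand["seq"])
            key = (d, cand["dist_germ"], cand["seq"])
            if best is None or key < best[0]:
                best = (key, cand["node_id"])
        gkey = (node["dist_germ"], 0, germ)
        if best is None or gkey <= best[0]:
            parent = "germline"
        else:
            parent = best[1]
        children.setdefault(parent, []).append((node, node["dist_germ"]))
        children.setdefault(node["node_id"], [])

    def render(parent_key, parent_seq: str) -> str:
        parts = []
        for node, _ in children.get(parent_key, []):
            label = f"n{node['node_id']}_{node['size']}"
            dist = _hamming(node["seq"], parent_seq)
            sub = render(node["node_id"], node["seq"])
            if sub:
                parts.append(f"({sub}){label}:{dist}")
            else:
                parts.append(f"{label}:{dist}")
        return ",".join(parts)

    body = render("germline", germ)
    return f"({body})germline;" if body else "germline;"
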