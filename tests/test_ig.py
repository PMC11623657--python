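"""Tests for pairing, mutation calling, affinity flagging and clonal grouping."""

import numpy as np
import pandas as pd
import pytest

from pcmat import SimulationConfig, run_simulation
from pcmat.germline import germline_of
from pcmat.ig import (
    Mutation,
    annotate,
    assign_clones,
    call_mutations,
    is_affinity_enhancing,
    mutation_load,
    pair_chains,
    read_annotated,
    write_annotated,
)


def _chain(cell, locus, v="IGHV1-72*01", seq="WAY", germ="WAY", junc="CARW"):
    return {
        "cell_id": cell,
        "locus": locus,
        "v_call": v,
        "j_call": "J1",
        "sequence_alignment": seq,
        "germline_alignment": germ,
        "junction_aa": junc,
    }


class TestPairChains:
    def test_keep_and_discard_reasons(self):
        chains = pd.DataFrame(
            [
                _chain("ok", "IGH"),
                _chain("ok", "IGK"),
                _chain("lambda_ok", "IGH"),
                _chain("lambda_ok", "IGL"),
                _chain("two_heavy", "IGH"),
                _chain("two_heavy", "IGH", seq="WAX"),
                _chain("two_heavy", "IGK"),
                _chain("no_light", "IGH"),
                _chain("no_heavy", "IGK"),
                _chain("two_light", "IGH"),
                _chain("two_light", "IGK"),
                _chain("two_light", "IGL", seq="WAX"),
            ]
        )
        res = pair_chains(chains)
        assert sorted(res.paired.cell_id) == ["lambda_ok", "ok"]
        reasons = dict(zip(res.discarded.cell_id, res.discarded.reason))
        assert reasons == {
            "two_heavy": "MULTI_HEAVY",
            "no_light": "NO_LIGHT",
            "no_heavy": "NO_HEAVY",
            "two_light": "MULTI_LIGHT",
        }

    def test_exact_duplicates_deduplicated_with_warning(self):
        chains = pd.DataFrame(
            [_chain("a", "IGH"), _chain("a", "IGH"), _chain("a", "IGK")]
        )
        with pytest.warns(UserWarning, match="duplicate"):
            res = pair_chains(chains)
        assert res.n_deduplicated == 1
        assert list(res.paired.cell_id) == ["a"]

    def test_missing_cell_id_rejected(self):
        with pytest.raises(ValueError, match="cell_id"):
            pair_chains(pd.DataFrame({"locus": ["IGH"]}))


class TestCallMutations:
    def test_identical_gives_empty(self):
        assert call_mutations("WAY", "WAY") == []

    def test_single_difference_reported_one_based(self):
        germ = germline_of("IGHV1-72*01")
        obs = germ[:32] + "L" + germ[33:]
        muts = call_mutations(obs, germ, chain="heavy")
        assert muts == [Mutation("heavy", 33, "W", "L")]
        assert muts[0].label == "W33L"

    @pytest.mark.parametrize("gap", [".", "-", "X"])
    def test_gap_positions_skipped(self, gap):
        assert call_mutations(f"W{gap}Y", "WAY") == []
        assert call_mutations("WAY", f"W{gap}Y") == []

    def test_length_mismatch_names_cell(self):
        with pytest.raises(ValueError, match="cellX"):
            call_mutations("WA", "WAY", cell_id="cellX")


class TestAffinityFlag:
    def test_v_restricted_any_rule(self):
        w33l = [Mutation("heavy", 33, "W", "L")]
        flag, hits = is_affinity_enhancing("IGHV1-72*01", w33l)
        assert flag and hits == {"W33L"}
        # same substitution on another V gene does not count
        flag, hits = is_affinity_enhancing("IGHV1-53*01", w33l)
        assert not flag and hits == frozenset()

    def test_unmutated_not_flagged(self):
        flag, hits = is_affinity_enhancing("IGHV1-72*01", [])
        assert not flag

    def test_all_rule_requires_every_site(self):
        muts = [Mutation("heavy", 33, "W", "L"), Mutation("heavy", 59, "K", "R")]
        flag, _ = is_affinity_enhancing("IGHV1-72*01", muts, rule="all")
        assert not flag
        muts.append(Mutation("heavy", 99, "Y", "G"))
        flag, hits = is_affinity_enhancing("IGHV1-72*01", muts, rule="all")
        assert flag and hits == {"W33L", "K59R", "Y99G"}

    def test_light_chain_sites_never_match(self):
        muts = [Mutation("light", 33, "W", "L")]
        flag, _ = is_affinity_enhancing("IGHV1-72*01", muts)
        assert not flag

    def test_empty_site_set_is_usage_error(self):
        with pytest.raises(ValueError):
            is_affinity_enhancing("IGHV1-72*01", [], site_set=frozenset())

    def test_monotone_in_added_sites(self):
        # adding mutations can only turn the flag on, never off
        base = [Mutation("heavy", 59, "K", "R")]
        flag_before, _ = is_affinity_enhancing("IGHV1-72*01", base)
        more = base + [Mutation("heavy", 33, "W", "L"), Mutation("light", 5, "A", "C")]
        flag_after, _ = is_affinity_enhancing("IGHV1-72*01", more)
        assert flag_after >= flag_before


class TestMutationLoad:
    def test_additive_over_chains(self):
        muts = [
            Mutation("heavy", 1, "A", "C"),
            Mutation("heavy", 2, "A", "C"),
            Mutation("heavy", 3, "A", "C"),
            Mutation("light", 1, "A", "C"),
            Mutation("light", 2, "A", "C"),
        ]
        assert mutation_load(muts) == 5
        assert mutation_load([]) == 0


def _paired_df(rows):
    return pd.DataFrame(
        [
            {
                "cell_id": cid,
                "heavy_v_call": v,
                "heavy_j_call": j,
                "heavy_junction": junc,
            }
            for cid, v, j, junc in rows
        ]
    )


class TestAssignClones:
    def test_identical_heavy_chains_share_clone(self):
        df = _paired_df([("a", "V1", "J1", "CARWWWWWWW"), ("b", "V1", "J1", "CARWWWWWWW")])
        clones = assign_clones(df)
        assert clones["a" == df.cell_id].iloc[0] == clones["b" == df.cell_id].iloc[0]

    def test_different_junction_lengths_split(self):
        df = _paired_df([("a", "V1", "J1", "CARWWWWWWW"), ("b", "V1", "J1", "CARWWWWWW")])
        clones = assign_clones(df)
        assert clones.nunique() == 2

    def test_single_linkage_transitive_closure(self):
        # pairwise identities: AB = 0.9, BC = 0.9, AC = 0.8 -> one clone
        a = "AAAAAAAAAA"
        b = "AAAAAAAAAC"  # 1 diff from a
        c = "AAAAAAAACC"  # 1 diff from b, 2 from a
        df = _paired_df([("a", "V1", "J1", a), ("b", "V1", "J1", b), ("c", "V1", "J1", c)])
        clones = assign_clones(df, cdr3_identity_min=0.85)
        assert clones.nunique() == 1
        # without the bridge cell, a and c split
        df2 = _paired_df([("a", "V1", "J1", a), ("c", "V1", "J1", c)])
        assert assign_clones(df2, cdr3_identity_min=0.85).nunique() == 2

    def test_deterministic_under_permutation(self):
        rows = [("a", "V1", "J1", "AAAAAAAAAA"), ("b", "V2", "J1", "AAAAAAAAAA"),
                ("c", "V1", "J1", "AAAAAAAAAC")]
        df1 = _paired_df(rows)
        df2 = _paired_df(rows[::-1]).sort_values("cell_id").reset_index(drop=True)
        c1 = assign_clones(df1).to_list()
        c2 = assign_clones(df2).to_list()
        assert c1 == c2


class TestEndToEnd:
    def test_annotation_round_trip(self, default_run, tmp_path):
        ann = annotate(default_run.repertoire)
        path = tmp_path / "annotated.tsv"
        write_annotated(ann, str(path))
        back = read_annotated(str(path))
        assert list(back.cell_id) == list(ann.cell_id)
        assert list(back.clone_id) == list(ann.clone_id)
        assert list(back.mutation_count) == list(ann.mutation_count)
        assert list(back.affinity_flag) == list(ann.affinity_flag)
        assert [list(m) for m in back.mutations] == [list(m) for m in ann.mutations]

    def test_called_mutations_match_ground_truth(self, default_run):
        """Mutation calls equal the simulator's event log, cell by cell."""
        ann = annotate(default_run.repertoire)
        log = default_run.mutation_log
        checked = 0
        for row in ann.itertuples(index=False):
            events = log[row.cell_id]
            net = {}
            for chain, pos, _old, new in events:
                net[(chain, pos)] = new
            germs = {"heavy": row.heavy_germline, "light": row.light_germline}
            expected = {
                (chain, pos, germs[chain][pos - 1], res)
                for (chain, pos), res in net.items()
                if germs[chain][pos - 1] != res  # back-mutations cancel
            }
            called = {(m.chain, m.position, m.from_res, m.to_res) for m in row.mutations}
            assert called == expected
            checked += 1
        assert checked > 500

    def test_clone_assignment_recovers_founders_at_low_mutation(self):
        cfg = SimulationConfig(seed=21, mutation_rate=0.05, horizon_steps=20)
        out = run_simulation(cfg)
        ann = annotate(out.repertoire)
        truth = out.cells.set_index("cell_id").clone_id
        ann = ann.assign(truth=[truth[c] for c in ann.cell_id])
        # inferred clones neither merge distinct founders nor split one
        merged = ann.groupby("clone_id").truth.nunique()
        assert (merged == 1).all()
        split = ann.groupby("truth").clone_id.nunique()
        assert (split == 1).all()
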