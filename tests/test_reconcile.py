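"""Reconciliation-layer tests, including the three anchor scenarios:
a shallowly divergent allopatric sister pair merges, a deeply divergent
(>5.5%) allopatric pair is retained, and sympatric pairs are retained
regardless of divergence.
"""

import numpy as np
import pytest

from otudelim import distance_matrix, genetree
from otudelim.gap_partition import Partition
from otudelim.reconcile import (
    MorphologyOverride,
    ReconcileConfig,
    congruent_core,
    reconcile,
    sympatric,
)
from otudelim.seqdata import Alignment, SequenceRecord, UNKNOWN_REGION

RNG = np.random.default_rng(99)
BASE = "".join(np.random.default_rng(1234).choice(list("ACGT"), size=615))

TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def mutate(seq, positions):
    """Apply transitions at the given columns (controlled divergence)."""
    s = list(seq)
    for p in positions:
        s[p] = TS[s[p]]
    return "".join(s)


def build(groups):
    """groups: list of (prefix, n_copies, transition_positions, region, label).

    Returns an alignment of identical-within, controlled-between groups.
    """
    records = []
    for prefix, n, positions, region, label in groups:
        seq = mutate(BASE, positions)
        for i in range(n):
            records.append(
                SequenceRecord(
                    specimen_id=f"{prefix}{i + 1}",
                    sequence=seq,
                    morphospecies_label=label,
                    regions=frozenset({region}) if region else frozenset({UNKNOWN_REGION}),
                )
            )
    return Alignment(tuple(records))


def run_case(groups, p_gap_sets, p_ptp_sets, config=None):
    aln = build(groups)
    dm = distance_matrix(aln)
    tree = genetree.midpoint_root(genetree.neighbor_joining(dm))
    p_gap = Partition.from_sets(aln.ids, p_gap_sets, method="gap")
    p_ptp = Partition.from_sets(aln.ids, p_ptp_sets, method="ptp")
    return reconcile(p_gap, p_ptp, tree, dm, aln, config or ReconcileConfig()), aln


class TestCongruentCore:
    def test_identical_partitions_all_congruent(self):
        p = Partition.from_sets("abcdef", [("a", "b"), ("c", "d"), ("e", "f")])
        congruent, blocks = congruent_core(p, p)
        assert len(congruent) == 3 and not blocks

    def test_simple_conflict_block(self):
        pa = Partition.from_sets("abc", [("a", "b"), ("c",)])
        pb = Partition.from_sets("abc", [("a",), ("b",), ("c",)])
        congruent, blocks = congruent_core(pa, pb)
        assert congruent == [frozenset("c")]
        assert blocks == [frozenset("ab")]

    def test_blocks_are_exactly_where_finer_method_splits(self):
        # coarse partition nests the fine one: every conflict block is one
        # coarse OTU that the finer method subdivides
        ids = [f"s{i}" for i in range(12)]
        coarse = Partition.from_sets(ids, [ids[:6], ids[6:9], ids[9:]])
        fine = Partition.from_sets(
            ids, [ids[:3], ids[3:6], ids[6:9], ids[9:11], ids[11:]]
        )
        congruent, blocks = congruent_core(coarse, fine)
        assert congruent == [frozenset(ids[6:9])]
        assert set(blocks) == {frozenset(ids[:6]), frozenset(ids[9:])}

    def test_specimen_mismatch_raises(self):
        pa = Partition.from_sets("abc", [("a", "b", "c")])
        pb = Partition.from_sets("abd", [("a", "b", "d")])
        with pytest.raises(ValueError, match="c.*d|d.*c"):
            congruent_core(pa, pb)


class TestSympatry:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"SAS"}, {"ECS", "SCS"}, "allopatric"),
            ({"SCS"}, {"SCS", "IO"}, "sympatric"),
            ({UNKNOWN_REGION}, {"IO"}, "unknown"),
            (set(), {"IO"}, "unknown"),
            ({"GC", UNKNOWN_REGION}, {"GC"}, "sympatric"),
        ],
    )
    def test_predicate(self, a, b, expected):
        assert sympatric(a, b) == expected


class TestAnchorScenarios:
    def test_shallow_allopatric_pair_merges(self):
        # ~1.5% K2P between completely isolated groups: merged, tentative
        groups = [
            ("x", 3, [], "SAS", "Simulus one"),
            ("y", 3, range(9), "IO", "Simulus one"),
        ]
        table, aln = run_case(
            groups, [aln_ids := [f"x{i}" for i in (1, 2, 3)] + [f"y{i}" for i in (1, 2, 3)]],
            [["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        )
        assert table.n_species == 1
        assert "merged_allopatric" in table.hypotheses[0].status_flags
        assert "tentative" in table.hypotheses[0].status_flags

    def test_deep_allopatric_pair_retained(self):
        # ~5.9% K2P >= the strong-evidence threshold: kept as two species
        groups = [
            ("x", 3, [], "SAS", "Simulus one"),
            ("y", 3, range(34), "IO", "Simulus two"),
        ]
        table, _ = run_case(
            groups,
            [[f"x{i}" for i in (1, 2, 3)] + [f"y{i}" for i in (1, 2, 3)]],
            [["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        )
        assert table.n_species == 2
        for h in table.hypotheses:
            assert "strong_divergence_retained" in h.status_flags

    def test_sympatric_pair_retained_at_two_percent(self):
        groups = [
            ("x", 3, [], "SCS", "Simulus one"),
            ("y", 3, range(12), "SCS", "Simulus two"),
        ]
        table, _ = run_case(
            groups,
            [[f"x{i}" for i in (1, 2, 3)] + [f"y{i}" for i in (1, 2, 3)]],
            [["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        )
        assert table.n_species == 2
        for h in table.hypotheses:
            assert "retained_sympatric" in h.status_flags

    def test_unknown_region_keeps_split_tentative(self):
        groups = [
            ("x", 3, [], None, "Simulus one"),
            ("y", 3, range(12), None, "Simulus two"),
        ]
        table, _ = run_case(
            groups,
            [[f"x{i}" for i in (1, 2, 3)] + [f"y{i}" for i in (1, 2, 3)]],
            [["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        )
        assert table.n_species == 2
        for h in table.hypotheses:
            assert "tentative" in h.status_flags

    def test_three_subotu_case_merge_then_sympatric_retention(self):
        # three sub-OTUs: a/c allopatric sisters at ~3.6% merge; the merged
        # group is sympatric with b and both are retained -> 2 species, plus
        # a near-identical bPTP oversplit of a that merges first
        groups = [
            ("a", 3, [], "SAS", "Simulus undo"),
            ("c", 2, range(22), "ECS", "Simulus undo"),
            ("b", 2, range(22, 53), "SAS", "Simulus undo"),
        ]
        all_ids = ["a1", "a2", "a3", "c1", "c2", "b1", "b2"]
        table, _ = run_case(
            groups,
            [all_ids],
            [["a1", "a2"], ["a3"], ["c1", "c2"], ["b1", "b2"]],
        )
        assert table.n_species == 2
        merged = next(h for h in table.hypotheses if "a1" in h.members)
        assert set(merged.members) == {"a1", "a2", "a3", "c1", "c2"}
        assert "merged_allopatric" in merged.status_flags


class TestConfigEffects:
    CASE = dict(
        groups=[
            ("x", 3, [], "SAS", "Simulus one"),
            ("y", 3, range(20), "IO", "Simulus two"),  # ~3.3%
        ],
        gap=[["x1", "x2", "x3", "y1", "y2", "y3"]],
        ptp=[["x1", "x2", "x3"], ["y1", "y2", "y3"]],
    )

    def count(self, t_strong):
        table, _ = run_case(
            self.CASE["groups"],
            self.CASE["gap"],
            self.CASE["ptp"],
            ReconcileConfig(t_low=0.015, t_strong=t_strong),
        )
        return table.n_species

    def test_merging_monotone_in_t_strong(self):
        assert self.count(0.02) == 2  # 3.3% >= 2%: retained
        assert self.count(0.055) == 1  # 3.3% < 5.5%: merged
        assert self.count(0.02) >= self.count(0.055)

    def test_morphology_override_distinct_blocks_merge(self):
        table, _ = run_case(
            self.CASE["groups"],
            self.CASE["gap"],
            self.CASE["ptp"],
            ReconcileConfig(
                morphology_overrides=(
                    MorphologyOverride(
                        frozenset({"x1"}), frozenset({"y1"}), "distinct"
                    ),
                )
            ),
        )
        assert table.n_species == 2

    def test_morphology_override_conspecific_forces_merge(self):
        groups = [
            ("x", 3, [], "SCS", "Simulus one"),
            ("y", 3, range(20), "SCS", "Simulus one"),  # sympatric: kept by default
        ]
        cfg = ReconcileConfig(
            morphology_overrides=(
                MorphologyOverride(frozenset({"x1"}), frozenset({"y1"}), "conspecific"),
            )
        )
        table, _ = run_case(groups, self.CASE["gap"], self.CASE["ptp"], cfg)
        assert table.n_species == 1


class TestInvariants:
    def test_output_partitions_specimens(self, sim_default, sim_dm):
        from otudelim import run_all

        alignment, _ = sim_default
        result = run_all(alignment, seed=0)
        result.table.validate_partition(alignment.ids)

    def test_all_sympatric_never_merges_above_negligible(self):
        # one shared region: conflict sub-OTUs >= 1% apart stay split
        groups = [
            ("x", 3, [], "GC", "Simulus one"),
            ("y", 3, range(20), "GC", "Simulus two"),
        ]
        table, _ = run_case(
            groups,
            [["x1", "x2", "x3", "y1", "y2", "y3"]],
            [["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        )
        assert table.n_species == 2

    def test_no_region_data_no_merges_all_tentative(self):
        groups = [
            ("x", 2, [], None, "Simulus one"),
            ("y", 2, range(15), None, "Simulus one"),
            ("z", 2, range(15, 45), None, "Simulus two"),
        ]
        table, _ = run_case(
            groups,
            [["x1", "x2", "y1", "y2", "z1", "z2"]],
            [["x1", "x2"], ["y1", "y2"], ["z1", "z2"]],
        )
        assert table.n_species == 3
        for h in table.hypotheses:
            assert "tentative" in h.status_flags


class TestNaming:
    def test_mixed_labels_flagged_and_type_locality_wins(self):
        groups = [
            ("x", 2, [], "SCS", "Simulus alpha"),
            ("y", 1, [1], "SCS", "Simulus beta"),
        ]
        aln = build(groups)
        # mark y1 (label beta) as a type-locality specimen
        from dataclasses import replace

        records = tuple(
            replace(r, is_type_locality=(r.specimen_id == "y1")) for r in aln.records
        )
        aln = Alignment(records)
        dm = distance_matrix(aln)
        tree = genetree.midpoint_root(genetree.neighbor_joining(dm))
        one = [["x1", "x2", "y1"]]
        table = reconcile(
            Partition.from_sets(aln.ids, one, method="gap"),
            Partition.from_sets(aln.ids, one, method="ptp"),
            tree,
            dm,
            aln,
        )
        h = table.hypotheses[0]
        assert "name_incongruent" in h.status_flags
        assert h.assigned_name == "Simulus beta"
        assert h.name_basis == "type_locality"

    def test_majority_label_without_type_locality(self):
        groups = [
            ("x", 3, [], "SCS", "Simulus alpha"),
            ("y", 1, [1], "SCS", "Simulus beta"),
        ]
        table, _ = run_case(groups, [[f"x{i}" for i in (1, 2, 3)] + ["y1"]], [["x1", "x2", "x3", "y1"]])
        h = table.hypotheses[0]
        assert h.assigned_name == "Simulus alpha"
        assert h.name_basis == "majority_label"

    def test_tie_stays_unassigned(self):
        groups = [
            ("x", 2, [], "SCS", "Simulus alpha"),
            ("y", 2, [1], "SCS", "Simulus beta"),
        ]
        table, _ = run_case(groups, [["x1", "x2", "y1", "y2"]], [["x1", "x2", "y1", "y2"]])
        assert table.hypotheses[0].assigned_name == "unassigned"
        assert table.hypotheses[0].name_basis == "none"

    def test_label_split_across_otus_flags_both(self):
        groups = [
            ("x", 2, [], "SAS", "Simulus alpha"),
            ("y", 2, range(40), "IO", "Simulus alpha"),
        ]
        table, _ = run_case(
            groups,
            [["x1", "x2"], ["y1", "y2"]],
            [["x1", "x2"], ["y1", "y2"]],
        )
        assert table.n_species == 2
        for h in table.hypotheses:
            assert "name_incongruent" in h.status_flags
        assert "Simulus alpha" in table.name_report["polyphyletic_labels"]
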