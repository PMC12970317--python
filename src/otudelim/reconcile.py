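"""Integrative reconciliation of two delimitations into species hypotheses.

Two independent single-locus delimiters (the barcode-gap partitioner and
PTP) rarely agree everywhere.  This module implements the decision layer
that turns their outputs into a final species-hypothesis table:

* OTUs with identical member sets in both partitions are accepted as
  congruent support for a species.
* Where the partitions disagree, the conflicting specimens form a block;
  within a block the finer partition supplies candidate sub-OTUs, which
  are then merged or retained pairwise along the guide tree:
  sympatric sister OTUs (sharing a biogeographic region) are kept
  distinct, allopatric sisters are merged unless their divergence exceeds
  a strong-evidence threshold (default 5.5% K2P), and pairs with unknown
  geography are kept but flagged tentative.  Optional per-pair morphology
  overrides ("distinct"/"conspecific") take precedence, reflecting
  specimen examination the software cannot perform.
* OTUs mixing several morphospecies labels, or labels scattered over
  several OTUs, are flagged as name-incongruent (database
  misidentifications are common in public barcode records).
* Each OTU is assigned a name: the unique label backed by a type-locality
  specimen if one exists, otherwise the majority label; unresolvable ties
  stay "unassigned".
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .gap_partition import Partition
from .seqdata import Alignment, UNKNOWN_REGION

log = logging.getLogger(__name__)

STATUS_FLAGS = (
    "congruent",
    "merged_allopatric",
    "retained_sympatric",
    "strong_divergence_retained",
    "name_incongruent",
    "tentative",
)


@dataclass(frozen=True)
class MorphologyOverride:
    """Per-pair evidence from specimen examination.

    The override applies to a candidate sister pair when ``ids_a`` has
    representatives in one side and ``ids_b`` in the other (representative
    semantics, so overrides survive earlier merges).
    """

    ids_a: frozenset[str]
    ids_b: frozenset[str]
    decision: str  # "distinct" | "conspecific"

    def __post_init__(self) -> None:
        if self.decision not in ("distinct", "conspecific"):
            raise ValueError(f"unknown override decision {self.decision!r}")

    def matches(self, x: set[str], y: set[str]) -> bool:
        return (bool(self.ids_a & x) and bool(self.ids_b & y)) or (
            bool(self.ids_a & y) and bool(self.ids_b & x)
        )


@dataclass(frozen=True)
class ReconcileConfig:
    t_low: float = 0.03  # divergence guide for species boundaries
    t_strong: float = 0.055  # strong-evidence override for allopatric pairs
    t_negligible: float = 0.01  # sister OTUs below this merge outright
    congruence_policy: str = "strict_equality"
    unknown_region_policy: str = "never_merge_flag"
    morphology_overrides: tuple[MorphologyOverride, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.t_low <= self.t_strong):
            raise ValueError("need 0 < t_low <= t_strong")
        if not (0 <= self.t_negligible < self.t_low):
            raise ValueError("need 0 <= t_negligible < t_low")


@dataclass(frozen=True)
class SpeciesHypothesis:
    otu_id: str
    members: tuple[str, ...]
    morphospecies_labels: dict[str, int] = field(default_factory=dict)
    regions: frozenset[str] = frozenset()
    status_flags: frozenset[str] = frozenset()
    assigned_name: str = "unassigned"
    name_basis: str = "none"  # type_locality | majority_label | none
    divergence_to_sister: tuple[float, float, float] | None = None  # min/mean/max

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("species hypothesis with no members")
        bad = set(self.status_flags) - set(STATUS_FLAGS)
        if bad:
            raise ValueError(f"unknown status flags {sorted(bad)}")
        if {"merged_allopatric", "retained_sympatric"} <= set(self.status_flags):
            raise ValueError("merged_allopatric and retained_sympatric conflict")


@dataclass(frozen=True)
class SpeciesHypothesisTable:
    hypotheses: tuple[SpeciesHypothesis, ...]
    provenance: dict = field(default_factory=dict)
    name_report: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.hypotheses)

    def specimen_ids(self) -> frozenset[str]:
        return frozenset(s for h in self.hypotheses for s in h.members)

    def validate_partition(self, expected_ids) -> None:
        seen: list[str] = []
        for h in self.hypotheses:
            seen.extend(h.members)
        if len(seen) != len(set(seen)):
            raise ValueError("hypotheses overlap: some specimen assigned twice")
        if set(seen) != set(expected_ids):
            missing = sorted(set(expected_ids) - set(seen))
            raise ValueError(f"specimens left unassigned: {missing}")

    def as_partition(self, ids) -> Partition:
        return Partition.from_sets(
            ids, [h.members for h in self.hypotheses], method="reconciled"
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for h in self.hypotheses:
            div = h.divergence_to_sister
            rows.append(
                {
                    "otu_id": h.otu_id,
                    "n_members": len(h.members),
                    "members": ",".join(h.members),
                    "labels": ";".join(
                        f"{k}:{v}" for k, v in sorted(h.morphospecies_labels.items())
                    ),
                    "regions": ",".join(sorted(h.regions)),
                    "flags": ",".join(sorted(h.status_flags)),
                    "assigned_name": h.assigned_name,
                    "name_basis": h.name_basis,
                    "sister_min_pct": round(div[0] * 100, 4) if div else "",
                    "sister_mean_pct": round(div[1] * 100, 4) if div else "",
                    "sister_max_pct": round(div[2] * 100, 4) if div else "",
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "name_report": self.name_report,
            "hypotheses": [
                {
                    "otu_id": h.otu_id,
                    "members": list(h.members),
                    "labels": h.morphospecies_labels,
                    "regions": sorted(h.regions),
                    "flags": sorted(h.status_flags),
                    "assigned_name": h.assigned_name,
                    "name_basis": h.name_basis,
                    "divergence_to_sister": h.divergence_to_sister,
                }
                for h in self.hypotheses
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --- congruence -----------------------------------------------------------


def congruent_core(
    p_a: Partition, p_b: Partition
) -> tuple[list[frozenset[str]], list[frozenset[str]]]:
    """Split the specimen set into congruent OTUs and conflict blocks.

    Congruent OTUs have identical member sets in both partitions.  The
    remaining OTUs are chained by member overlap; each connected component
    becomes one conflict block (a set of specimen ids).
    """
    if set(p_a.ids) != set(p_b.ids):
        diff = sorted(set(p_a.ids) ^ set(p_b.ids))
        raise ValueError(f"partitions cover different specimens: {diff}")
    sets_a, sets_b = p_a.as_sets(), p_b.as_sets()
    congruent = sorted(sets_a & sets_b, key=lambda g: sorted(g)[0])
    leftover = [g for g in list(sets_a) + list(sets_b) if g not in sets_a & sets_b]
    # union-find over overlapping OTUs
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g in leftover:
        ids = sorted(g)
        for sid in ids:
            parent.setdefault(sid, sid)
        root = find(ids[0])
        for sid in ids[1:]:
            parent[find(sid)] = root
    blocks: dict[str, set[str]] = {}
    for sid in parent:
        blocks.setdefault(find(sid), set()).add(sid)
    return congruent, sorted(
        (frozenset(b) for b in blocks.values()), key=lambda b: sorted(b)[0]
    )


# --- geography ------------------------------------------------------------


def sympatric(regions_a, regions_b) -> str:
    """Classify a pair of region sets: sympatric / allopatric / unknown.

    UNKNOWN never counts as overlap; a side left empty after dropping
    UNKNOWN makes the comparison undecidable.
    """
    a = set(regions_a) - {UNKNOWN_REGION}
    b = set(regions_b) - {UNKNOWN_REGION}
    if not a or not b:
        return "unknown"
    return "sympatric" if a & b else "allopatric"


# --- conflict-block resolution -------------------------------------------


class _CladeIndex:
    """Leaf sets per node of the guide tree, for MRCA/sister queries."""

    def __init__(self, tree: dendropy.Tree):
        self.clades: list[frozenset[str]] = []
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd._leafset = frozenset([nd.taxon.label])
            else:
                nd._leafset = frozenset().union(
                    *(c._leafset for c in nd.child_nodes())
                )
            self.clades.append(nd._leafset)
        self.clades.sort(key=len)

    def mrca_clade(self, ids: set[str]) -> frozenset[str]:
        want = frozenset(ids)
        for clade in self.clades:
            if want <= clade:
                return clade
        raise ValueError(f"ids {sorted(want)} not all on the guide tree")


def _cluster_regions(cluster, alignment: Alignment) -> frozenset[str]:
    regions: set[str] = set()
    for sid in cluster:
        regions |= alignment.record(sid).regions
    regions -= {UNKNOWN_REGION}
    return frozenset(regions) if regions else frozenset({UNKNOWN_REGION})


def resolve_conflict_block(
    block: frozenset[str],
    sub_otus: list[frozenset[str]],
    clade_index: _CladeIndex,
    dm: DistanceMatrix,
    alignment: Alignment,
    config: ReconcileConfig,
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Merge/retain the finer partition's sub-OTUs inside one conflict block.

    Sister pairs (read off the guide tree, most recent first) are decided
    by morphology overrides, then the sympatry criterion, then the
    strong-divergence threshold; merging repeats until no rule applies.
    Returns (members, flags) pairs.
    """
    clusters: list[set[str]] = [set(g) for g in sub_otus]
    flags: list[set[str]] = [set() for _ in clusters]
    for cl in clusters:
        if len(cl) > 1:
            mrca = clade_index.mrca_clade(cl)
            if (mrca & block) - cl:
                log.warning(
                    "non-monophyletic OTU in conflict block; using "
                    "nearest-ancestor grouping: %s",
                    sorted(cl),
                )
    decided: set[frozenset[int]] = set()

    def sister_pairs():
        pairs = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = frozenset([frozenset(clusters[i]), frozenset(clusters[j])])
                if key in decided:
                    continue
                union = clusters[i] | clusters[j]
                clade = clade_index.mrca_clade(union)
                extra = (clade & block) - union
                if not extra:
                    pairs.append((len(clade), i, j))
        pairs.sort()
        return [(i, j) for _, i, j in pairs]

    def nearest_undecided_pairs():
        """Fallback when the tree offers no clean sister pair (interleaved
        non-monophyletic sub-OTUs): closest pair by K2P first."""
        pairs = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = frozenset([frozenset(clusters[i]), frozenset(clusters[j])])
                if key in decided:
                    continue
                d_min, _, _ = dm.group_stats(sorted(clusters[i]), sorted(clusters[j]))
                pairs.append((d_min, i, j))
        pairs.sort()
        return [(i, j) for _, i, j in pairs]

    while len(clusters) > 1:
        progressed = False
        candidates = sister_pairs() or nearest_undecided_pairs()
        for i, j in candidates:
            key = frozenset(
                [frozenset(clusters[i]), frozenset(clusters[j])]
            )
            if key in decided:
                continue
            decision, new_flags = _decide_pair(
                clusters[i], clusters[j], dm, alignment, config
            )
            if decision == "merge":
                merged = clusters[i] | clusters[j]
                # retention flags describe superseded clusters, not the union
                merged_flags = (
                    (flags[i] | flags[j]) - {"retained_sympatric", "strong_divergence_retained"}
                ) | new_flags
                keep = [
                    (c, f)
                    for k, (c, f) in enumerate(zip(clusters, flags))
                    if k not in (i, j)
                ]
                clusters = [c for c, _ in keep] + [merged]
                flags = [f for _, f in keep] + [merged_flags]
                decided = set()  # memberships changed
            else:
                for k in (i, j):
                    add = set(new_flags)
                    if "merged_allopatric" in flags[k]:
                        add.discard("retained_sympatric")
                    flags[k] |= add
                decided.add(key)
            progressed = True
            break
        if not progressed:
            break
    return [
        (frozenset(c), frozenset(f)) for c, f in zip(clusters, flags)
    ]


def _decide_pair(x, y, dm, alignment, config):
    for ov in config.morphology_overrides:
        if ov.matches(x, y):
            if ov.decision == "distinct":
                return "keep", set()
            return "merge", set()
    d_min, _, _ = dm.group_stats(sorted(x), sorted(y))
    # near-identical sister OTUs are delimiter noise (the finer method
    # overpredicting); merge them regardless of geography
    if d_min < config.t_negligible:
        return "merge", set()
    geo = sympatric(_cluster_regions(x, alignment), _cluster_regions(y, alignment))
    if geo == "sympatric":
        return "keep", {"retained_sympatric"}
    if geo == "unknown":
        return "keep", {"tentative"}
    if d_min < config.t_strong:
        return "merge", {"merged_allopatric", "tentative"}
    return "keep", {"strong_divergence_retained"}


# --- naming ---------------------------------------------------------------


def flag_name_incongruence(
    table: SpeciesHypothesisTable,
) -> SpeciesHypothesisTable:
    """Flag OTUs with mixed labels and labels spanning several OTUs."""
    label_to_otus: dict[str, list[str]] = {}
    for h in table.hypotheses:
        for label in h.morphospecies_labels:
            if label:
                label_to_otus.setdefault(label, []).append(h.otu_id)
    polyphyletic = {k: v for k, v in label_to_otus.items() if len(v) > 1}
    mixed = [
        h.otu_id
        for h in table.hypotheses
        if len([l for l in h.morphospecies_labels if l]) > 1
    ]
    flagged = []
    for h in table.hypotheses:
        labels = [l for l in h.morphospecies_labels if l]
        incongruent = len(labels) > 1 or any(l in polyphyletic for l in labels)
        if incongruent:
            h = replace(h, status_flags=h.status_flags | {"name_incongruent"})
        flagged.append(h)
    report = dict(table.name_report)
    report["mixed_label_otus"] = sorted(mixed)
    report["polyphyletic_labels"] = {k: sorted(v) for k, v in sorted(polyphyletic.items())}
    return SpeciesHypothesisTable(
        hypotheses=tuple(flagged), provenance=table.provenance, name_report=report
    )


def assign_names(
    table: SpeciesHypothesisTable, alignment: Alignment
) -> SpeciesHypothesisTable:
    """Assign a name to each OTU, anchored on type-locality specimens.

    If exactly one label inside the OTU is carried by a type-locality
    specimen, that label wins; otherwise the (strict) majority label;
    ties and unlabeled OTUs stay unassigned.
    """
    out = []
    for h in table.hypotheses:
        labels = Counter()
        tl_labels = set()
        for sid in h.members:
            rec = alignment.record(sid)
            if rec.morphospecies_label:
                labels[rec.morphospecies_label] += 1
                if rec.is_type_locality:
                    tl_labels.add(rec.morphospecies_label)
        name, basis = "unassigned", "none"
        if len(tl_labels) == 1:
            name, basis = next(iter(tl_labels)), "type_locality"
        elif labels:
            ranked = labels.most_common()
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                name, basis = ranked[0][0], "majority_label"
        out.append(replace(h, assigned_name=name, name_basis=basis))
    return SpeciesHypothesisTable(
        hypotheses=tuple(out), provenance=table.provenance, name_report=table.name_report
    )


# --- end-to-end -----------------------------------------------------------


def reconcile(
    p_gap: Partition,
    p_ptp: Partition,
    guide_tree: dendropy.Tree,
    dm: DistanceMatrix,
    alignment: Alignment,
    config: ReconcileConfig | None = None,
) -> SpeciesHypothesisTable:
    """Full reconciliation: congruence, block resolution, flags and names."""
    config = config or ReconcileConfig()
    congruent, blocks = congruent_core(p_gap, p_ptp)
    clade_index = _CladeIndex(guide_tree)

    resolved: list[tuple[frozenset[str], frozenset[str]]] = [
        (g, frozenset({"congruent"})) for g in congruent
    ]
    for block in blocks:
        ga = p_gap.restricted(block)
        gb = p_ptp.restricted(block)
        finer = gb if gb.n_otus >= ga.n_otus else ga
        sub_otus = sorted(finer.as_sets(), key=lambda g: sorted(g)[0])
        resolved.extend(
            resolve_conflict_block(block, sub_otus, clade_index, dm, alignment, config)
        )

    # stable ordering: by first member in alignment order
    order = {sid: k for k, sid in enumerate(alignment.ids)}
    resolved.sort(key=lambda item: min(order[s] for s in item[0]))
    hypotheses = []
    for k, (members, flags) in enumerate(resolved):
        members_sorted = tuple(sorted(members, key=order.get))
        labels = Counter(
            alignment.record(s).morphospecies_label
            for s in members_sorted
            if alignment.record(s).morphospecies_label
        )
        regions = _cluster_regions(members, alignment)
        if "congruent" not in flags and regions == frozenset({UNKNOWN_REGION}):
            # conflict-block hypotheses with no geography stay tentative
            flags = flags | {"tentative"}
        hypotheses.append(
            SpeciesHypothesis(
                otu_id=f"OTU{k + 1:03d}",
                members=members_sorted,
                morphospecies_labels=dict(labels),
                regions=regions,
                status_flags=flags,
            )
        )

    # sister divergences: nearest other hypothesis by minimum K2P
    if len(hypotheses) > 1:
        with_div = []
        for h in hypotheses:
            best = None
            for other in hypotheses:
                if other is h:
                    continue
                stats = dm.group_stats(h.members, other.members)
                if best is None or stats[0] < best[0]:
                    best = stats
            with_div.append(replace(h, divergence_to_sister=best))
        hypotheses = with_div

    digest = hashlib.md5(
        ("|".join(dm.ids) + dm.d.tobytes().hex()[:64]).encode()
    ).hexdigest()[:12]
    table = SpeciesHypothesisTable(
        hypotheses=tuple(hypotheses),
        provenance={
            "config": {
                "t_low": config.t_low,
                "t_strong": config.t_strong,
                "congruence_policy": config.congruence_policy,
                "unknown_region_policy": config.unknown_region_policy,
                "n_morphology_overrides": len(config.morphology_overrides),
            },
            "n_specimens": len(dm.ids),
            "input_digest": digest,
            "otu_counts": {"gap": p_gap.n_otus, "ptp": p_ptp.n_otus},
        },
    )
    table.validate_partition(dm.ids)
    table = flag_name_incongruence(table)
    table = assign_names(table, alignment)
    table.validate_partition(dm.ids)
    return table
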