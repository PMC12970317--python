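"""Ground-truth synthetic data for exercising the delimitation pipeline.

The generator emulates the statistical structure of a curated single-locus
barcode dataset: several species related by a Yule (pure-birth) species
tree, shallow within-species variation grafted at the tips, sequences
evolved under the two-parameter (K80) substitution model -- the exact model
the K2P distance estimator assumes, so estimator consistency is testable --
region assignments from the eight-province vocabulary with a controllable
probability that sister species are sympatric, and label noise mimicking
database misidentifications.

Scales are expressed in substitutions/site: ``mu`` is the species-tree
root-to-tip depth, ``pop_scale`` the within-species subtree depth as a
fraction of ``mu``.  Species-tree draws are resampled until the youngest
split is at least ``min_split_frac`` of the depth, which enforces the >= 1%
interspecific divergence floor typical of real barcode datasets (a Yule
draw can otherwise place two species arbitrarily close, where no
single-locus method can separate them).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .gap_partition import Partition
from .seqdata import (
    DEFAULT_REGIONS,
    Alignment,
    SequenceRecord,
    write_fasta,
    write_metadata,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 5
    n_per_species: int = 6
    birth_rate: float = 1.0  # per-lineage speciation rate (shape only)
    mu: float = 0.06  # species-tree root-to-tip depth, subs/site
    pop_scale: float = 0.05  # within-species depth as a fraction of mu
    # youngest split >= this fraction of depth; with pop_scale = 0.05 the
    # default keeps the within/between depth ratio at or below 0.1
    min_split_frac: float = 0.5
    seq_length: int = 615
    kappa: float = 4.0  # transition/transversion rate ratio
    regions_per_species: int = 1
    p_sympatric_sisters: float = 0.5
    mislabel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_per_species, self.seq_length) < 1:
            raise ValueError("counts must be positive")
        if min(self.birth_rate, self.mu, self.kappa) <= 0:
            raise ValueError("rates must be positive")
        if not (0 <= self.mislabel_rate < 1):
            raise ValueError("mislabel_rate must be in [0, 1)")
        if self.pop_scale >= 1:
            raise ValueError(
                "pop_scale >= 1: expected within-species divergence would "
                "exceed between-species divergence; no delimiter can work there"
            )
        if self.n_species > 1 and self.pop_scale >= self.min_split_frac:
            raise ValueError(
                "pop_scale must be < min_split_frac so within-species "
                "subtrees fit under the youngest speciation"
            )
        if not (1 <= self.regions_per_species <= len(DEFAULT_REGIONS)):
            raise ValueError("regions_per_species out of range")


@dataclass(frozen=True)
class SimulationTruth:
    true_partition: Partition
    species_tree_newick: str
    gene_tree_newick: str
    true_labels: dict[str, str]
    observed_labels: dict[str, str]
    species_regions: dict[str, tuple[str, ...]]
    config: SimConfig

    def gene_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.gene_tree_newick, schema="newick", preserve_underscores=True
        )

    def write_json(self, path: str | Path) -> None:
        payload = {
            "true_partition": {
                sid: otu for sid, otu in zip(
                    self.true_partition.ids, self.true_partition.otus
                )
            },
            "species_tree": self.species_tree_newick,
            "gene_tree": self.gene_tree_newick,
            "true_labels": self.true_labels,
            "observed_labels": self.observed_labels,
            "species_regions": {k: list(v) for k, v in self.species_regions.items()},
            "config": {k: getattr(self.config, k) for k in self.config.__dataclass_fields__},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[_Node] = []
        self.length = length
        self.label = label


def _yule(n_tips: int, rate: float, rng: np.random.Generator) -> tuple[_Node, float]:
    """Forward Yule tree with an exponential tail after the last split.

    Returns (root, total depth).  With one tip the 'tree' is a single
    pendant lineage of expected length 1/rate.
    """
    if n_tips == 1:
        root = _Node(length=float(rng.exponential(1.0 / rate)))
        return root, root.length
    t = 0.0
    root = _Node(length=0.0)  # depth is measured from the root split
    first = (_Node(), _Node())
    root.children = list(first)
    active: list[tuple[_Node, float]] = [(first[0], 0.0), (first[1], 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += float(rng.exponential(1.0 / (k * rate)))
        pick = int(rng.integers(k))
        node, born = active.pop(pick)
        node.length = t - born
        left, right = _Node(), _Node()
        node.children = [left, right]
        active.append((left, t))
        active.append((right, t))
    total = t + float(rng.exponential(1.0 / (n_tips * rate)))
    for node, born in active:
        node.length = total - born
    return root, total


def _scale(node: _Node, factor: float) -> None:
    node.length *= factor
    for c in node.children:
        _scale(c, factor)


def _youngest_split_age(root: _Node, depth: float) -> float:
    """Age (time before present) of the most recent split."""
    ages = []

    def walk(node: _Node, dist: float) -> None:
        dist += node.length
        if node.children:
            ages.append(depth - dist)
            for c in node.children:
                walk(c, dist)

    walk(root, -root.length)
    return min(ages) if ages else depth


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.10f}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length:.10f}"


def _leaves(node: _Node) -> list[_Node]:
    if not node.children:
        return [node]
    return [lf for c in node.children for lf in _leaves(c)]


def _evolve(parent_codes: np.ndarray, b: float, kappa: float, rng) -> np.ndarray:
    """One branch of K80 evolution (branch length b in subs/site)."""
    if b <= 0:
        return parent_codes.copy()
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta * b)
    e2 = math.exp(-2.0 * (alpha + beta) * b)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(parent_codes.size)
    out = parent_codes.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    out[ts_mask] = parent_codes[ts_mask] ^ 2  # A<->G, C<->T
    out[tv1_mask] = (parent_codes[tv1_mask] + 1) % 4
    out[tv2_mask] = (parent_codes[tv2_mask] + 3) % 4
    return out


def simulate(config: SimConfig | None = None) -> tuple[Alignment, SimulationTruth]:
    """Generate one dataset with known species truth, reproducible by seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    # species tree, conditioned on a separable youngest split
    for _ in range(1000):
        root, total = _yule(config.n_species, config.birth_rate, rng)
        _scale(root, config.mu / total)
        if config.n_species == 1:
            break
        if _youngest_split_age(root, config.mu) >= config.min_split_frac * config.mu:
            break
    else:
        raise RuntimeError("could not draw a species tree meeting min_split_frac")

    species = [f"sp{k + 1:02d}" for k in range(config.n_species)]
    species_leaves = _leaves(root)
    for leaf, name in zip(species_leaves, species):
        leaf.label = name
    species_newick = _newick(root) + ";"

    # regions: primary per species, cherries forced sympatric/allopatric
    pool = sorted(DEFAULT_REGIONS)
    primary = {sp: pool[int(rng.integers(len(pool)))] for sp in species}

    def cherries(node: _Node):
        if node.children:
            kids = node.children
            if all(not c.children for c in kids):
                yield tuple(c.label for c in kids)
            for c in kids:
                yield from cherries(c)

    for pair in cherries(root):
        a, b = pair[0], pair[1]
        if rng.random() < config.p_sympatric_sisters:
            primary[b] = primary[a]
        else:
            while primary[b] == primary[a]:
                primary[b] = pool[int(rng.integers(len(pool)))]
    species_regions: dict[str, tuple[str, ...]] = {}
    for sp in species:
        extra = [r for r in pool if r != primary[sp]]
        picks = list(
            rng.choice(extra, size=config.regions_per_species - 1, replace=False)
        )
        species_regions[sp] = tuple([primary[sp]] + sorted(str(x) for x in picks))

    # gene tree: graft within-species subtrees at the species tips
    subtree_depth = config.pop_scale * config.mu
    specimen_ids: dict[str, list[str]] = {}
    for leaf in species_leaves:
        sp = leaf.label
        names = [f"{sp}_{i + 1:02d}" for i in range(config.n_per_species)]
        specimen_ids[sp] = names
        if config.n_per_species == 1:
            leaf.label = names[0]
            continue
        sub_root, sub_total = _yule(config.n_per_species, 1.0, rng)
        _scale(sub_root, subtree_depth / sub_total)
        for sub_leaf, nm in zip(_leaves(sub_root), names):
            sub_leaf.label = nm
        leaf.label = None
        leaf.length -= subtree_depth
        if leaf.length < 0:  # cannot happen under the config validation
            raise RuntimeError("within-species subtree deeper than terminal branch")
        leaf.children = sub_root.children
    gene_newick = _newick(root) + ";"

    # sequences under K80 down the gene tree
    sequences: dict[str, str] = {}
    root_codes = rng.integers(0, 4, size=config.seq_length)

    def descend(node: _Node, codes: np.ndarray) -> None:
        for child in node.children:
            child_codes = _evolve(codes, child.length, config.kappa, rng)
            if child.children:
                descend(child, child_codes)
            else:
                sequences[child.label] = "".join(_BASES[c] for c in child_codes)

    if root.children:
        descend(root, root_codes)
    else:
        sequences[root.label] = "".join(
            _BASES[c] for c in _evolve(root_codes, root.length, config.kappa, rng)
        )

    # specimen table: true labels, mislabeling, type-locality anchors
    label_of = {sp: f"Simulus {sp}" for sp in species}
    true_labels: dict[str, str] = {}
    observed_labels: dict[str, str] = {}
    records = []
    for sp in species:
        for k, sid in enumerate(specimen_ids[sp]):
            true_labels[sid] = label_of[sp]
            observed = label_of[sp]
            is_type = k == 0  # type-locality samples are reliably identified
            if (
                not is_type
                and config.n_species > 1
                and rng.random() < config.mislabel_rate
            ):
                others = [s for s in species if s != sp]
                observed = label_of[others[int(rng.integers(len(others)))]]
            observed_labels[sid] = observed
            region = species_regions[sp][int(rng.integers(len(species_regions[sp])))]
            records.append(
                SequenceRecord(
                    specimen_id=sid,
                    sequence=sequences[sid],
                    morphospecies_label=observed,
                    locality=region,
                    regions=frozenset({region}),
                    is_type_locality=is_type,
                    source="synthetic",
                )
            )

    alignment = Alignment(tuple(records))
    truth = SimulationTruth(
        true_partition=Partition.from_sets(
            alignment.ids, [specimen_ids[sp] for sp in species], method="truth"
        ),
        species_tree_newick=species_newick,
        gene_tree_newick=gene_newick,
        true_labels=true_labels,
        observed_labels=observed_labels,
        species_regions=species_regions,
        config=config,
    )
    return alignment, truth


def simulate_to_files(config: SimConfig, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write FASTA + metadata TSV + truth JSON (+ trees inside the JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignment, truth = simulate(config)
    fasta = outdir / "simulated.fasta"
    meta = outdir / "simulated.tsv"
    truth_path = outdir / "truth.json"
    write_fasta(alignment, fasta)
    write_metadata(alignment, meta)
    truth.write_json(truth_path)
    return fasta, meta, truth_path


@dataclass(frozen=True)
class RecoveryScore:
    exact_count_match: bool
    adjusted_rand: float
    split_errors: int  # true species split over several estimated OTUs
    merge_errors: int  # estimated OTUs lumping several true species


def score_recovery(estimated: Partition, truth: Partition) -> RecoveryScore:
    """Compare an estimated partition against simulation truth."""
    if set(estimated.ids) != set(truth.ids):
        raise ValueError("partitions cover different specimens")
    order = truth.ids
    est = estimated.assignment
    tru = truth.assignment
    est_vec = [est[s] for s in order]
    tru_vec = [tru[s] for s in order]
    ari = float(adjusted_rand_score(tru_vec, est_vec))
    splits = sum(
        1 for g in truth.as_sets() if len({est[s] for s in g}) > 1
    )
    merges = sum(
        1 for g in estimated.as_sets() if len({tru[s] for s in g}) > 1
    )
    return RecoveryScore(
        exact_count_match=estimated.n_otus == truth.n_otus,
        adjusted_rand=ari,
        split_errors=splits,
        merge_errors=merges,
    )
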