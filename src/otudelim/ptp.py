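"""Poisson-tree-processes (PTP) species delimitation.

PTP models the number of substitutions along each branch of a rooted gene
tree as one of two exponential processes: *speciation* branches (between
species) with rate lambda_s and *coalescent* branches (within species) with
rate lambda_c.  A delimitation is encoded by the set S of internal
"speciation" nodes, which must be a rooted ancestral set (a node can be in
S only if its parent is); the species are then the maximal subtrees hanging
below S, i.e. all of whose internal edges are coalescent-class.  An edge is
speciation-class exactly when its parent node is in S; the empty S is the
single-species state.

Rates are profiled analytically at their ML values (lambda-hat = 1/mean
branch length per class), so the log-likelihood of a labeling is

    sum over classes of  n * ln(n / sum_b) - n

with n edges of total length sum_b in the class.  The ML search enumerates
every valid S exhaustively on small trees and hill-climbs with random
restarts on larger ones; the Bayesian variant (bPTP) runs a Metropolis
sampler over S with single-node flip proposals and a uniform prior,
reporting the best partition seen and posterior support per OTU.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import dendropy
import numpy as np

from .gap_partition import Partition
from .seqdata import resolve_polytomies

log = logging.getLogger(__name__)

_ZERO_TERMINAL = 1e-9  # exponential density is undefined at zero mean

# Branches at or below this length carry essentially no substitutions and are
# excluded from the likelihood (both classes), the same guard multi-rate PTP
# implementations apply: without it, a class of near-zero edges has an
# unbounded exponential likelihood and the ML solution shatters clusters of
# identical sequences into singletons.
DEFAULT_MIN_BRANCH = 1e-4


class _IndexedTree:
    """Array-backed rooted binary tree for fast PTP state evaluation."""

    def __init__(self, tree: dendropy.Tree, min_branch: float = DEFAULT_MIN_BRANCH):
        work = tree.clone(depth=1)
        n_resolved = resolve_polytomies(work)
        if n_resolved:
            log.info("PTP input tree had polytomies; resolved with zero-length edges")
        nodes = list(work.preorder_node_iter())
        self.n = len(nodes)
        index = {id(nd): k for k, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=np.int64)
        self.children: list[tuple[int, ...]] = [()] * self.n
        self.edge_len = np.zeros(self.n)
        self.leaf_label: list[str | None] = [None] * self.n
        for k, nd in enumerate(nodes):
            kids = nd.child_nodes()
            self.children[k] = tuple(index[id(c)] for c in kids)
            for c in kids:
                self.parent[index[id(c)]] = k
            if nd is not work.seed_node:
                self.edge_len[k] = float(nd.edge.length or 0.0)
            if not kids:
                self.leaf_label[k] = nd.taxon.label
                if self.edge_len[k] == 0.0:
                    self.edge_len[k] = _ZERO_TERMINAL
        self.min_branch = min_branch
        self.counted = self.edge_len > min_branch
        self.counted[0] = False  # root has no edge
        self.internal = np.array(
            [k for k in range(self.n) if self.children[k]], dtype=np.int64
        )
        self.leaves = [k for k in range(self.n) if not self.children[k]]
        # leaf labels under each node, in preorder
        self.clade: list[list[str]] = [[] for _ in range(self.n)]
        for k in range(self.n - 1, -1, -1):
            if self.leaf_label[k] is not None:
                self.clade[k] = [self.leaf_label[k]]
            else:
                self.clade[k] = [x for c in self.children[k] for x in self.clade[c]]
        self.total_length = float(self.edge_len[self.counted].sum())

    def labels(self) -> tuple[str, ...]:
        return tuple(self.clade[0])

    def partition_of(self, in_s: np.ndarray) -> Partition:
        """Species = maximal subtrees below the speciation set."""
        if not in_s.any():
            return Partition.from_sets(self.labels(), [self.clade[0]], method="ptp")
        groups = []
        for k in range(self.n):
            p = self.parent[k]
            if not in_s[k] and p >= 0 and in_s[p]:
                groups.append(self.clade[k])
        return Partition.from_sets(self.labels(), groups, method="ptp")

    def class_sums(self, in_s: np.ndarray) -> tuple[int, float, int, float]:
        """(n_spec, sum_spec, n_coal, sum_coal) over counted non-root edges."""
        mask = np.zeros(self.n, dtype=bool)
        nonroot = self.parent >= 0
        mask[nonroot] = in_s[self.parent[nonroot]]
        spec = mask & self.counted
        coal = ~mask & self.counted
        return (
            int(spec.sum()),
            float(self.edge_len[spec].sum()),
            int(coal.sum()),
            float(self.edge_len[coal].sum()),
        )


def _class_ll(n: int, total: float) -> float:
    return n * math.log(n / total) - n if n else 0.0


def loglik_from_sums(ns: int, ss: float, nc: int, sc: float) -> float:
    """Profiled two-class exponential log-likelihood.

    A class whose edges sum to zero length has an undefined rate and is
    collapsed into the other class.
    """
    if ns and ss == 0.0:
        nc, sc, ns, ss = nc + ns, sc, 0, 0.0
    if nc and sc == 0.0:
        ns, ss, nc, sc = ns + nc, ss, 0, 0.0
    if (ns and ss == 0.0) or (nc and sc == 0.0):
        return float("-inf")  # every edge has zero length
    return _class_ll(ns, ss) + _class_ll(nc, sc)


@dataclass(frozen=True)
class PTPModel:
    """A delimitation and its profiled rates on a fixed rooted tree."""

    speciation_clades: frozenset[frozenset[str]]  # leaf sets under S-nodes
    lambda_s: float | None
    lambda_c: float | None
    loglik: float
    n_species: int


@dataclass(frozen=True)
class MCMCSettings:
    generations: int = 500_000
    thin: int = 100
    burnin_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.generations >= self.thin >= 1):
            raise ValueError("need generations >= thin >= 1")
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must be in [0, 1)")


@dataclass(frozen=True)
class BPTPResult:
    ml_partition: Partition
    ml_model: PTPModel
    posterior_mean_n_species: float
    posterior_mode_n_species: int
    support: dict[frozenset[str], float]
    acceptance_rate: float
    n_samples: int
    n_species_trace: tuple[int, ...]
    warnings: tuple[str, ...] = ()


def ptp_loglik(tree: dendropy.Tree, speciation_clades) -> float:
    """Log-likelihood of the delimitation given by ``speciation_clades``.

    ``speciation_clades`` identifies the S-nodes by the leaf set each
    subtends (stable across tree representations).
    """
    it = _IndexedTree(tree)
    want = {frozenset(c) for c in speciation_clades}
    in_s = np.zeros(it.n, dtype=bool)
    for k in it.internal:
        if frozenset(it.clade[k]) in want:
            in_s[k] = True
    found = {frozenset(it.clade[k]) for k in it.internal if in_s[k]}
    if found != want:
        raise ValueError("speciation clades do not match internal nodes of the tree")
    _check_ancestral(it, in_s)
    return loglik_from_sums(*it.class_sums(in_s))


def _check_ancestral(it: _IndexedTree, in_s: np.ndarray) -> None:
    for k in it.internal:
        if in_s[k] and it.parent[k] >= 0 and not in_s[it.parent[k]]:
            raise ValueError("speciation nodes must form a rooted ancestral set")


def _model(it: _IndexedTree, in_s: np.ndarray) -> PTPModel:
    ns, ss, nc, sc = it.class_sums(in_s)
    return PTPModel(
        speciation_clades=frozenset(
            frozenset(it.clade[k]) for k in it.internal if in_s[k]
        ),
        lambda_s=(ns / ss) if ns and ss > 0 else None,
        lambda_c=(nc / sc) if nc and sc > 0 else None,
        loglik=loglik_from_sums(ns, ss, nc, sc),
        n_species=it.partition_of(in_s).n_otus,
    )


def enumerate_states(it: _IndexedTree):
    """Yield every valid speciation set as a boolean array (exhaustive)."""

    def rec(v: int):
        if not it.children[v]:
            yield ()
            return
        yield ()  # v not in S: nothing below may be either
        kids = it.children[v]
        sub = [list(rec(c)) for c in kids]
        for combo in product(*sub):
            yield (v,) + tuple(x for part in combo for x in part)

    for nodes in rec(0):
        in_s = np.zeros(it.n, dtype=bool)
        if nodes:
            in_s[list(nodes)] = True
        yield in_s


def _valid_toggle(it: _IndexedTree, in_s: np.ndarray, v: int) -> bool:
    if in_s[v]:
        return not any(in_s[c] for c in it.children[v])
    p = it.parent[v]
    return p < 0 or bool(in_s[p])


def _toggle_delta(it, in_s, sums, v):
    """Class sums after toggling v (edges to v's children switch class)."""
    ns, ss, nc, sc = sums
    kids = [c for c in it.children[v] if it.counted[c]]
    lengths = sum(it.edge_len[c] for c in kids)
    k = len(kids)
    if in_s[v]:  # remove: children edges speciation -> coalescent
        return ns - k, ss - lengths, nc + k, sc + lengths
    return ns + k, ss + lengths, nc - k, sc - lengths


def ptp_ml_search(
    tree: dendropy.Tree,
    exhaustive_max_leaves: int = 12,
    restarts: int = 16,
    seed: int = 0,
    null_penalty: float = 1.0,
) -> tuple[Partition, PTPModel]:
    """Maximum-likelihood PTP delimitation.

    Exhaustive over all valid speciation sets up to
    ``exhaustive_max_leaves`` leaves; otherwise greedy single-flip
    hill-climbing from deterministic (empty/full) plus seeded random starts.

    The two-class model carries one parameter more than the single-rate
    null; unless the best delimitation beats the null by more than
    ``null_penalty`` log-likelihood units (1.0 = the AIC margin for one
    parameter) the single-species partition is returned instead, which
    keeps one tight coalescent cluster from being split on noise.
    """
    it = _IndexedTree(tree)
    if len(it.leaves) < 2:
        raise ValueError("PTP needs >= 2 leaves")
    if it.total_length <= 0:
        log.warning("tree has zero total length; returning one species")
        in_s = np.zeros(it.n, dtype=bool)
        return it.partition_of(in_s), _model(it, in_s)

    if len(it.leaves) <= exhaustive_max_leaves:
        best = None
        best_ll = -math.inf
        for in_s in enumerate_states(it):
            ll = loglik_from_sums(*it.class_sums(in_s))
            if ll > best_ll:
                best_ll, best = ll, in_s
        return _with_null_check(it, best, best_ll, null_penalty)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(it.n, dtype=bool)]
    full = np.zeros(it.n, dtype=bool)
    full[it.internal] = True
    starts.append(full)
    for _ in range(restarts):
        p = rng.uniform(0.2, 0.8)
        s = np.zeros(it.n, dtype=bool)
        for v in it.internal:  # preorder: parent decided before child
            par = it.parent[v]
            if par < 0 or s[par]:
                s[v] = rng.random() < p
        starts.append(s)

    best = None
    best_ll = -math.inf
    for s0 in starts:
        in_s = s0.copy()
        sums = it.class_sums(in_s)
        ll = loglik_from_sums(*sums)
        improved = True
        while improved:
            improved = False
            cand_v, cand_ll, cand_sums = -1, ll, None
            for v in it.internal:
                if not _valid_toggle(it, in_s, v):
                    continue
                nsums = _toggle_delta(it, in_s, sums, v)
                nll = loglik_from_sums(*nsums)
                if nll > cand_ll + 1e-12:
                    cand_v, cand_ll, cand_sums = v, nll, nsums
            if cand_v >= 0:
                in_s[cand_v] = not in_s[cand_v]
                ll, sums = cand_ll, cand_sums
                improved = True
        if ll > best_ll:
            best_ll, best = ll, in_s.copy()
    return _with_null_check(it, best, best_ll, null_penalty)


def _with_null_check(it, best, best_ll, null_penalty):
    null = np.zeros(it.n, dtype=bool)
    null_ll = loglik_from_sums(*it.class_sums(null))
    if best_ll - null_ll <= null_penalty:
        return it.partition_of(null), _model(it, null)
    return it.partition_of(best), _model(it, best)


def bptp_mcmc(tree: dendropy.Tree, settings: MCMCSettings | None = None) -> BPTPResult:
    """Metropolis sampler over valid speciation sets (uniform prior).

    Single-node flip proposals; the proposal kernel is symmetric so the
    acceptance ratio is the likelihood ratio.  Reports the highest-
    likelihood state encountered anywhere in the chain, the posterior mean
    and mode of the species count, and per-OTU support for the ML
    partition (fraction of retained samples in which that exact member set
    is delimited as one species).  Fully reproducible given the seed.
    """
    settings = settings or MCMCSettings()
    it = _IndexedTree(tree)
    if len(it.leaves) < 2:
        raise ValueError("PTP needs >= 2 leaves")
    rng = np.random.default_rng(settings.seed)
    internal = it.internal
    in_s = np.zeros(it.n, dtype=bool)
    sums = it.class_sums(in_s)
    ll = loglik_from_sums(*sums)
    best_s, best_ll = in_s.copy(), ll

    gens = settings.generations
    picks = rng.integers(0, len(internal), size=gens)
    unif = rng.random(size=gens)
    accepted = 0
    kept_parts: list[frozenset[frozenset[str]]] = []
    kept_n: list[int] = []
    burnin_end = int(gens * settings.burnin_fraction)
    for g in range(gens):
        v = internal[picks[g]]
        if _valid_toggle(it, in_s, v):
            nsums = _toggle_delta(it, in_s, sums, v)
            nll = loglik_from_sums(*nsums)
            if nll >= ll or unif[g] < math.exp(nll - ll):
                in_s[v] = not in_s[v]
                sums, ll = nsums, nll
                accepted += 1
                if ll > best_ll:
                    best_ll, best_s = ll, in_s.copy()
        if g >= burnin_end and (g + 1) % settings.thin == 0:
            part = it.partition_of(in_s)
            kept_parts.append(part.as_sets())
            kept_n.append(part.n_otus)

    acc_rate = accepted / gens
    warnings = []
    if acc_rate < 0.01 or acc_rate > 0.99:
        warnings.append(
            f"possible non-mixing chain: acceptance rate {acc_rate:.3f}"
        )
        log.warning(warnings[-1])

    ml_partition = it.partition_of(best_s)
    ml_model = _model(it, best_s)
    support = {}
    for otu in ml_partition.as_sets():
        hits = sum(1 for p in kept_parts if otu in p)
        support[otu] = hits / len(kept_parts) if kept_parts else float("nan")
    counts = np.bincount(kept_n) if kept_n else np.array([0])
    return BPTPResult(
        ml_partition=ml_partition,
        ml_model=ml_model,
        posterior_mean_n_species=float(np.mean(kept_n)) if kept_n else float("nan"),
        posterior_mode_n_species=int(np.argmax(counts)),
        support=support,
        acceptance_rate=acc_rate,
        n_samples=len(kept_n),
        n_species_trace=tuple(kept_n),
        warnings=tuple(warnings),
    )
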