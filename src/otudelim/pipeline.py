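"""End-to-end orchestration: distances -> guide tree -> both delimiters ->
reconciliation -> run report.

Every stage is deterministic given the master seed; per-stage seeds are
expanded from it with fixed offsets so re-running a recorded report
reproduces identical outputs.  Artifacts are written with a stable filename
scheme when an output directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import distances, gap_partition, genetree, ptp, seqdata
from . import reconcile as reconcile_mod

log = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed expansion from one master seed."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % _SEED_MOD
    return (master * 7919 + h) % _SEED_MOD


@dataclass(frozen=True)
class RunReport:
    n_specimens: int
    alignment_length: int
    input_digest: str
    seed: int
    settings: dict
    otu_counts: dict  # gap_best, gap_at_t_low, ptp_ml, bptp_mode (optional)
    final_species_count: int
    flag_tallies: dict
    warnings: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "n_specimens": self.n_specimens,
            "alignment_length": self.alignment_length,
            "input_digest": self.input_digest,
            "seed": self.seed,
            "settings": self.settings,
            "otu_counts": self.otu_counts,
            "final_species_count": self.final_species_count,
            "flag_tallies": self.flag_tallies,
            "warnings": list(self.warnings),
        }
        return json.dumps(payload, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass(frozen=True)
class PipelineResult:
    report: RunReport
    table: reconcile_mod.SpeciesHypothesisTable
    dm: distances.DistanceMatrix
    guide_tree: dendropy.Tree
    gap_result: gap_partition.GapResult
    gap_at_t_low: gap_partition.Partition
    ptp_partition: gap_partition.Partition
    ptp_model: ptp.PTPModel
    bptp: ptp.BPTPResult | None = None


def run_all(
    alignment: seqdata.Alignment,
    guide_tree: dendropy.Tree | None = None,
    config: reconcile_mod.ReconcileConfig | None = None,
    mcmc: ptp.MCMCSettings | None = None,
    run_bptp: bool = False,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole delimitation pipeline on one alignment.

    ``guide_tree`` (an externally built ML tree) is preferred when given;
    otherwise a midpoint-rooted neighbor-joining tree built from the K2P
    matrix is used.  ``run_bptp`` switches the Bayesian PTP sampler on in
    addition to the ML search.
    """
    config = config or reconcile_mod.ReconcileConfig()
    warnings: list[str] = []

    dm = distances.distance_matrix(alignment)
    if guide_tree is None:
        if len(dm) == 2:
            tree = genetree.two_taxon_tree(dm)
        else:
            tree = genetree.midpoint_root(genetree.neighbor_joining(dm))
    else:
        tree = guide_tree.clone(depth=1)
        if seqdata.resolve_polytomies(tree):
            warnings.append("external guide tree had polytomies; resolved")
        tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if tree_leaves != set(alignment.ids):
            raise ValueError(
                "guide tree leaves do not match alignment ids: "
                f"{sorted(tree_leaves ^ set(alignment.ids))}"
            )

    p_gap_t = gap_partition.partition_at_threshold(dm, config.t_low)
    if len(dm) >= 3:
        gap_result = gap_partition.rank_partitions(dm)
        if gap_result.no_barcode_gap:
            warnings.append("no barcode gap detected; gap partition degenerate")
        p_gap = gap_result.best
    else:  # degenerate two-specimen dataset: threshold rule only
        score = gap_partition.PartitionScore(
            partition=p_gap_t,
            threshold=config.t_low,
            gap_width=float("nan"),
            relative_gap=float("nan"),
            rank=1,
        )
        gap_result = gap_partition.GapResult(scores=(score,))
        p_gap = p_gap_t

    p_ptp, model = ptp.ptp_ml_search(tree, seed=stage_seed(seed, "ptp_ml"))
    bptp_result = None
    if run_bptp:
        settings = mcmc or ptp.MCMCSettings(seed=stage_seed(seed, "bptp"))
        bptp_result = ptp.bptp_mcmc(tree, settings)
        warnings.extend(bptp_result.warnings)

    table = reconcile_mod.reconcile(p_gap, p_ptp, tree, dm, alignment, config)

    tallies: dict[str, int] = {}
    for h in table.hypotheses:
        for fl in h.status_flags:
            tallies[fl] = tallies.get(fl, 0) + 1
    counts = {
        "gap_best": p_gap.n_otus,
        "gap_at_t_low": p_gap_t.n_otus,
        "ptp_ml": p_ptp.n_otus,
    }
    if bptp_result is not None:
        counts["bptp_posterior_mode"] = bptp_result.posterior_mode_n_species
    report = RunReport(
        n_specimens=len(alignment),
        alignment_length=alignment.length,
        input_digest=table.provenance["input_digest"],
        seed=seed,
        settings={
            "t_low": config.t_low,
            "t_strong": config.t_strong,
            "guide_tree": "external" if guide_tree is not None else "nj_midpoint",
            "bptp": run_bptp,
        },
        otu_counts=counts,
        final_species_count=table.n_species,
        flag_tallies=tallies,
        warnings=tuple(warnings),
    )
    result = PipelineResult(
        report=report,
        table=table,
        dm=dm,
        guide_tree=tree,
        gap_result=gap_result,
        gap_at_t_low=p_gap_t,
        ptp_partition=p_ptp,
        ptp_model=model,
        bptp=bptp_result,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.dm.write_phylip(outdir / "distances.phylip.tsv")
    result.dm.write_long(outdir / "distances.long.tsv")
    seqdata.write_newick(result.guide_tree, outdir / "guide_tree.nwk")
    result.gap_result.write_tsv(outdir / "gap_ranked.tsv")
    result.gap_result.best.write_tsv(outdir / "partition_gap.tsv")
    result.ptp_partition.write_tsv(outdir / "partition_ptp.tsv")
    result.table.write_tsv(outdir / "species_hypotheses.tsv")
    result.table.write_json(outdir / "species_hypotheses.json")
    result.report.write(outdir / "run_report.json")
    if result.bptp is not None:
        rows = [
            {"otu_members": ",".join(sorted(k)), "posterior_support": v}
            for k, v in sorted(
                result.bptp.support.items(), key=lambda kv: sorted(kv[0])[0]
            )
        ]
        pd.DataFrame(rows).to_csv(outdir / "bptp_support.tsv", sep="\t", index=False)


def summarize_divergences(
    table: reconcile_mod.SpeciesHypothesisTable,
    dm: distances.DistanceMatrix,
    by_label: bool = False,
) -> pd.DataFrame:
    """Min/mean/max K2P (percent) for every hypothesis pair (or label pair)."""
    if by_label:
        groups: dict[str, list[str]] = {}
        for h in table.hypotheses:
            groups.setdefault(h.assigned_name, []).extend(h.members)
        items = sorted(groups.items())
    else:
        items = [(h.otu_id, list(h.members)) for h in table.hypotheses]
    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (ka, ga), (kb, gb) = items[i], items[j]
            d_min, d_mean, d_max = dm.group_stats(ga, gb)
            rows.append(
                {
                    "group1": ka,
                    "group2": kb,
                    "min_pct": round(d_min * 100, 4),
                    "mean_pct": round(d_mean * 100, 4),
                    "max_pct": round(d_max * 100, 4),
                }
            )
    return pd.DataFrame(rows, columns=["group1", "group2", "min_pct", "mean_pct", "max_pct"])
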