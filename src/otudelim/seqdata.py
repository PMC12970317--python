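"""Domain types and I/O for barcode alignments, specimen metadata and trees.

The pipeline works from three plain-text inputs: an aligned FASTA of
single-locus (COI-style) sequences, a tab-separated specimen metadata table,
and optionally a rooted newick guide tree.  Specimens carry a morphospecies
label (the name under which the sequence was deposited), a locality, one or
more biogeographic region codes, and a flag marking samples collected at a
species' type locality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

# Closed vocabulary of biogeographic provinces for shelf-dwelling benthic
# fishes: Greater Caribbean, Brazilian provinces, tropical East Atlantic,
# East China Sea, South China Sea, Sahul Shelf + Australia, Central West
# Pacific, Indian Ocean.
DEFAULT_REGIONS = frozenset({"GC", "BP", "TEA", "ECS", "SCS", "SAS", "CWP", "IO"})
UNKNOWN_REGION = "UNKNOWN"

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")

SOURCES = ("novel", "genbank", "bold", "synthetic")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, bad symbols)."""


class MetadataError(ValueError):
    """Raised for malformed metadata tables (undeclared region codes etc.)."""


def parse_region(code: str, extra_regions: Iterable[str] = ()) -> str:
    """Validate a single region code against the closed vocabulary.

    Empty/missing codes map to UNKNOWN.  Codes outside the default
    vocabulary must be declared in ``extra_regions`` or a
    :class:`MetadataError` is raised; this keeps the sympatry predicate
    decidable.
    """
    code = (code or "").strip()
    if not code or code.upper() == UNKNOWN_REGION:
        return UNKNOWN_REGION
    code = code.upper()
    if code in DEFAULT_REGIONS or code in {c.upper() for c in extra_regions}:
        return code
    raise MetadataError(
        f"region code {code!r} is not in the region vocabulary "
        f"{sorted(DEFAULT_REGIONS)} and was not declared as an extension"
    )


def parse_regions(text: str, extra_regions: Iterable[str] = ()) -> frozenset[str]:
    """Parse a (possibly multi-valued, comma/semicolon separated) region field."""
    parts = [p for chunk in (text or "").split(";") for p in chunk.split(",")]
    codes = {parse_region(p, extra_regions) for p in parts if p.strip()} or {UNKNOWN_REGION}
    if len(codes) > 1:
        codes.discard(UNKNOWN_REGION)
    return frozenset(codes)


@dataclass(frozen=True)
class SequenceRecord:
    specimen_id: str
    sequence: str
    morphospecies_label: str = ""
    locality: str = ""
    regions: frozenset[str] = frozenset({UNKNOWN_REGION})
    is_type_locality: bool = False
    source: str = "novel"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise AlignmentError("specimen_id must be non-empty")
        if not self.sequence:
            raise AlignmentError(f"empty sequence for {self.specimen_id!r}")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise AlignmentError(
                f"record {self.specimen_id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )
        if self.source not in SOURCES:
            raise AlignmentError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length collection of sequence records."""

    records: tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        length = len(self.records[0].sequence)
        for i, rec in enumerate(self.records, start=1):
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"record {i} ({rec.specimen_id!r}) has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise AlignmentError(f"duplicate specimen ids: {dupes}")
        object.__setattr__(self, "length", length)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.specimen_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, specimen_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)

    def with_metadata(self, meta: Mapping[str, dict]) -> "Alignment":
        """Attach metadata rows to records; ids without a row keep defaults.

        The join is total over alignment ids: no aligned specimen is ever
        dropped; missing regions fall back to UNKNOWN.
        """
        new = []
        for rec in self.records:
            row = meta.get(rec.specimen_id)
            new.append(replace(rec, **row) if row else rec)
        return Alignment(tuple(new))


def read_fasta(path: str | Path, source: str = "novel") -> Alignment:
    """Read an aligned FASTA; ids are the first whitespace token of each header.

    Sequences are uppercased.  Ragged records and duplicate ids raise
    :class:`AlignmentError` naming the offender.
    """
    records = tuple(
        SequenceRecord(specimen_id=rec.id, sequence=str(rec.seq).upper(), source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    )
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in alignment.records:
            fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")


METADATA_COLUMNS = ("id", "species", "locality", "region", "type_locality")


def read_metadata(
    path: str | Path,
    alignment: Alignment | None = None,
    extra_regions: Iterable[str] = (),
) -> dict[str, dict]:
    """Read the specimen metadata TSV into per-id field dicts.

    Expected header columns: id, species, locality, region, type_locality.
    Rows whose id is absent from ``alignment`` (when given) are skipped with
    a warning.  Region codes outside the vocabulary raise
    :class:`MetadataError`; empty regions become UNKNOWN and empty
    type_locality becomes False.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table lacks required columns: {missing}")
    known = set(alignment.ids) if alignment is not None else None
    meta: dict[str, dict] = {}
    for _, row in df.iterrows():
        sid = row["id"].strip()
        if known is not None and sid not in known:
            log.warning("metadata id %r not in alignment; row skipped", sid)
            continue
        tl = row["type_locality"].strip().lower()
        meta[sid] = {
            "morphospecies_label": row["species"].strip(),
            "locality": row["locality"].strip(),
            "regions": parse_regions(row["region"], extra_regions),
            "is_type_locality": tl in {"1", "true", "yes"},
        }
    return meta


def write_metadata(alignment: Alignment, path: str | Path) -> None:
    rows = []
    for rec in alignment.records:
        region = ",".join(sorted(rec.regions - {UNKNOWN_REGION}))
        rows.append(
            {
                "id": rec.specimen_id,
                "species": rec.morphospecies_label,
                "locality": rec.locality,
                "region": region,
                "type_locality": int(rec.is_type_locality),
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


# --- trees ----------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; leaves must be labeled, polytomies are accepted."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("newick tree contains an unlabeled leaf")
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def resolve_polytomies(tree: dendropy.Tree, rng=None) -> int:
    """Resolve polytomies in place with zero-length edges; returns the count.

    Resolution order is dendropy's deterministic default (no rng), so the
    same input always yields the same binary refinement.  Needed because the
    Poisson-tree-processes delimiter assumes a binary tree.
    """
    n_poly = sum(
        1 for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2
    )
    if n_poly:
        tree.resolve_polytomies(rng=rng)
        for edge in tree.preorder_edge_iter():
            if edge.length is None and edge.head_node is not tree.seed_node:
                edge.length = 0.0
        log.info("resolved %d polytomies with zero-length edges", n_poly)
    return n_poly
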