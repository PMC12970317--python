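"""Kimura two-parameter (K2P) pairwise distances.

The K2P model corrects observed sequence differences separately for
transitions (A<->G, C<->T; proportion P) and transversions (proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Distances are substitutions/site; the reporting layer converts to percent.
Columns where either sequence carries a gap, N or any ambiguity code are
excluded pair by pair (pairwise deletion) -- standard practice for
mixed-provenance barcode data.  Pairs whose divergence saturates the
correction (log argument <= 0) are flagged and assigned a configurable cap
so the matrix stays finite; they are excluded from barcode-gap statistics
downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import Alignment

log = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i  # A=0 C=1 G=2 T=3; purines even, pyrimidines odd


class SaturationError(ValueError):
    """K2P correction undefined: observed divergence too high."""


class NoComparableSitesError(ValueError):
    """No alignment column has unambiguous bases in both sequences."""


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (255 = gap/ambiguity)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SitePairCounts:
    n_compared: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.n_compared:
            raise ValueError("more substitutions than compared sites")

    @property
    def P(self) -> float:
        return self.transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.n_compared


def count_site_pairs(seq_a: str, seq_b: str, pair_ids=("A", "B")) -> SitePairCounts:
    """Count comparable sites, transitions and transversions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise NoComparableSitesError(
            f"no comparable sites between {pair_ids[0]!r} and {pair_ids[1]!r}"
        )
    diff = valid & (a != b)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    return SitePairCounts(n_compared=n, transitions=ts, transversions=int(diff.sum()) - ts)


def k2p(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance from site-pair counts (subs/site)."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair counts retained.

    ``saturated`` marks pairs whose correction failed (or that had no
    comparable sites); their ``d`` holds the connectivity cap, and they are
    skipped when barcode-gap statistics are computed.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    n_compared: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index(id_a), self.index(id_b)])

    def condensed(self, include_saturated: bool = True) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.d[iu]
        if not include_saturated:
            vals = vals[~self.saturated[iu]]
        return vals

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = np.array([self.index(i) for i in ids])
        sel = np.ix_(idx, idx)
        return DistanceMatrix(
            ids=tuple(ids),
            d=self.d[sel].copy(),
            n_compared=self.n_compared[sel].copy(),
            P=self.P[sel].copy(),
            Q=self.Q[sel].copy(),
            saturated=self.saturated[sel].copy(),
        )

    def group_stats(self, ids_a, ids_b) -> tuple[float, float, float]:
        """(min, mean, max) distance between two specimen groups."""
        ia = np.array([self.index(i) for i in ids_a])
        ib = np.array([self.index(i) for i in ids_b])
        vals = self.d[np.ix_(ia, ib)].ravel()
        return float(vals.min()), float(vals.mean()), float(vals.max())

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{sid}\t{row}\n")

    def write_long(self, path: str | Path) -> None:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "n_compared": int(self.n_compared[i, j]),
                        "P": self.P[i, j],
                        "Q": self.Q[i, j],
                        "d": self.d[i, j],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def distance_matrix(alignment: Alignment, saturation_cap: float = 1.0) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion.

    Saturated or incomparable pairs get ``saturation_cap`` as a placeholder
    distance (keeping single-linkage clustering connected) and are marked in
    the ``saturated`` mask; a summary count is logged.
    """
    n = len(alignment)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    enc = np.stack([encode(r.sequence) for r in alignment.records])
    valid = enc < 4
    ncmp = np.zeros((n, n), dtype=np.int64)
    ts_m = np.zeros((n, n), dtype=np.int64)
    tv_m = np.zeros((n, n), dtype=np.int64)
    parity = enc & 1
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        ts = diff & (parity[i] == parity[i + 1 :])
        ncmp[i, i + 1 :] = both.sum(axis=1)
        ts_m[i, i + 1 :] = ts.sum(axis=1)
        tv_m[i, i + 1 :] = diff.sum(axis=1) - ts.sum(axis=1)
    ncmp += ncmp.T
    ts_m += ts_m.T
    tv_m += tv_m.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(ncmp > 0, ts_m / np.maximum(ncmp, 1), np.nan)
        Q = np.where(ncmp > 0, tv_m / np.maximum(ncmp, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    saturated = (ncmp == 0) | (w1 <= 0) | (w2 <= 0) | ~np.isfinite(d)
    np.fill_diagonal(saturated, False)
    d = np.where(saturated, saturation_cap, d)
    np.fill_diagonal(d, 0.0)
    n_sat = int(saturated.sum() // 2)
    if n_sat:
        log.warning(
            "%d pairs saturated/incomparable; capped at %.3f subs/site",
            n_sat,
            saturation_cap,
        )
    d = (d + d.T) / 2.0 + 0.0  # exact symmetry; +0.0 normalizes -0.0
    return DistanceMatrix(
        ids=alignment.ids,
        d=d,
        n_compared=ncmp,
        P=np.nan_to_num(P),
        Q=np.nan_to_num(Q),
        saturated=saturated,
    )
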