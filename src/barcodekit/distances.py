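"""Uncorrected p-distances and K2P distances with pairwise deletion.

A column contributes to a pair's comparison only when both sequences carry
an unambiguous base (A/C/G/T) there; gap and ambiguity columns are excluded
per pair ("pairwise deletion"). ``complete`` deletion (drop a column for
all pairs if any sequence is gapped/ambiguous there) is available for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._alphabet import BASES, TRANSITIONS
from .seqio import Alignment, SeqRecord

__all__ = [
    "DistanceMatrix",
    "DistancePartition",
    "RegionComparison",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "partition_distances",
    "summarize",
    "compare_regions",
    "SaturatedDistanceError",
]

GAP_POLICIES = ("pairwise", "complete")


class SaturatedDistanceError(ValueError):
    """K2P logarithm domain violation: sequences too diverged."""


def _comparable_mask(a: str, b: str) -> list[bool]:
    return [x in BASES and y in BASES for x, y in zip(a, b)]


def p_distance(a: str, b: str, gap_policy: str = "pairwise") -> tuple[float, int, int]:
    """Uncorrected p-distance between two aligned residue strings.

    Returns ``(p, ndiff, ncomp)``. With ``ncomp == 0`` the distance is
    undefined and ``p`` is NaN.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    ndiff = ncomp = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            ncomp += 1
            if x != y:
                ndiff += 1
    p = ndiff / ncomp if ncomp else math.nan
    return p, ndiff, ncomp


def k2p_distance(a: str, b: str, gap_policy: str = "pairwise") -> float:
    """Kimura 2-parameter distance: -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are transition and transversion proportions over compared
    sites. Raises :class:`SaturatedDistanceError` outside the log domain.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    ntrans = ntransv = ncomp = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            ncomp += 1
            if x != y:
                if frozenset((x, y)) in TRANSITIONS:
                    ntrans += 1
                else:
                    ntransv += 1
    if ncomp == 0:
        return math.nan
    P, Q = ntrans / ncomp, ntransv / ncomp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair site counts."""

    ids: list[str]
    p: np.ndarray       # proportions, NaN where ncomp == 0
    ndiff: np.ndarray   # differing-site counts
    ncomp: np.ndarray   # compared-site counts

    def __post_init__(self) -> None:
        n = len(self.ids)
        for m in (self.p, self.ndiff, self.ncomp):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        """Pairs with zero comparable sites (undefined distance)."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.ncomp[i, j] == 0:
                    out.append((self.ids[i], self.ids[j]))
        return out

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.p[i, j])

    def to_tsv(self) -> str:
        """Square TSV with id header row/column, 4 decimals."""
        lines = ["\t".join([""] + self.ids)]
        for i, rid in enumerate(self.ids):
            row = [rid] + [
                "NA" if math.isnan(self.p[i, j]) else f"{self.p[i, j]:.4f}"
                for j in range(self.n)
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        """Lower-triangle PHYLIP-style rendering."""
        lines = [f"{self.n}"]
        for i, rid in enumerate(self.ids):
            vals = " ".join(f"{self.p[i, j]:.4f}" for j in range(i))
            lines.append(f"{rid}\t{vals}".rstrip())
        return "\n".join(lines) + "\n"


def _complete_deletion_columns(records: Sequence[SeqRecord]) -> list[int]:
    ncols = len(records[0].residues)
    keep = []
    for c in range(ncols):
        if all(r.residues[c] in BASES for r in records):
            keep.append(c)
    return keep


def distance_matrix(aln: Alignment, gap_policy: str = "pairwise") -> DistanceMatrix:
    """All-pairs uncorrected p-distance matrix for an alignment.

    Pairs with no comparable sites get NaN and are reported via
    ``DistanceMatrix.flagged_pairs``; the matrix is still returned.
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    records = aln.records
    if gap_policy == "complete":
        keep = _complete_deletion_columns(records)
        seqs = ["".join(r.residues[c] for c in keep) for r in records]
    else:
        seqs = [r.residues for r in records]
    n = len(records)
    # encode to integers for vectorized column comparison: ACGT->0..3, other->-1
    lut = np.full(128, -1, dtype=np.int8)
    for k, base in enumerate("ACGT"):
        lut[ord(base)] = k
    enc = np.array([lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs])
    valid = enc >= 0
    p = np.zeros((n, n))
    ndiff = np.zeros((n, n), dtype=np.int64)
    ncomp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ncomp[i, i] = valid[i].sum()
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            nd = int(((enc[i] != enc[j]) & both).sum())
            ncomp[i, j] = ncomp[j, i] = nc
            ndiff[i, j] = ndiff[j, i] = nd
            p[i, j] = p[j, i] = nd / nc if nc else math.nan
    return DistanceMatrix(ids=list(aln.ids), p=p, ndiff=ndiff, ncomp=ncomp)


@dataclass
class DistancePartition:
    """Pairwise distances split by taxonomic relationship.

    Intergeneric pairs (different genus) are by construction also in the
    interspecific list; both conventions are reported.
    """

    intraspecific: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    interspecific: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    intergeneric: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    def values(self, which: str) -> list[float]:
        return [v for _, v in getattr(self, which)]


def partition_distances(
    m: DistanceMatrix, records: Sequence[SeqRecord]
) -> DistancePartition:
    """Partition pairwise distances by species/genus labels.

    NaN (undefined) distances are carried through; species with a single
    sequence contribute no intraspecific values.
    """
    by_id = {r.id: r for r in records}
    for rid in m.ids:
        r = by_id.get(rid)
        if r is None or not r.species or not r.genus:
            raise ValueError(f"record {rid!r} lacks species/genus label")
    part = DistancePartition()
    for i in range(m.n):
        a = by_id[m.ids[i]]
        for j in range(i + 1, m.n):
            b = by_id[m.ids[j]]
            entry = ((a.id, b.id), float(m.p[i, j]))
            if a.species == b.species:
                part.intraspecific.append(entry)
            else:
                part.interspecific.append(entry)
                if a.genus != b.genus:
                    part.intergeneric.append(entry)
    return part


def summarize(values: Iterable[float]) -> tuple[float, float, float, int]:
    """(min, max, mean, n) of a nonempty list of distances; NaNs rejected."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot summarize an empty list")
    if any(math.isnan(v) for v in vals):
        raise ValueError("undefined (NaN) distances in summary input")
    return min(vals), max(vals), sum(vals) / len(vals), len(vals)


@dataclass
class RegionComparison:
    """Per-pair barcode-region vs full-gene distances.

    ``rows``: (id_a, id_b, p_region, ndiff_region, p_full, ndiff_full),
    sorted by p_full - p_region descending.
    """

    rows: list[tuple[str, str, float, int, float, int]]

    def to_tsv(self) -> str:
        header = "id_a\tid_b\tp_region\tndiff_region\tp_full\tndiff_full"
        lines = [header]
        for a, b, pr, nr, pf, nf in self.rows:
            lines.append(f"{a}\t{b}\t{pr:.4f}\t{nr}\t{pf:.4f}\t{nf}")
        return "\n".join(lines) + "\n"


def compare_regions(
    m_region: DistanceMatrix, m_full: DistanceMatrix
) -> RegionComparison:
    """Compare barcode-region distances with full-gene distances per pair."""
    shared = [i for i in m_region.ids if i in set(m_full.ids)]
    if len(shared) < 2:
        raise ValueError("fewer than two shared ids between the two matrices")
    rows = []
    for i, a in enumerate(shared):
        for b in shared[i + 1 :]:
            ri, rj = m_region.ids.index(a), m_region.ids.index(b)
            fi, fj = m_full.ids.index(a), m_full.ids.index(b)
            rows.append(
                (
                    a,
                    b,
                    float(m_region.p[ri, rj]),
                    int(m_region.ndiff[ri, rj]),
                    float(m_full.p[fi, fj]),
                    int(m_full.ndiff[fi, fj]),
                )
            )
    rows.sort(key=lambda r: (r[4] - r[2]), reverse=True)
    return RegionComparison(rows=rows)
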