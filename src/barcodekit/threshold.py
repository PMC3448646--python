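"""Threshold-based species separation statistics.

A species is "separated" at threshold t when its sequences are at least t
away from every other species' sequences (nearest-neighbor criterion,
the default). A barcode-gap criterion (minimum heterospecific distance
strictly greater than the species' own maximum intraspecific distance)
and an all-pairs criterion are available for bracketing, since published
analyses rarely state which convention they used. Ties at exactly p = t
count as separated. Denominators are reported explicitly: fractions are
over all species; intraspecific-overlap counts are over multi-sequence
species only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .distances import DistanceMatrix
from .seqio import SeqRecord

__all__ = [
    "SeparationConfig",
    "SpeciesSeparation",
    "SeparationResult",
    "species_separation",
    "intraspecific_overlap",
    "threshold_sweep",
    "problem_pairs",
]

CRITERIA = ("nearest-neighbor", "all-pairs", "barcode-gap")


@dataclass(frozen=True)
class SeparationConfig:
    t: float = 0.02
    criterion: str = "nearest-neighbor"

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"threshold {self.t} outside [0, 1]")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class SpeciesSeparation:
    species: str
    separated: bool
    nearest_species: str
    nearest_distance: float
    max_intraspecific: float  # 0.0 for single-sequence species


@dataclass
class SeparationResult:
    config: SeparationConfig
    per_species: list[SpeciesSeparation]
    fraction_separated: float
    n_species: int
    overlap_count: int
    n_multiseq_species: int
    problem_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = [
            f"# criterion={self.config.criterion} t={self.config.t}"
            " (coordinates 1-based, closed)",
            "species\tseparated\tnearest_species\tnearest_distance\tmax_intraspecific",
        ]
        for s in self.per_species:
            lines.append(
                f"{s.species}\t{int(s.separated)}\t{s.nearest_species}"
                f"\t{s.nearest_distance:.4f}\t{s.max_intraspecific:.4f}"
            )
        return "\n".join(lines) + "\n"


def _species_of(m: DistanceMatrix, records: Sequence[SeqRecord]) -> list[str]:
    by_id = {r.id: r for r in records}
    labels = []
    for rid in m.ids:
        r = by_id.get(rid)
        if r is None or not r.species:
            raise ValueError(f"record {rid!r} lacks a species label")
        labels.append(r.species)
    return labels


def _heterospecific_minima(
    m: DistanceMatrix, labels: list[str]
) -> tuple[dict[str, tuple[str, float]], dict[str, float]]:
    """Per species: (nearest other species, its distance) and max intra p."""
    nearest: dict[str, tuple[str, float]] = {}
    max_intra: dict[str, float] = {sp: 0.0 for sp in labels}
    for i in range(m.n):
        for j in range(i + 1, m.n):
            d = float(m.p[i, j])
            if math.isnan(d):
                continue
            si, sj = labels[i], labels[j]
            if si == sj:
                if d > max_intra[si]:
                    max_intra[si] = d
                continue
            for a, b in ((si, sj), (sj, si)):
                cur = nearest.get(a)
                if cur is None or d < cur[1]:
                    nearest[a] = (b, d)
    return nearest, max_intra


def species_separation(
    m: DistanceMatrix,
    records: Sequence[SeqRecord],
    cfg: SeparationConfig = SeparationConfig(),
) -> SeparationResult:
    """Evaluate per-species separation at a p-distance threshold."""
    labels = _species_of(m, records)
    species = sorted(set(labels))
    if len(species) < 2:
        raise ValueError("need at least two species")
    nearest, max_intra = _heterospecific_minima(m, labels)
    multiseq = {sp for sp in species if labels.count(sp) >= 2}
    per: list[SpeciesSeparation] = []
    for sp in species:
        nn_sp, nn_d = nearest.get(sp, ("", math.inf))
        if cfg.criterion == "barcode-gap":
            sep = nn_d > max_intra[sp]
        else:  # nearest-neighbor and all-pairs coincide on min distance
            sep = nn_d >= cfg.t
        per.append(
            SpeciesSeparation(
                species=sp,
                separated=sep,
                nearest_species=nn_sp,
                nearest_distance=nn_d,
                max_intraspecific=max_intra[sp],
            )
        )
    frac = sum(s.separated for s in per) / len(species)
    overlap = sum(1 for sp in multiseq if max_intra[sp] >= cfg.t)
    return SeparationResult(
        config=cfg,
        per_species=per,
        fraction_separated=frac,
        n_species=len(species),
        overlap_count=overlap,
        n_multiseq_species=len(multiseq),
        problem_pairs=problem_pairs(m, records),
    )


def intraspecific_overlap(
    m: DistanceMatrix, records: Sequence[SeqRecord], t: float
) -> tuple[int, list[str]]:
    """Species whose maximum intraspecific distance reaches t.

    Returns (count, offending species). The denominator convention is the
    number of species with >= 2 sequences; zero such species is flagged by
    the caller via the empty list.
    """
    labels = _species_of(m, records)
    _, max_intra = _heterospecific_minima(m, labels)
    multiseq = sorted({sp for sp in set(labels) if labels.count(sp) >= 2})
    offenders = [sp for sp in multiseq if max_intra[sp] >= t]
    return len(offenders), offenders


def threshold_sweep(
    m: DistanceMatrix,
    records: Sequence[SeqRecord],
    grid: Sequence[float],
    criterion: str = "nearest-neighbor",
) -> list[tuple[float, float, int]]:
    """(t, fraction_separated, overlap_count) per threshold in the grid."""
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    if list(grid) != sorted(grid):
        raise ValueError("threshold grid must be sorted ascending")
    rows = []
    for t in grid:
        res = species_separation(m, records, SeparationConfig(t=t, criterion=criterion))
        rows.append((t, res.fraction_separated, res.overlap_count))
    return rows


def problem_pairs(
    m: DistanceMatrix,
    records: Sequence[SeqRecord],
    cutoff: float = 0.004,
) -> list[tuple[str, str, float]]:
    """Species pairs whose minimum heterospecific distance falls below cutoff.

    Sorted ascending by distance, then by name for determinism.
    """
    labels = _species_of(m, records)
    if len(set(labels)) < 2:
        raise ValueError("need at least two species")
    best: dict[tuple[str, str], float] = {}
    for i in range(m.n):
        for j in range(i + 1, m.n):
            si, sj = labels[i], labels[j]
            if si == sj:
                continue
            d = float(m.p[i, j])
            if math.isnan(d):
                continue
            key = (min(si, sj), max(si, sj))
            if key not in best or d < best[key]:
                best[key] = d
    out = [(a, b, d) for (a, b), d in best.items() if d < cutoff]
    out.sort(key=lambda r: (r[2], r[0], r[1]))
    return out
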