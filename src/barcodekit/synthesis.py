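"""Synthetic species-structured alignments with known ground truth.

Sequences evolve by substitution only, star-like within species: a
uniform random ancestor, one founder per species, then independent
members per founder. Mutating a site replaces its base by a uniformly
chosen different base, so two lineages that differ from their common
ancestor with per-site probabilities a and b differ from each other with
probability a + b - (4/3)ab. Per-lineage rates are solved from that
identity so realized mean intraspecific and (member-level)
interspecific p-distances both converge to the requested targets.

Problem pairs, gap columns, ambiguity codes and diagnostic characters
are planted afterwards; planted diagnostic sites are protected from all
other noise. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .seqio import Alignment, SeqRecord

__all__ = ["SynthParams", "PlantedCharacter", "SyntheticTruth", "generate"]

_GAP, _AMBIG = -1, -2


@dataclass(frozen=True)
class PlantedCharacter:
    group: str
    kind: str                 # pure | compound_pure | doubly_compound
    columns: tuple[int, ...]  # 1-based alignment columns
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        order = {"pure": 1, "compound_pure": 2, "doubly_compound": 3}.get(self.kind)
        if order is None:
            raise ValueError(f"unknown planted kind {self.kind!r}")
        if len(self.columns) != order or len(self.states) != order:
            raise ValueError(f"{self.kind} needs exactly {order} column(s)/state(s)")
        if len(set(self.columns)) != order:
            raise ValueError("planted columns must be distinct")
        if any(s not in "ACGT" for s in self.states):
            raise ValueError("planted states must be unambiguous bases")


@dataclass(frozen=True)
class SynthParams:
    n_species: int
    seqs_per_species: int | tuple[int, ...]
    ncols: int
    intra_div: float = 0.004
    inter_div: float = 0.08
    n_problem_pairs: int = 0
    problem_p: float = 0.003
    planted_characters: tuple[PlantedCharacter, ...] = ()
    indel_rate: float = 0.0
    ambiguity_rate: float = 0.0
    species_per_genus: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_div < self.inter_div <= 0.75:
            raise ValueError("need 0 <= intra_div < inter_div <= 0.75")
        for rate in (self.indel_rate, self.ambiguity_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_species < 1 or self.ncols < 1:
            raise ValueError("n_species and ncols must be positive")
        if 2 * self.n_problem_pairs > self.n_species:
            raise ValueError("too many problem pairs for the species count")
        seen: dict[int, str] = {}
        for ch in self.planted_characters:
            for col in ch.columns:
                if not 1 <= col <= self.ncols:
                    raise ValueError(f"planted column {col} outside 1..{self.ncols}")
                if col in seen:
                    raise ValueError(
                        f"column {col} used by two planted characters"
                        f" ({seen[col]!r} and {ch.group!r})"
                    )
                seen[col] = ch.group

    def counts(self) -> list[int]:
        if isinstance(self.seqs_per_species, int):
            return [self.seqs_per_species] * self.n_species
        counts = list(self.seqs_per_species)
        if len(counts) != self.n_species:
            raise ValueError("per-species counts must match n_species")
        return counts


@dataclass
class SyntheticTruth:
    """Planted parameters and diagnostics of a generated alignment."""

    species_of: dict[str, str]
    expected_intra_p: float
    expected_inter_p: float
    expected_pair_p: dict[tuple[str, str], float]  # species-pair level
    planted_characters: list[PlantedCharacter]
    problem_pairs: list[tuple[str, str, float]]    # (species_a, species_b, expected p)
    ncols: int
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "ncols": self.ncols,
            "expected_intra_p": self.expected_intra_p,
            "expected_inter_p": self.expected_inter_p,
            "species_of": self.species_of,
            "expected_pair_p": {
                f"{a}|{b}": p for (a, b), p in sorted(self.expected_pair_p.items())
            },
            "problem_pairs": [list(t) for t in self.problem_pairs],
            "planted_characters": [
                {
                    "group": c.group,
                    "kind": c.kind,
                    "columns": list(c.columns),
                    "states": list(c.states),
                }
                for c in self.planted_characters
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _compose(a: float, b: float) -> float:
    """Per-site difference probability of two independent lineages."""
    return a + b - (4.0 / 3.0) * a * b


def _half_rate(target: float) -> float:
    """Solve compose(q, q) = target for the per-lineage rate q."""
    if target == 0.0:
        return 0.0
    disc = 1.0 - (4.0 / 3.0) * target
    if disc < 0.0:
        raise ValueError(f"pairwise target {target} unattainable")
    return 0.75 * (1.0 - math.sqrt(disc))


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            protected: np.ndarray) -> np.ndarray:
    """Mutate Binomial(ncols, rate) distinct unprotected columns."""
    out = seq.copy()
    k = rng.binomial(len(seq), rate)
    free = np.flatnonzero(~protected)
    k = min(k, len(free))
    if k:
        cols = rng.choice(free, size=k, replace=False)
        out[cols] = (out[cols] + rng.integers(1, 4, size=k)) % 4
    return out


def generate(params: SynthParams) -> tuple[Alignment, SyntheticTruth]:
    """Generate a labelled alignment plus its ground-truth record."""
    rng = np.random.default_rng(params.seed)
    ncols = params.ncols
    counts = params.counts()
    species = [f"sp{idx + 1:02d}" for idx in range(params.n_species)]
    genus_of = {
        sp: f"g{idx // max(params.species_per_genus, 1) + 1:02d}"
        for idx, sp in enumerate(species)
    }

    protected = np.zeros(ncols, dtype=bool)
    for ch in params.planted_characters:
        for col in ch.columns:
            protected[col - 1] = True

    # member-vs-member targets: intra pairs hit intra_div exactly; for
    # inter pairs, solve founder rate so the composed member lineage
    # (founder + within-species noise) meets inter_div
    q_intra = _half_rate(params.intra_div)
    m_target = _half_rate(params.inter_div)  # member divergence from ancestor
    q_inter = (m_target - q_intra) / (1.0 - (4.0 / 3.0) * q_intra)

    ancestor = rng.integers(0, 4, size=ncols)
    founders = {sp: _mutate(rng, ancestor, q_inter, protected) for sp in species}

    problem: list[tuple[str, str, float]] = []
    if params.n_problem_pairs:
        picks = rng.choice(
            params.n_species, size=2 * params.n_problem_pairs, replace=False
        )
        for k in range(params.n_problem_pairs):
            a, b = species[picks[2 * k]], species[picks[2 * k + 1]]
            founders[b] = founders[a].copy()
            nmut = int(math.floor(params.problem_p * ncols))
            free = np.flatnonzero(~protected)
            cols = rng.choice(free, size=min(nmut, len(free)), replace=False)
            founders[b][cols] = (
                founders[b][cols] + rng.integers(1, 4, size=len(cols))
            ) % 4
            problem.append(
                (a, b, params.intra_div + len(cols) / ncols)
            )

    labels: list[tuple[str, str]] = []  # (record id, species)
    mats: list[np.ndarray] = []
    members_of: dict[str, list[int]] = {sp: [] for sp in species}
    for sp, count in zip(species, counts):
        for m in range(count):
            members_of[sp].append(len(mats))
            labels.append((f"{sp}_{m + 1}", sp))
            mats.append(_mutate(rng, founders[sp], q_intra, protected))

    _plant_characters(rng, mats, members_of, params.planted_characters)

    # indels: each event gaps one unprotected column across one species
    if params.indel_rate > 0:
        free = np.flatnonzero(~protected)
        n_events = min(rng.binomial(ncols, params.indel_rate), len(free))
        if n_events:
            gap_cols = rng.choice(free, size=n_events, replace=False)
            for col in gap_cols:
                sp = species[int(rng.integers(0, len(species)))]
                for row in members_of[sp]:
                    mats[row][col] = _GAP
    if params.ambiguity_rate > 0:
        for mat in mats:
            free = np.flatnonzero(~protected & (mat >= 0))
            k = min(rng.binomial(ncols, params.ambiguity_rate), len(free))
            if k:
                mat[rng.choice(free, size=k, replace=False)] = _AMBIG

    def decode(vec: np.ndarray) -> str:
        return "".join(
            "-" if v == _GAP else "N" if v == _AMBIG else "ACGT"[v] for v in vec
        )

    aln = Alignment(
        records=tuple(
            SeqRecord(
                id=rid, species=sp, genus=genus_of[sp], group="synthetic",
                residues=decode(mat),
            )
            for (rid, sp), mat in zip(labels, mats)
        )
    )

    problem_lookup = {frozenset((a, b)): p for a, b, p in problem}
    expected_pair: dict[tuple[str, str], float] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            expected_pair[(a, b)] = problem_lookup.get(
                frozenset((a, b)), params.inter_div
            )
    truth = SyntheticTruth(
        species_of=dict(labels),
        expected_intra_p=params.intra_div,
        expected_inter_p=params.inter_div,
        expected_pair_p=expected_pair,
        planted_characters=list(params.planted_characters),
        problem_pairs=problem,
        ncols=ncols,
        seed=params.seed,
    )
    return aln, truth


def _plant_characters(
    rng: np.random.Generator,
    mats: list[np.ndarray],
    members_of: dict[str, list[int]],
    characters: Sequence[PlantedCharacter],
) -> None:
    """Write planted diagnostics in place; sites were protected upstream.

    Pure: members carry the state, every outsider is forced off it.
    Compound/doubly-compound: the joint pattern is unique to the group
    while every proper subset of sites is shared with >= 1 outsider, so
    no subset is diagnostic on its own.
    """
    base_index = {b: i for i, b in enumerate("ACGT")}
    for ch in characters:
        if ch.group not in members_of or not members_of[ch.group]:
            raise ValueError(f"planted group {ch.group!r} has no members")
        member_rows = set(members_of[ch.group])
        outsiders = [i for i in range(len(mats)) if i not in member_rows]
        if not outsiders:
            raise ValueError("planted character needs at least one outsider")
        cols0 = [c - 1 for c in ch.columns]
        codes = [base_index[s] for s in ch.states]
        for row in member_rows:
            for c0, code in zip(cols0, codes):
                mats[row][c0] = code
        order = len(cols0)
        if order == 1:
            c0, code = cols0[0], codes[0]
            for row in outsiders:
                if mats[row][c0] == code:
                    mats[row][c0] = (code + int(rng.integers(1, 4))) % 4
            continue
        # break full-pattern outsiders at a random site
        for row in outsiders:
            if all(mats[row][c0] == code for c0, code in zip(cols0, codes)):
                i = int(rng.integers(0, order))
                mats[row][cols0[i]] = (codes[i] + int(rng.integers(1, 4))) % 4
        # then give every proper subset a dedicated outsider carrier;
        # carriers are distinct so no later write destroys a pattern
        subsets = [
            sub for k in range(1, order) for sub in combinations(range(order), k)
        ]
        if len(outsiders) < len(subsets):
            raise ValueError(
                f"planting a {ch.kind} for {ch.group!r} needs at least"
                f" {len(subsets)} outsider sequences, have {len(outsiders)}"
            )
        carriers = rng.choice(len(outsiders), size=len(subsets), replace=False)
        for sub, cidx in zip(subsets, carriers):
            carrier = outsiders[int(cidx)]
            for i in sub:
                mats[carrier][cols0[i]] = codes[i]
            rest = [i for i in range(order) if i not in sub]
            i = rest[0]
            mats[carrier][cols0[i]] = (codes[i] + int(rng.integers(1, 4))) % 4
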