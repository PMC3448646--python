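"""Labelled sequence I/O, amplicon extraction, trimming and deduplication.

Coordinates in all user-facing I/O are 1-based, closed intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._alphabet import ALLOWED, BASES, GAP, chars_compatible, normalize, reverse_complement

__all__ = [
    "SeqRecord",
    "Alignment",
    "PrimerPair",
    "LabelOverride",
    "read_labeled_fasta",
    "write_fasta",
    "read_metadata_table",
    "apply_overrides",
    "extract_amplicon",
    "trim_to_core",
    "deduplicate",
    "validate_alignment",
    "ValidationReport",
]


class SeqIOError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class SeqRecord:
    """One labelled nucleotide sequence."""

    id: str
    residues: str
    species: str = ""
    genus: str = ""
    group: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be nonempty")
        object.__setattr__(self, "residues", normalize(self.residues))
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length records."""

    records: tuple[SeqRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if not recs:
            raise SeqIOError("alignment must contain at least one record")
        n = len(recs[0].residues)
        for r in recs:
            if len(r.residues) != n:
                raise SeqIOError(
                    f"record {r.id!r} has length {len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate record ids: {dupes}")

    @property
    def ncols(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column `col` across records."""
        return "".join(r.residues[col - 1] for r in self.records)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3'."""

    forward: str
    reverse: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", normalize(self.forward).replace(" ", ""))
        object.__setattr__(self, "reverse", normalize(self.reverse).replace(" ", ""))
        if not self.forward or not self.reverse:
            raise SeqIOError("both primers must be nonempty")
        for p in (self.forward, self.reverse):
            if set(p) - (ALLOWED - {GAP}):
                raise SeqIOError(f"primer {p!r} contains non-IUPAC characters")
        if self.max_mismatch < 0:
            raise SeqIOError("max_mismatch must be >= 0")


# the default V4 primer pair (D512 forward / D978 reverse)
V4_PRIMERS = PrimerPair(forward="ATTCCAGCTCCAATAGCG", reverse="GACTACGATGGTATCTAATC")

LabelOverride = dict  # id -> species string, or id -> (species, genus)


def _parse_header(header: str, label_scheme: str) -> dict[str, str]:
    if label_scheme == "pipe":
        parts = [p.strip() for p in header.split("|")]
        keys = ("id", "species", "genus", "group")
        d = dict(zip(keys, parts))
        d.setdefault("id", header)
        return d
    if label_scheme == "id-only":
        return {"id": header.split()[0]}
    raise SeqIOError(f"unknown label scheme {label_scheme!r}")


def read_labeled_fasta(
    path: str | Path,
    label_scheme: str = "pipe",
    metadata: dict[str, dict[str, str]] | None = None,
) -> list[SeqRecord]:
    """Read a FASTA file into labelled records.

    ``label_scheme`` is ``"pipe"`` (headers ``id|species|genus|group``) or
    ``"id-only"``. A ``metadata`` side table (id -> field dict, e.g. from
    :func:`read_metadata_table`) overrides header-derived labels.
    """
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        fields = _parse_header(entry.description, label_scheme)
        rid = fields["id"]
        if rid in seen:
            raise SeqIOError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        if metadata and rid in metadata:
            fields.update({k: v for k, v in metadata[rid].items() if v})
        if not str(entry.seq):
            raise SeqIOError(f"record {rid!r}: empty sequence")
        records.append(
            SeqRecord(
                id=rid,
                residues=str(entry.seq),
                species=fields.get("species", ""),
                genus=fields.get("genus", ""),
                group=fields.get("group", ""),
                strain=fields.get("strain", ""),
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as pipe-labelled FASTA wrapped at 80 columns."""
    bio = []
    for r in records:
        header = f"{r.id}|{r.species}|{r.genus}|{r.group}"
        bio.append(_BioSeqRecord(Seq(r.residues), id=header, description=""))
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(bio)


def read_metadata_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV side table (header row: id, species, genus, ...)."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rid = row.pop("id")
            out[rid] = {k: (v or "") for k, v in row.items()}
    return out


def apply_overrides(
    records: Sequence[SeqRecord], overrides: dict[str, str | tuple[str, str]]
) -> tuple[list[SeqRecord], list[str]]:
    """Relabel records by id; returns (records, audit log).

    Override values are either a species string or (species, genus).
    Keys matching no record raise, guarding against typos.
    """
    by_id = {r.id: r for r in records}
    missing = sorted(set(overrides) - set(by_id))
    if missing:
        raise SeqIOError(f"override keys match no record: {missing}")
    audit: list[str] = []
    out: list[SeqRecord] = []
    for r in records:
        if r.id in overrides:
            val = overrides[r.id]
            if isinstance(val, tuple):
                species, genus = val
            else:
                species, genus = val, val.split()[0] if val else r.genus
            audit.append(f"{r.id}: species {r.species!r} -> {species!r}")
            r = replace(r, species=species, genus=genus)
        out.append(r)
    return out, audit


def _hamming_hits(template: str, primer: str, max_mismatch: int) -> list[int]:
    """Start offsets (0-based) where primer matches within mismatch budget."""
    hits = []
    m = len(primer)
    for start in range(len(template) - m + 1):
        mm = 0
        for a, b in zip(template[start : start + m], primer):
            if not chars_compatible(a, b):
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(start)
    return hits


def extract_amplicon(record: SeqRecord, primers: PrimerPair) -> SeqRecord | None:
    """In-silico PCR: the subsequence strictly between primer sites.

    The forward primer is matched on the given strand (leftmost hit); the
    reverse primer is reverse-complemented and the nearest hit downstream
    of the forward site is used. Primer sequences are excluded from the
    returned amplicon. Returns None when either primer has no hit within
    the Hamming mismatch budget, or the reverse hit lies upstream.
    """
    seq = record.residues
    if GAP in seq:
        raise SeqIOError(f"record {record.id!r} is gapped; ungap before extraction")
    fwd_hits = _hamming_hits(seq, primers.forward, primers.max_mismatch)
    if not fwd_hits:
        return None
    fstart = fwd_hits[0]
    fend = fstart + len(primers.forward)  # 3' end of forward primer
    rc = reverse_complement(primers.reverse)
    rev_hits = [h for h in _hamming_hits(seq, rc, primers.max_mismatch) if h >= fend]
    if not rev_hits:
        return None
    rstart = rev_hits[0]
    amplicon = seq[fend:rstart]
    if not amplicon:
        return None
    return replace(record, residues=amplicon)


def trim_to_core(aln: Alignment, policy: tuple[int, int] = (1, 333)) -> Alignment:
    """Slice alignment columns [start, start+length-1] (1-based, closed)."""
    start, length = policy
    if start < 1 or length < 1:
        raise SeqIOError(f"trim policy {policy} out of range")
    if start + length - 1 > aln.ncols:
        raise SeqIOError(
            f"trim policy {policy} exceeds alignment width {aln.ncols}"
        )
    lo, hi = start - 1, start - 1 + length
    return Alignment(
        tuple(replace(r, residues=r.residues[lo:hi]) for r in aln.records)
    )


def deduplicate(
    records: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Collapse identical residue strings; first occurrence is representative.

    Returns (unique records, representative id -> multiplicity).
    """
    uniques: list[SeqRecord] = []
    counts: dict[str, int] = {}
    rep_by_seq: dict[str, str] = {}
    for r in records:
        rep = rep_by_seq.get(r.residues)
        if rep is None:
            rep_by_seq[r.residues] = r.id
            counts[r.id] = 1
            uniques.append(r)
        else:
            counts[rep] += 1
    return uniques, counts


@dataclass
class ValidationReport:
    """Soft findings from alignment validation (hard errors raise)."""

    all_gap_columns: list[int] = field(default_factory=list)  # 1-based
    ambiguity_counts: dict[str, int] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.all_gap_columns and not any(self.ambiguity_counts.values())

    def __str__(self) -> str:
        lines = ["# alignment validation (1-based, closed coordinates)"]
        if self.all_gap_columns:
            cols = ",".join(map(str, self.all_gap_columns))
            lines.append(f"WARNING all-gap columns: {cols}")
        for rid, n in self.ambiguity_counts.items():
            if n:
                lines.append(f"NOTE {rid}: {n} ambiguity code(s)")
        if len(lines) == 1:
            lines.append("OK")
        return "\n".join(lines)


def validate_alignment(records: Sequence[SeqRecord]) -> ValidationReport:
    """Validate same-length records; raises on ragged input.

    Reports all-gap columns and per-record ambiguity-code counts.
    """
    if not records:
        raise SeqIOError("no records to validate")
    n = len(records[0].residues)
    for r in records:
        if len(r.residues) != n:
            raise SeqIOError(
                f"record {r.id!r} has length {len(r.residues)}, expected {n}"
            )
    report = ValidationReport()
    for col in range(n):
        if all(r.residues[col] == GAP for r in records):
            report.all_gap_columns.append(col + 1)
    for r in records:
        report.ambiguity_counts[r.id] = sum(
            1 for c in r.residues if c != GAP and c not in BASES
        )
    return report
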