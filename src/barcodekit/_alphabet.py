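"""Nucleotide alphabet tables shared across modules.

Residues are stored uppercase with U normalized to T; '-' is the gap
character ('.' is accepted on input as a gap alias).
"""

from __future__ import annotations

# IUPAC code -> set of unambiguous bases it can stand for
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES = frozenset("ACGT")
GAP = "-"
ALLOWED = frozenset(IUPAC) | {GAP}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def normalize(residues: str) -> str:
    """Uppercase, U->T, '.'->'-'."""
    return residues.upper().replace("U", "T").replace(".", GAP)


def reverse_complement(residues: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(residues))


def is_base(c: str) -> bool:
    return c in BASES


def chars_compatible(a: str, b: str) -> bool:
    """True when the IUPAC sets of two residue characters intersect.

    Gaps are compatible with nothing (including another gap).
    """
    sa = IUPAC.get(a)
    sb = IUPAC.get(b)
    if sa is None or sb is None:
        return False
    return bool(sa & sb)
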