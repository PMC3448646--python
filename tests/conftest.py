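from __future__ import annotations

import numpy as np
import pytest

from barcodekit.seqio import Alignment, SeqRecord

ALPHABET = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_records: int,
    ncols: int,
    n_species: int | None = None,
    gap_rate: float = 0.02,
    ambig_rate: float = 0.02,
    base_similarity: float = 0.8,
) -> Alignment:
    """Random labelled alignment with gaps/ambiguities, species-structured."""
    n_species = n_species or max(2, n_records // 2)
    ref = rng.integers(0, 4, size=ncols)
    records = []
    for i in range(n_records):
        chars = []
        for c in range(ncols):
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + ambig_rate:
                chars.append("N")
            elif rng.random() < base_similarity:
                chars.append(ALPHABET[ref[c]])
            else:
                chars.append(ALPHABET[rng.integers(0, 4)])
        sp = f"sp{(i % n_species) + 1}"
        records.append(
            SeqRecord(
                id=f"r{i + 1}", species=sp, genus=f"g{(i % n_species) // 2 + 1}",
                residues="".join(chars),
            )
        )
    return Alignment(records=tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_alignment() -> Alignment:
    # two species x two sequences, one variable column
    return Alignment(
        records=(
            SeqRecord(id="a1", species="A", genus="GA", residues="ACGTACGTAC"),
            SeqRecord(id="a2", species="A", genus="GA", residues="ACGTACGTAC"),
            SeqRecord(id="b1", species="B", genus="GB", residues="ACGTACGTAA"),
            SeqRecord(id="b2", species="B", genus="GB", residues="ACGTACGTAA"),
        )
    )
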