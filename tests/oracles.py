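"""Independent brute-force reference implementations used by the tests.

Deliberately naive and written against the documented definitions only,
never calling into the package's search/matrix code.
"""

from __future__ import annotations

import math
from itertools import combinations

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}
BASES = set("ACGT")


def naive_p(a: str, b: str) -> tuple[float, int, int]:
    ndiff = ncomp = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            ncomp += 1
            ndiff += x != y
    return (ndiff / ncomp if ncomp else math.nan), ndiff, ncomp


def naive_matrix(seqs: list[str]) -> list[list[float]]:
    n = len(seqs)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i][j] = naive_p(seqs[i], seqs[j])[0]
    return out


def naive_separation(matrix, species: list[str], t: float) -> dict[str, bool]:
    """Species -> separated flag under the nearest-neighbor criterion."""
    out = {}
    for sp in set(species):
        dists = [
            matrix[i][j]
            for i in range(len(species))
            for j in range(len(species))
            if species[i] == sp and species[j] != sp
            and not math.isnan(matrix[i][j])
        ]
        out[sp] = all(d >= t for d in dists)
    return out


def naive_problem_pairs(matrix, species: list[str], cutoff: float):
    pairs = {}
    n = len(species)
    for i in range(n):
        for j in range(i + 1, n):
            if species[i] == species[j] or math.isnan(matrix[i][j]):
                continue
            key = tuple(sorted((species[i], species[j])))
            pairs[key] = min(pairs.get(key, 1e9), matrix[i][j])
    return sorted(
        [(a, b, d) for (a, b), d in pairs.items() if d < cutoff],
        key=lambda r: (r[2], r[0], r[1]),
    )


def naive_overlap(matrix, species: list[str], t: float) -> list[str]:
    offenders = []
    for sp in sorted(set(species)):
        rows = [i for i, s in enumerate(species) if s == sp]
        if len(rows) < 2:
            continue
        intra = [
            matrix[i][j] for i in rows for j in rows
            if i < j and not math.isnan(matrix[i][j])
        ]
        if intra and max(intra) >= t:
            offenders.append(sp)
    return offenders


def _member_state(seqs, rows, col):
    states = {seqs[r][col] for r in rows}
    if len(states) == 1 and next(iter(states)) in BASES:
        return next(iter(states))
    return None


def _carries(seqs, row, cols, states):
    return all(states[k] in IUPAC.get(seqs[row][c], set()) for k, c in enumerate(cols))


def naive_diagnostics(seqs: list[str], groups: list[str], order: int):
    """All minimal order-k diagnostics as (group, columns0, states) tuples.

    columns0 are 0-based; minimality means no proper subset of the sites
    is itself jointly unique to the group.
    """
    ncols = len(seqs[0])
    var_cols = [
        c for c in range(ncols)
        if len({s[c] for s in seqs} & BASES) >= 2
    ]
    found = []
    for g in sorted(set(groups)):
        member_rows = [i for i, x in enumerate(groups) if x == g]
        other_rows = [i for i, x in enumerate(groups) if x != g]
        fixed = []
        for c in var_cols:
            st = _member_state(seqs, member_rows, c)
            if st is not None:
                fixed.append((c, st))
        for combo in combinations(fixed, order):
            cols = tuple(c for c, _ in combo)
            states = tuple(s for _, s in combo)
            if any(_carries(seqs, r, cols, states) for r in other_rows):
                continue
            minimal = True
            for k in range(1, order):
                for sub in combinations(range(order), k):
                    sc = tuple(cols[i] for i in sub)
                    ss = tuple(states[i] for i in sub)
                    if not any(_carries(seqs, r, sc, ss) for r in other_rows):
                        minimal = False
                        break
                if not minimal:
                    break
            if minimal:
                found.append((g, cols, states))
    return sorted(found)


def naive_private(seqs: list[str], groups: list[str]):
    """(group, column0, state) private characters."""
    ncols = len(seqs[0])
    var_cols = [
        c for c in range(ncols) if len({s[c] for s in seqs} & BASES) >= 2
    ]
    found = []
    for g in sorted(set(groups)):
        member_rows = [i for i, x in enumerate(groups) if x == g]
        other_rows = [i for i, x in enumerate(groups) if x != g]
        for c in var_cols:
            carried = {seqs[r][c] for r in member_rows} & BASES
            for state in sorted(carried):
                n_with = sum(1 for r in member_rows if seqs[r][c] == state)
                if n_with == len(member_rows):
                    continue
                if any(state in IUPAC.get(seqs[r][c], set()) for r in other_rows):
                    continue
                found.append((g, c, state))
    return sorted(found)
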