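"""Character-based species discrimination.

Diagnostics are searched against a guide grouping (species labels by
default, or groups cut from a neighbor-joining guide tree):

* pure — a single base state carried by every group member and by no
  non-member;
* compound_pure — two sites whose joint states are unique to the group
  although neither site is diagnostic alone;
* doubly_compound — three sites, jointly unique, no subset diagnostic;
  treated downstream as equivalent to a pure diagnostic;
* private — a state confined to the group but not carried by all of its
  members (reported for audit; typically base-calling noise).

Member-side matching is strict: a gap or ambiguity code at a candidate
site in any member disqualifies the state for that group. Non-member
ambiguity codes are IUPAC-expanded and any overlap with the diagnostic
state disqualifies it. Sites are reported both as variable-site ordinals
(1-based rank among polymorphic columns) and as absolute 1-based
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import BASES, IUPAC
from .distances import DistanceMatrix
from .seqio import Alignment, SeqRecord

__all__ = [
    "VariableSiteIndex",
    "DiagnosticCharacter",
    "CharacterTable",
    "grouping_from_records",
    "grouping_from_tree",
    "variable_sites",
    "find_pure_diagnostics",
    "find_compound_diagnostics",
    "find_private_characters",
    "build_character_table",
    "build_guide_tree",
    "classify_sequence",
    "CombinatorialBudgetError",
]

KINDS = ("pure", "compound_pure", "doubly_compound", "private")

# exhaustive enumeration stays desk-scale below these variable-site counts
DEFAULT_SITE_CAP = {2: 200, 3: 80}


class CombinatorialBudgetError(RuntimeError):
    """Variable-site count exceeds the exhaustive-search cap."""


@dataclass(frozen=True)
class VariableSiteIndex:
    """Polymorphic alignment columns, 1-based; ordinal k <-> columns[k-1]."""

    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.columns) != sorted(set(self.columns)):
            raise ValueError("variable-site columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    def ordinal(self, column: int) -> int:
        return self.columns.index(column) + 1

    def column(self, ordinal: int) -> int:
        return self.columns[ordinal - 1]


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A (sites, states) rule identifying one group."""

    group: str
    sites: tuple[int, ...]    # variable-site ordinals, 1-based
    columns: tuple[int, ...]  # absolute alignment columns, 1-based
    states: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        expected = {"pure": 1, "compound_pure": 2, "doubly_compound": 3}.get(self.kind)
        if expected is not None and len(self.sites) != expected:
            raise ValueError(f"{self.kind} requires {expected} site(s)")
        if not (len(self.sites) == len(self.columns) == len(self.states)):
            raise ValueError("sites, columns and states must align")


@dataclass
class CharacterTable:
    """Per-group diagnostics ranked pure < compound < doubly_compound."""

    by_group: dict[str, list[DiagnosticCharacter]] = field(default_factory=dict)
    private: dict[str, list[DiagnosticCharacter]] = field(default_factory=dict)
    skipped_orders: list[int] = field(default_factory=list)

    _RANK = {"pure": 0, "compound_pure": 1, "doubly_compound": 2}

    def add(self, ch: DiagnosticCharacter) -> None:
        target = self.private if ch.kind == "private" else self.by_group
        target.setdefault(ch.group, []).append(ch)
        if ch.kind != "private":
            self.by_group[ch.group].sort(key=lambda c: (self._RANK[c.kind], c.sites))

    def groups(self) -> list[str]:
        return sorted(self.by_group)

    def to_tsv(self) -> str:
        lines = [
            "# sites are variable-site ordinals; columns are alignment"
            " columns (both 1-based, closed)",
            "group\tkind\tsites\tcolumns\tstates",
        ]
        everything = [c for chars in self.by_group.values() for c in chars]
        everything += [c for chars in self.private.values() for c in chars]
        everything.sort(key=lambda c: (c.group, self._RANK.get(c.kind, 9), c.sites))
        for c in everything:
            lines.append(
                f"{c.group}\t{c.kind}\t{','.join(map(str, c.sites))}"
                f"\t{','.join(map(str, c.columns))}\t{','.join(c.states)}"
            )
        return "\n".join(lines) + "\n"


def grouping_from_records(records: Sequence[SeqRecord]) -> dict[str, str]:
    """Default guide grouping: sequence id -> species label."""
    grouping = {}
    for r in records:
        if not r.species:
            raise ValueError(f"record {r.id!r} lacks a species label")
        grouping[r.id] = r.species
    return grouping


def grouping_from_tree(newick: str, edge_cutoff: float) -> dict[str, str]:
    """Guide grouping from a tree: cut edges longer than the cutoff.

    Leaves that stay connected after removing every edge with length
    greater than ``edge_cutoff`` form one group; groups are labelled
    cluster1, cluster2, ... in leaf order. An alternative to species
    labels when labels are suspect.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            if length <= edge_cutoff:
                union(id(node), id(child))
    roots: dict[int, str] = {}
    grouping: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        root = find(id(leaf))
        if root not in roots:
            roots[root] = f"cluster{len(roots) + 1}"
        grouping[leaf.taxon.label] = roots[root]
    return grouping


def variable_sites(aln: Alignment, count_gaps: bool = False) -> VariableSiteIndex:
    """Columns with >= 2 distinct states across the record set.

    Gaps are ignored as states by default; ambiguity codes never count as
    states on their own.
    """
    cols = []
    for c in range(1, aln.ncols + 1):
        states = {ch for ch in aln.column(c) if ch in BASES}
        if count_gaps and "-" in aln.column(c) and states:
            states.add("-")
        if len(states) >= 2:
            cols.append(c)
    return VariableSiteIndex(columns=tuple(cols))


def _check_grouping(aln: Alignment, grouping: Mapping[str, str]) -> None:
    missing = [r.id for r in aln.records if r.id not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover records: {missing}")
    if len(set(grouping[r.id] for r in aln.records)) < 2:
        raise ValueError("grouping must contain at least two groups")


def _group_state(members: Sequence[SeqRecord], col: int) -> str | None:
    """The single unambiguous base all members share at col, else None."""
    states = {r.residues[col - 1] for r in members}
    if len(states) == 1:
        s = next(iter(states))
        if s in BASES:
            return s
    return None


def _nonmember_overlaps(ch: str, state: str) -> bool:
    """Does a non-member residue character possibly carry `state`?"""
    return state in IUPAC.get(ch, frozenset())


def find_pure_diagnostics(
    aln: Alignment,
    grouping: Mapping[str, str],
    vsi: VariableSiteIndex | None = None,
) -> list[DiagnosticCharacter]:
    """Single-site states unique to one group and fixed within it."""
    _check_grouping(aln, grouping)
    vsi = vsi or variable_sites(aln)
    out: list[DiagnosticCharacter] = []
    groups = sorted({grouping[r.id] for r in aln.records})
    for g in groups:
        members = [r for r in aln.records if grouping[r.id] == g]
        others = [r for r in aln.records if grouping[r.id] != g]
        for ordinal, col in enumerate(vsi.columns, start=1):
            state = _group_state(members, col)
            if state is None:
                continue
            if any(_nonmember_overlaps(o.residues[col - 1], state) for o in others):
                continue
            out.append(
                DiagnosticCharacter(
                    group=g, sites=(ordinal,), columns=(col,),
                    states=(state,), kind="pure",
                )
            )
    return out


def find_compound_diagnostics(
    aln: Alignment,
    grouping: Mapping[str, str],
    order: int = 2,
    vsi: VariableSiteIndex | None = None,
    site_cap: int | None = None,
    doubly_compound_mode: str = "any",
) -> list[DiagnosticCharacter]:
    """Minimal multi-site diagnostics of the given order (2 or 3).

    A combination qualifies when every group member carries the joint
    state pattern, no non-member can carry it jointly, and no proper
    subset of the sites is itself diagnostic for the group.

    ``doubly_compound_mode`` applies to order 3: ``"any"`` enumerates all
    variable-site triples; ``"private-sites"`` restricts candidates to
    sites that host a private character for the group (a literal reading
    of three-private-site combinations; usually far more restrictive).
    Exceeding ``site_cap`` variable sites raises
    :class:`CombinatorialBudgetError` rather than truncating silently.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if doubly_compound_mode not in ("any", "private-sites"):
        raise ValueError(f"unknown doubly_compound_mode {doubly_compound_mode!r}")
    _check_grouping(aln, grouping)
    vsi = vsi or variable_sites(aln)
    cap = site_cap if site_cap is not None else DEFAULT_SITE_CAP[order]
    if len(vsi) > cap:
        raise CombinatorialBudgetError(
            f"{len(vsi)} variable sites exceeds the order-{order} cap of {cap};"
            " raise site_cap explicitly to proceed"
        )
    kind = "compound_pure" if order == 2 else "doubly_compound"
    out: list[DiagnosticCharacter] = []
    groups = sorted({grouping[r.id] for r in aln.records})
    for g in groups:
        members = [r for r in aln.records if grouping[r.id] == g]
        others = [r for r in aln.records if grouping[r.id] != g]
        # sites where the group is fixed for a single base
        fixed: list[tuple[int, int, str]] = []  # (ordinal, col, state)
        for ordinal, col in enumerate(vsi.columns, start=1):
            state = _group_state(members, col)
            if state is not None:
                fixed.append((ordinal, col, state))
        if order == 3 and doubly_compound_mode == "private-sites":
            priv_cols = {
                c
                for ch in find_private_characters(aln, grouping, vsi)
                if ch.group == g
                for c in ch.columns
            }
            fixed = [f for f in fixed if f[1] in priv_cols]
        # bitmask per site: which outsiders can carry the group's state
        # there; a site set is jointly diagnostic iff the AND of its
        # masks is zero, and minimal iff every proper subset ANDs nonzero
        masks = []
        for _, col, state in fixed:
            m = 0
            for bit, o in enumerate(others):
                if _nonmember_overlaps(o.residues[col - 1], state):
                    m |= 1 << bit
            masks.append(m)
        # sites with mask 0 are pure on their own; minimality excludes them
        live = [idx for idx, m in enumerate(masks) if m != 0]

        def emit(idxs: tuple[int, ...]) -> None:
            out.append(
                DiagnosticCharacter(
                    group=g,
                    sites=tuple(fixed[i][0] for i in idxs),
                    columns=tuple(fixed[i][1] for i in idxs),
                    states=tuple(fixed[i][2] for i in idxs),
                    kind=kind,
                )
            )

        if order == 2:
            for a_pos, i in enumerate(live):
                mi = masks[i]
                for j in live[a_pos + 1 :]:
                    if mi & masks[j] == 0:
                        emit((i, j))
        else:
            for a_pos, i in enumerate(live):
                mi = masks[i]
                for b_pos in range(a_pos + 1, len(live)):
                    j = live[b_pos]
                    mij = mi & masks[j]
                    if mij == 0:
                        continue  # the pair is already diagnostic
                    for k in live[b_pos + 1 :]:
                        mk = masks[k]
                        if mij & mk == 0 and mi & mk != 0 and masks[j] & mk != 0:
                            emit((i, j, k))
    return out


def find_private_characters(
    aln: Alignment,
    grouping: Mapping[str, str],
    vsi: VariableSiteIndex | None = None,
) -> list[DiagnosticCharacter]:
    """States confined to a group but not carried by all of its members."""
    _check_grouping(aln, grouping)
    vsi = vsi or variable_sites(aln)
    out: list[DiagnosticCharacter] = []
    groups = sorted({grouping[r.id] for r in aln.records})
    for g in groups:
        members = [r for r in aln.records if grouping[r.id] == g]
        others = [r for r in aln.records if grouping[r.id] != g]
        for ordinal, col in enumerate(vsi.columns, start=1):
            carried = {r.residues[col - 1] for r in members} & BASES
            for state in sorted(carried):
                n_with = sum(1 for r in members if r.residues[col - 1] == state)
                if n_with == len(members):
                    continue  # fixed in the group -> pure territory, not private
                if any(_nonmember_overlaps(o.residues[col - 1], state) for o in others):
                    continue
                out.append(
                    DiagnosticCharacter(
                        group=g, sites=(ordinal,), columns=(col,),
                        states=(state,), kind="private",
                    )
                )
    return out


def build_character_table(
    aln: Alignment,
    grouping: Mapping[str, str] | None = None,
    orders: Sequence[int] = (1, 2, 3),
    site_cap: int | None = None,
    doubly_compound_mode: str = "any",
    on_budget_error: str = "raise",
) -> CharacterTable:
    """Run the pure/compound/private searches and assemble a table.

    With ``on_budget_error="skip"``, over-budget compound orders are left
    out and listed in ``table.skipped_orders`` instead of raising.
    """
    if on_budget_error not in ("raise", "skip"):
        raise ValueError(f"unknown on_budget_error {on_budget_error!r}")
    if grouping is None:
        grouping = grouping_from_records(aln.records)
    vsi = variable_sites(aln)
    table = CharacterTable()
    if 1 in orders:
        for ch in find_pure_diagnostics(aln, grouping, vsi):
            table.add(ch)
    for order in (2, 3):
        if order in orders:
            try:
                for ch in find_compound_diagnostics(
                    aln, grouping, order, vsi, site_cap, doubly_compound_mode
                ):
                    table.add(ch)
            except CombinatorialBudgetError:
                if on_budget_error == "raise":
                    raise
                table.skipped_orders.append(order)
    for ch in find_private_characters(aln, grouping, vsi):
        table.add(ch)
    return table


def build_guide_tree(m: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Ties in the Q-criterion break deterministically toward the smallest
    (row, column) pair in current node order, so repeated runs produce
    identical trees.
    """
    n = m.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(m.p).any():
        raise ValueError("distance matrix contains undefined entries")
    d = {(a, b): float(m.p[i, j]) for i, a in enumerate(m.ids) for j, b in enumerate(m.ids)}
    nodes: list[str] = list(m.ids)
    newick: dict[str, str] = {t: _quote(t) for t in nodes}
    while len(nodes) > 2:
        r = len(nodes)
        sums = {a: sum(d[(a, b)] for b in nodes if b != a) for a in nodes}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = nodes[i], nodes[j]
                q = (r - 2) * d[(a, b)] - sums[a] - sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * d[(a, b)] + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = d[(a, b)] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = f"__nj{len(newick)}"
        newick[u] = f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f})"
        for c in list(nodes):
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        d[(u, u)] = 0.0
        nodes = [c for c in nodes if c not in (a, b)] + [u]
    a, b = nodes
    return f"({newick[a]}:{d[(a, b)] / 2:.6f},{newick[b]}:{d[(a, b)] / 2:.6f});"


def _quote(name: str) -> str:
    if any(c in name for c in " ():;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def classify_sequence(
    query: SeqRecord, table: CharacterTable, ncols: int
) -> set[str]:
    """Groups whose full diagnostic rule set the query satisfies.

    A singleton set is an identification; a multi-group set is ambiguous;
    an empty set means unassigned. Groups without any pure/compound
    diagnostic never match (private characters are audit-only). Matching
    is by exact base state, so gaps or ambiguity codes at a diagnostic
    site fail that rule.
    """
    if len(query.residues) != ncols:
        raise ValueError(
            f"query {query.id!r} has length {len(query.residues)}, expected {ncols}"
        )
    matched: set[str] = set()
    for g, chars in table.by_group.items():
        if not chars:
            continue
        ok = all(
            all(query.residues[c - 1] == s for c, s in zip(ch.columns, ch.states))
            for ch in chars
        )
        if ok:
            matched.add(g)
    return matched
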