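from __future__ import annotations

import numpy as np
import pytest

import dendropy

from barcodekit.characters import (
    CombinatorialBudgetError,
    build_character_table,
    build_guide_tree,
    classify_sequence,
    find_compound_diagnostics,
    find_private_characters,
    find_pure_diagnostics,
    grouping_from_records,
    variable_sites,
)
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.seqio import Alignment, SeqRecord
from conftest import random_alignment
from oracles import naive_diagnostics, naive_private


def aln_from(rows: dict[str, tuple[str, str]]) -> Alignment:
    """rows: id -> (group label, residues)."""
    return Alignment(
        records=tuple(
            SeqRecord(id=rid, species=grp, genus=grp, residues=seq)
            for rid, (grp, seq) in rows.items()
        )
    )


class TestVariableSites:
    def test_identical_empty(self):
        aln = aln_from({"a": ("A", "ACGT"), "b": ("B", "ACGT")})
        assert len(variable_sites(aln)) == 0

    def test_single_column(self):
        aln = aln_from({"a": ("A", "ACGTA"), "b": ("B", "ACTTA")})
        vsi = variable_sites(aln)
        assert vsi.columns == (3,)
        assert vsi.ordinal(3) == 1 and vsi.column(1) == 3

    def test_gaps_not_states(self):
        aln = aln_from({"a": ("A", "A-G"), "b": ("B", "AAG")})
        assert variable_sites(aln).columns == ()

    def test_planted_polymorphic_columns(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        cols = sorted(rng.choice(100, size=17, replace=False))
        other = list(base)
        for c in cols:
            other[c] = "ACGT"[("ACGT".index(other[c]) + 1) % 4]
        aln = aln_from({"a": ("A", base), "b": ("B", "".join(other))})
        assert variable_sites(aln).columns == tuple(c + 1 for c in cols)


class TestPureDiagnostics:
    def test_simple_pure(self):
        aln = aln_from({
            "a1": ("A", "ATG"), "a2": ("A", "ATG"),
            "b1": ("B", "ACG"), "b2": ("B", "ACG"),
        })
        out = find_pure_diagnostics(aln, grouping_from_records(aln.records))
        a_chars = [c for c in out if c.group == "A"]
        assert any(c.columns == (2,) and c.states == ("T",) for c in a_chars)

    def test_identical_groups_have_none(self):
        aln = aln_from({
            "p1": ("pseudocostatum", "ACGTT"), "t1": ("tropicum", "ACGTT"),
            "o1": ("other", "ACGAA"),
        })
        out = find_pure_diagnostics(aln, grouping_from_records(aln.records))
        assert not [c for c in out if c.group in ("pseudocostatum", "tropicum")]

    def test_member_gap_disqualifies(self):
        aln = aln_from({
            "a1": ("A", "ATG"), "a2": ("A", "A-G"),
            "b1": ("B", "ACG"),
        })
        out = find_pure_diagnostics(aln, grouping_from_records(aln.records))
        assert not [c for c in out if c.group == "A" and c.columns == (2,)]

    def test_nonmember_ambiguity_disqualifies(self):
        # Y = C or T overlaps the would-be diagnostic T
        aln = aln_from({
            "a1": ("A", "ATG"), "b1": ("B", "AYG"), "b2": ("B", "ACG"),
        })
        out = find_pure_diagnostics(aln, grouping_from_records(aln.records))
        assert not [c for c in out if c.group == "A"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 12, 40, n_species=4)
        grouping = grouping_from_records(aln.records)
        got = {
            (c.group, c.columns[0] - 1, c.states[0])
            for c in find_pure_diagnostics(aln, grouping)
        }
        seqs = [r.residues for r in aln.records]
        groups = [r.species for r in aln.records]
        oracle = {
            (g, cols[0], states[0])
            for g, cols, states in naive_diagnostics(seqs, groups, 1)
        }
        assert got == oracle


class TestCompoundDiagnostics:
    def test_constructed_compound(self):
        # A carries (3:A, 7:G); each single state shared with an outsider
        aln = aln_from({
            "a1": ("A", "CCACCCGCC"), "a2": ("A", "CCACCCGCC"),
            "b1": ("B", "CCACCCTCC"),   # shares site 3 'A'
            "b2": ("B", "CCGCCCGCC"),   # shares site 7 'G'
        })
        out = find_compound_diagnostics(aln, grouping_from_records(aln.records), 2)
        assert any(
            c.group == "A" and c.columns == (3, 7) and c.states == ("A", "G")
            for c in out
        )

    def test_fig5_style_two_site_difference(self):
        # two groups separated only by a CC vs CT pattern at two columns
        aln = aln_from({
            "p1": ("Pv", "ACCA"), "p2": ("Pv", "ACCA"),
            "b1": ("Bb", "ACTA"), "b2": ("Bb", "ACTA"),
            "o1": ("out", "ATCA"), "o2": ("out2", "ACGA"),
        })
        grouping = grouping_from_records(aln.records)
        out = find_compound_diagnostics(aln, grouping, 2)
        pv = [c for c in out if c.group == "Pv"]
        assert any(c.columns == (2, 3) and c.states == ("C", "C") for c in pv)

    @pytest.mark.parametrize("order", [2, 3])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle(self, seed, order):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 10, 40, n_species=3, base_similarity=0.9)
        grouping = grouping_from_records(aln.records)
        got = {
            (c.group, tuple(c - 1 for c in c.columns), c.states)
            for c in find_compound_diagnostics(aln, grouping, order, site_cap=300)
        }
        seqs = [r.residues for r in aln.records]
        groups = [r.species for r in aln.records]
        oracle = set(naive_diagnostics(seqs, groups, order))
        oracle = {(g, cols, states) for g, cols, states in oracle}
        assert got == oracle

    def test_budget_cap_errors(self, rng):
        aln = random_alignment(rng, 12, 300, n_species=4, base_similarity=0.5)
        grouping = grouping_from_records(aln.records)
        with pytest.raises(CombinatorialBudgetError):
            find_compound_diagnostics(aln, grouping, 3)

    def test_minimality_no_pure_subset(self, rng):
        aln = random_alignment(rng, 10, 30, n_species=3)
        grouping = grouping_from_records(aln.records)
        pures = {
            (c.group, c.columns[0], c.states[0])
            for c in find_pure_diagnostics(aln, grouping)
        }
        for c in find_compound_diagnostics(aln, grouping, 2, site_cap=300):
            for col, st in zip(c.columns, c.states):
                assert (c.group, col, st) not in pures


class TestPrivateCharacters:
    def test_unique_state_in_one_member(self):
        aln = aln_from({
            "a1": ("A", "AG"), "a2": ("A", "AA"),
            "b1": ("B", "AC"),
        })
        out = find_private_characters(aln, grouping_from_records(aln.records))
        assert any(c.group == "A" and c.columns == (2,) and c.states == ("G",)
                   for c in out)

    def test_state_shared_with_outsider_not_private(self):
        aln = aln_from({
            "a1": ("A", "AG"), "a2": ("A", "AA"),
            "b1": ("B", "AG"),
        })
        out = find_private_characters(aln, grouping_from_records(aln.records))
        assert not [c for c in out if c.group == "A" and c.states == ("G",)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 10, 40, n_species=4)
        grouping = grouping_from_records(aln.records)
        got = {
            (c.group, c.columns[0] - 1, c.states[0])
            for c in find_private_characters(aln, grouping)
        }
        seqs = [r.residues for r in aln.records]
        groups = [r.species for r in aln.records]
        assert got == set(naive_private(seqs, groups))


class TestGuideTree:
    def _matrix(self, ids, d):
        import numpy as np
        arr = np.array(d, dtype=float)
        return DistanceMatrix(
            ids=ids, p=arr,
            ndiff=(arr * 100).astype(int), ncomp=np.full_like(arr, 100, dtype=int),
        )

    def test_additive_four_taxa_recovered(self):
        # tree: ((a:0.02,b:0.03):0.05,(c:0.04,d:0.01)); path distances below
        ids = ["a", "b", "c", "d"]
        d = [
            [0.00, 0.05, 0.11, 0.08],
            [0.05, 0.00, 0.12, 0.09],
            [0.11, 0.12, 0.00, 0.05],
            [0.08, 0.09, 0.05, 0.00],
        ]
        nwk = build_guide_tree(self._matrix(ids, d))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        d[i][j], abs=1e-9
                    )

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = [[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]]
        nwk = build_guide_tree(self._matrix(ids, d))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i][j])

    def test_ties_deterministic(self, rng):
        aln = random_alignment(rng, 8, 40, n_species=4)
        m = distance_matrix(aln)
        assert build_guide_tree(m) == build_guide_tree(m)

    def test_tree_cut_grouping(self):
        # two tight pairs joined by one long internal edge
        ids = ["a", "b", "c", "d"]
        d = [
            [0.00, 0.01, 0.20, 0.20],
            [0.01, 0.00, 0.20, 0.20],
            [0.20, 0.20, 0.00, 0.01],
            [0.20, 0.20, 0.01, 0.00],
        ]
        from barcodekit.characters import grouping_from_tree

        nwk = build_guide_tree(self._matrix(ids, d))
        grouping = grouping_from_tree(nwk, edge_cutoff=0.05)
        assert grouping["a"] == grouping["b"]
        assert grouping["c"] == grouping["d"]
        assert grouping["a"] != grouping["c"]

    def test_too_few_taxa(self):
        ids = ["a", "b"]
        d = [[0.0, 0.1], [0.1, 0.0]]
        with pytest.raises(ValueError):
            build_guide_tree(self._matrix(ids, d))


class TestClassify:
    def _training(self):
        return aln_from({
            "a1": ("A", "ATGCA"), "a2": ("A", "ATGCA"),
            "b1": ("B", "ACGCA"), "b2": ("B", "ACGCA"),
            "c1": ("C", "ACGTA"), "c2": ("C", "ACGTA"),
        })

    def test_training_sequences_self_classify(self):
        aln = self._training()
        table = build_character_table(aln)
        for r in aln.records:
            assert classify_sequence(r, table, aln.ncols) == {r.species}

    def test_length_mismatch_errors(self):
        aln = self._training()
        table = build_character_table(aln)
        with pytest.raises(ValueError):
            classify_sequence(SeqRecord(id="q", residues="ACG"), table, aln.ncols)

    def test_unassigned_query(self):
        aln = self._training()
        table = build_character_table(aln)
        q = SeqRecord(id="q", residues="GGGGG")
        assert classify_sequence(q, table, aln.ncols) == set()

    def test_merged_pair_classifies_ambiguously(self):
        # identical species pair: diagnosable only as a merged group; a
        # query matching both groups' shared rule sets comes back empty
        # per-species but matches the pair-level grouping
        aln = aln_from({
            "p1": ("P", "ATTTT"), "t1": ("T", "ATTTT"),
            "o1": ("O", "ACTTT"), "o2": ("O2", "ACGTT"),
        })
        table = build_character_table(aln)
        q = SeqRecord(id="q", residues="ATTTT")
        assert classify_sequence(q, table, aln.ncols) == set()
        merged = {"p1": "PT", "t1": "PT", "o1": "O", "o2": "O2"}
        table2 = build_character_table(aln, grouping=merged)
        assert "PT" in classify_sequence(q, table2, aln.ncols)

    def test_synthetic_queries_high_accuracy(self):
        from barcodekit.synthesis import PlantedCharacter, SynthParams, generate

        planted = tuple(
            PlantedCharacter(f"sp{i + 1:02d}", "pure", (10 * (i + 1),), ("T",))
            for i in range(5)
        )
        aln, truth = generate(
            SynthParams(n_species=5, seqs_per_species=4, ncols=300,
                        intra_div=0.0, inter_div=0.1, seed=3,
                        planted_characters=planted)
        )
        table = build_character_table(aln, site_cap=500)
        correct = 0
        for r in aln.records:
            got = classify_sequence(r, table, aln.ncols)
            correct += got == {truth.species_of[r.id]}
        assert correct == len(aln.records)
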