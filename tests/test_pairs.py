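import numpy as np
import pytest
from Bio.Align import substitution_matrices

from enzconverge.entries import CatalyticResidue, CATHCode, CofactorSet, ECNumber, EnzymeEntry
from enzconverge.geometry import SuperpositionResult
from enzconverge.mechanism import classify_mechanism
from enzconverge.pairs import (
    PairRecord,
    align_sequences,
    assign_paradigm,
    classify_pairs,
    dedupe_unique,
    enumerate_pairs,
    filter_pairs,
    survey_counts,
)
from enzconverge.survey import beta_lactamase_catalogue


def make_entry(entry_id, ec="3.5.2.6", cath=("3.40.710.10",), incomplete=False, seq=None):
    return EnzymeEntry(
        entry_id=entry_id,
        ec=ECNumber.parse(ec),
        cath_codes=tuple(CATHCode.parse(c) for c in cath),
        pdb_id="XXXX",
        catalytic_residues=(CatalyticResidue("A", 1, name3="HIS"),),
        cofactors=CofactorSet(frozenset()),
        incomplete=incomplete,
        incomplete_reason="not all 4 EC levels determined" if incomplete else None,
        sequence=seq,
    )


def fake_superposition(n_mapped, rmsd, larger=6):
    return SuperpositionResult(
        rotation=np.eye(3), translation=np.zeros(3), rmsd=rmsd, wrmsd=rmsd,
        coverage=n_mapped / larger, iterations=1, converged=True,
        aligned_residue_pairs=tuple(("Res", "Res") for _ in range(n_mapped)),
        n_mapped=n_mapped,
    )


def make_pair(n_mapped=0, rmsd=None, similar=None, spurious=False, score=None):
    pair = PairRecord(
        entry_a=make_entry("a1"),
        entry_b=make_entry("a2", cath=("3.60.15.10",)),
        ec_level_matched=4,
        homology="analogue",
        spurious_flag=spurious,
    )
    if n_mapped:
        pair.superposition = fake_superposition(n_mapped, rmsd)
    if similar is not None or score is not None:
        pair.mech = classify_mechanism(score, override=similar)
    return pair


class TestEnumerate:
    def test_beta_lactamase_six_entries(self):
        pairs = enumerate_pairs(beta_lactamase_catalogue())
        assert len(pairs) == 15
        assert sum(p.homology == "homologue" for p in pairs) == 6
        assert sum(p.homology == "analogue" for p in pairs) == 9

    def test_single_entry_gives_nothing(self):
        assert enumerate_pairs([make_entry("only")]) == []

    def test_ec_level_threshold(self):
        a = make_entry("a", ec="3.5.2.6")
        b = make_entry("b", ec="3.5.2.7", cath=("3.60.15.10",))
        assert enumerate_pairs([a, b], ec_level=3)
        assert enumerate_pairs([a, b], ec_level=4) == []

    def test_deterministic_order(self):
        entries = beta_lactamase_catalogue()
        ids1 = [p.ids for p in enumerate_pairs(entries)]
        ids2 = [p.ids for p in enumerate_pairs(list(reversed(entries)))]
        assert ids1 == ids2


class TestFilter:
    def test_multi_domain_removed_with_reason(self):
        a = make_entry("multi", cath=("3.40.710.10", "3.60.15.10"))
        b = make_entry("ok", cath=("3.20.20.80",))
        kept, audit = filter_pairs(enumerate_pairs([a, b]))
        assert kept == []
        assert "multiple CATH numbers" in audit[0][1]

    def test_incomplete_removed_with_reason(self):
        a = make_entry("inc", ec="3.5.2.6", incomplete=True)
        b = make_entry("ok", cath=("3.60.15.10",))
        kept, audit = filter_pairs(enumerate_pairs([a, b]))
        assert kept == []
        assert "incomplete" in audit[0][1]

    def test_clean_pair_retained(self):
        pairs = enumerate_pairs([make_entry("a"), make_entry("b", cath=("3.60.15.10",))])
        kept, audit = filter_pairs(pairs)
        assert len(kept) == 1 and audit == []

    def test_curated_exclusions_logged(self):
        pairs = enumerate_pairs([make_entry("a"), make_entry("b", cath=("3.60.15.10",))])
        kept, audit = filter_pairs(pairs, exclusions={"a": "suspected homology"})
        assert kept == [] and "suspected homology" in audit[0][1]

    def test_pipeline_counts_monotone(self):
        entries = beta_lactamase_catalogue()
        enumerated = enumerate_pairs(entries)
        filtered, _ = filter_pairs(enumerated)
        unique = dedupe_unique(filtered)
        assert len(enumerated) >= len(filtered) >= len(unique)


class TestDedupe:
    def test_nine_analogous_beta_lactamase_pairs_collapse_to_one(self):
        pairs = [p for p in enumerate_pairs(beta_lactamase_catalogue())
                 if p.homology == "analogue"]
        assert len(pairs) == 9
        unique = dedupe_unique(pairs)
        assert len(unique) == 1
        assert unique[0].ids == ("metbla1", "serbla1")

    def test_distinct_cath_pairs_unchanged(self):
        entries = [
            make_entry("a", cath=("1.10.10.10",)),
            make_entry("b", cath=("2.20.20.20",)),
            make_entry("c", cath=("3.30.30.30",)),
        ]
        pairs = enumerate_pairs(entries)
        assert len(dedupe_unique(pairs)) == len(pairs) == 3

    def test_empty(self):
        assert dedupe_unique([]) == []


class TestAlignment:
    def test_identical_sequences_full_identity(self):
        identity, coverage = align_sequences("ACDEFGHIKL", "ACDEFGHIKL", "global")
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(100.0)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD", "global")

    def test_local_score_matches_bruteforce_enumeration_on_6mers(self):
        """Smith-Waterman optimum equals exhaustive enumeration of every
        local alignment (all start pairs, all monotone gap placements)."""
        from Bio import Align

        blosum = substitution_matrices.load("BLOSUM62")
        open_, ext = -10.0, -0.5

        def brute_best(a, b):
            best = 0.0

            def rec(i, j, score):
                nonlocal best
                score = score + blosum[a[i]][b[j]]
                best = max(best, score)
                for ni in range(i + 1, len(a)):
                    for nj in range(j + 1, len(b)):
                        da, db = ni - i - 1, nj - j - 1
                        pen = 0.0
                        if da:
                            pen += open_ + (da - 1) * ext
                        if db:
                            pen += open_ + (db - 1) * ext
                        rec(ni, nj, score + pen)

            for i in range(len(a)):
                for j in range(len(b)):
                    rec(i, j, 0.0)
            return best

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = blosum
        aligner.open_gap_score = open_
        aligner.extend_gap_score = ext
        for a, b in [("ACDEFG", "GFEDCA"), ("HKWYRN", "HKAYRN"), ("MNPQRS", "MNQRST")]:
            assert aligner.score(a, b) == pytest.approx(brute_best(a, b))

    def test_local_identity_on_shared_block(self):
        identity, coverage = align_sequences("AAAWWWWCCC", "DDDWWWWEEE", "local")
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(40.0)  # 4 aligned of the 10-mer


class TestParadigms:
    def test_structural_and_mechanistic(self):
        pair = make_pair(n_mapped=4, rmsd=1.45, score=0.30)
        assert assign_paradigm(pair) == "structural_and_mechanistic"

    def test_mechanistic_only_when_no_mapping(self):
        pair = make_pair(n_mapped=0, similar=True)
        assert assign_paradigm(pair) == "mechanistic_only"

    def test_reaction_only(self):
        pair = make_pair(n_mapped=0, score=0.0)
        assert assign_paradigm(pair) == "reaction_only"

    def test_high_rmsd_is_not_structural(self):
        pair = make_pair(n_mapped=3, rmsd=4.04, score=1.0)
        assert assign_paradigm(pair) == "mechanistic_only"

    def test_spurious_flag_vetoes_structural(self):
        pair = make_pair(n_mapped=2, rmsd=1.63, similar=True, spurious=True)
        assert assign_paradigm(pair) == "mechanistic_only"

    def test_motif_only_when_mechanism_differs(self):
        pair = make_pair(n_mapped=2, rmsd=0.83, score=0.0)
        assert assign_paradigm(pair) == "structural_motif_only"

    def test_unknown_mechanism_is_unclassified(self):
        pair = make_pair(n_mapped=4, rmsd=1.0)
        pair.mech = classify_mechanism(None)
        assert assign_paradigm(pair) == "unclassified"

    def test_order_invariance(self):
        pair = make_pair(n_mapped=4, rmsd=1.45, score=0.30)
        flipped = make_pair(n_mapped=4, rmsd=1.45, score=0.30)
        flipped.entry_a, flipped.entry_b = flipped.entry_b, flipped.entry_a
        assert assign_paradigm(pair) == assign_paradigm(flipped)

    def test_survey_counts_fold_motif_into_structural(self):
        counts = classify_pairs(
            [make_pair(n_mapped=4, rmsd=1.0, score=0.5),
             make_pair(n_mapped=2, rmsd=0.8, score=0.0)]
        )
        folded = survey_counts(counts)
        assert folded["structural_and_mechanistic"] == 2
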