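"""Unit and property tests for the duplicate-exon assembly-error scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from asmqc import synthetic
from asmqc.dupexon import (
    ExonRecord,
    detect_false_chimers,
    local_similarity_filter,
    neighboring_pairs,
    nw_normalized_score,
    scan_assembly,
)
from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestNormalizedScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGTACGT", "ACGTACGT", 5.0),          # identity anchor
            ("AAAA", "TTTT", -4.0),                 # four transversions beat gapping
            ("ACGTACGT", "ACGAACGT", 3.875),        # (7*5 - 4) / 8, single mismatch
        ],
    )
    def test_frozen_examples(self, a, b, expected):
        assert nw_normalized_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_identity_of_long_random_sequence_is_exactly_five(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 300)
        assert nw_normalized_score(s, s) == 5.0

    def test_matches_exhaustive_path_enumeration_on_short_pairs(self):
        """The DP score equals the best score over every explicitly
        enumerated global alignment, and the normalization denominator is
        the column count of an optimal alignment."""
        rng = np.random.default_rng(5)
        sizes = [(rng.integers(1, 6), rng.integers(1, 6)) for _ in range(30)]
        sizes += [(7, 7), (8, 8), (8, 5)]  # up to the full enumerable range
        for la, lb in sizes:
            a = random_seq(rng, la)
            b = random_seq(rng, lb)
            best, lengths = oracles.best_global_alignment_bruteforce(a, b)
            norm = nw_normalized_score(a, b)
            assert any(norm == pytest.approx(best / L, abs=1e-9) for L in lengths), (
                a, b, best, lengths, norm
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        assert nw_normalized_score(a, b) == pytest.approx(nw_normalized_score(b, a))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna, dna)
    def test_five_iff_identical(self, a, b):
        score = nw_normalized_score(a, b)
        assert score <= 5.0
        assert (score == 5.0) == (a == b)

    def test_score_strictly_decreases_with_substitutions(self):
        rng = np.random.default_rng(9)
        original = random_seq(rng, 300)
        mutated = list(original)
        positions = rng.choice(300, size=30, replace=False)
        scores = [nw_normalized_score(original, original)]
        for k, p in enumerate(positions):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
            if (k + 1) % 5 == 0:
                scores.append(nw_normalized_score(original, "".join(mutated)))
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            nw_normalized_score("", "ACGT")
        with pytest.raises(ValueError):
            nw_normalized_score("ACGT", "ACQT")


class TestLocalFilter:
    def test_identical_sequences_pass_with_full_coverage(self):
        rng = np.random.default_rng(13)
        s = random_seq(rng, 300)
        passed, coverage, evalue = local_similarity_filter(s, s)
        assert passed and coverage == 1.0 and evalue < 1e-100

    def test_random_pairs_fail(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b = random_seq(rng, 300), random_seq(rng, 300)
            passed, _, _ = local_similarity_filter(a, b)
            assert not passed

    def test_forty_percent_shared_block_fails_on_coverage(self):
        """A highly significant alignment covering only 40% of the shorter
        sequence must fail regardless of its e-value."""
        rng = np.random.default_rng(19)
        a = random_seq(rng, 300)
        b = random_seq(rng, 90) + a[100:220] + random_seq(rng, 90)
        passed, coverage, evalue = local_similarity_filter(a, b)
        assert not passed
        # chance matches may extend the block by a few bases
        assert coverage == pytest.approx(0.4, abs=0.02)
        assert evalue < 1e-10  # significant, but coverage rules it out


class TestNeighboringPairs:
    def _exon(self, eid, contig, start, end):
        return ExonRecord(eid, contig, start, end, sequence="")

    def test_gap_within_window_retained(self):
        a = self._exon("a", "c1", 100, 200)
        b = self._exon("b", "c1", 1000, 1100)
        pairs = neighboring_pairs([a, b])
        assert [(p[0].exon_id, p[1].exon_id) for p in pairs] == [("a", "b")]

    def test_overlapping_pair_excluded(self):
        a = self._exon("a", "c1", 100, 200)
        b = self._exon("b", "c1", 150, 250)
        assert neighboring_pairs([a, b]) == []

    def test_different_contigs_excluded(self):
        a = self._exon("a", "c1", 100, 200)
        b = self._exon("b", "c2", 300, 400)
        assert neighboring_pairs([a, b]) == []

    def test_gap_boundary_inclusive_at_5kb(self):
        a = self._exon("a", "c1", 0, 100)
        at_limit = self._exon("b", "c1", 5100, 5200)     # gap exactly 5000
        beyond = self._exon("c", "c1", 10101, 10200)     # gap 5001 from b? use a fresh pair
        assert len(neighboring_pairs([a, at_limit])) == 1
        far = self._exon("d", "c1", 5101, 5200)          # gap 5001
        assert neighboring_pairs([a, far]) == []


class TestScanAssembly:
    def test_recall_on_planted_identical_duplicates(self):
        contigs, exons, truth = synthetic.gen_genome_with_duplications(
            n_contigs=2, contig_length=120_000, n_exons=10, n_planted=3,
            dup_length=300, max_substitutions=0, seed=23,
        )
        scored, tr_counts, gene_counts = scan_assembly(exons)
        flagged = {frozenset((s.exon_a, s.exon_b)) for s in scored if s.flagged}
        planted = {
            frozenset((d["source_exon"], d["copy_exon"]))
            for d in truth.planted_duplications
        }
        assert flagged == planted and len(flagged) == 3
        # every flagged exon contributes to its transcript and gene tallies
        assert sum(gene_counts.values()) == 6

    def test_no_false_positives_without_plants(self):
        _, exons, _ = synthetic.gen_genome_with_duplications(
            n_contigs=2, contig_length=120_000, n_exons=12, n_planted=0, seed=29,
        )
        scored, _, _ = scan_assembly(exons)
        assert all(not s.flagged for s in scored)

    def test_ten_percent_divergent_copy_not_flagged(self):
        """A copy with 10% substitutions scores ~5 - 0.9 = 4.1, below the
        4.8 near-identity threshold, so it is not called an assembly error."""
        rng = np.random.default_rng(31)
        seq = random_seq(rng, 200)
        copy = synthetic._mutate(seq, 20, rng)
        a = ExonRecord("a", "c1", 0, 200, sequence=seq)
        b = ExonRecord("b", "c1", 500, 700, sequence=copy)
        scored, _, _ = scan_assembly([a, b])
        assert len(scored) == 1  # still similar enough to pass the pre-filter
        assert not scored[0].flagged
        assert scored[0].norm_score < 4.8


class TestFalseChimers:
    def test_parts_hitting_adjacent_reference_genes_split_between_blocks(self):
        call = detect_false_chimers(
            "g1",
            {"p5": (0, 400), "p3": (600, 1000)},
            {"p5": ("refA", 7), "p3": ("refB", 8)},
        )
        assert call.is_chimer and call.split_coord == 500 and not call.needs_review

    def test_same_reference_gene_is_not_a_chimer(self):
        call = detect_false_chimers(
            "g2",
            {"p5": (0, 400), "p3": (600, 1000)},
            {"p5": ("refA", 7), "p3": ("refA", 7)},
        )
        assert not call.is_chimer

    def test_non_neighboring_reference_genes_not_a_chimer(self):
        call = detect_false_chimers(
            "g3",
            {"p5": (0, 400), "p3": (600, 1000)},
            {"p5": ("refA", 2), "p3": ("refB", 7)},
        )
        assert not call.is_chimer

    def test_overlapping_hit_blocks_flagged_for_review(self):
        call = detect_false_chimers(
            "g4",
            {"p5": (0, 700), "p3": (600, 1000)},
            {"p5": ("refA", 3), "p3": ("refB", 4)},
        )
        assert call.is_chimer and call.split_coord is None and call.needs_review
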