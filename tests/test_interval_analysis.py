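"""Global alignment, identity with N removal, classification, selection."""

import functools

import numpy as np
import pytest

from conftest import random_dna
from crprimer import (
    classify_locus,
    global_align,
    identity_after_n_removal,
    identity_histogram,
    select_candidates,
)
from crprimer.conserved_regions import CandidateLocus, ConservedRegion
from crprimer.interval_analysis import AlignScoring
from crprimer.seqio import GeneModel, GenomeAnnotation, ValidationError


def exhaustive_best_score(a: str, b: str, sc: AlignScoring) -> float:
    """Independent oracle: optimal global alignment score by recursive
    enumeration of all alignments with affine gap costs (state-tracked)."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j, state):  # state: 0 diagonal, 1 gap-in-B (A consumed), 2 gap-in-A
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            step = sc.match if a[i] == b[j] else sc.mismatch
            best = max(best, step + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = sc.gap_extend if state == 1 else sc.gap_open
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = sc.gap_extend if state == 2 else sc.gap_open
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_identical_sequences_gap_free(self, rng):
        seq = random_dna(rng, 80)
        row_a, row_b, score = global_align(seq, seq)
        assert row_a == row_b == seq
        assert score == 5.0 * len(seq)

    def test_single_gap_case_matches_enumeration(self):
        row_a, row_b, score = global_align("ACGT", "AGT")
        assert len(row_a) == len(row_b) == 4
        assert row_b.count("-") == 1
        assert score == exhaustive_best_score("ACGT", "AGT", AlignScoring())

    @pytest.mark.parametrize("trial", range(12))
    def test_score_matches_exhaustive_enumeration(self, trial):
        """All optimal scores agree with brute-force alignment enumeration
        on random pairs of length <= 8."""
        rng = np.random.default_rng(900 + trial)
        a = random_dna(rng, int(rng.integers(1, 9)))
        b = random_dna(rng, int(rng.integers(1, 9)))
        _ra, _rb, score = global_align(a, b)
        assert score == pytest.approx(exhaustive_best_score(a, b, AlignScoring()))

    def test_beats_any_ungapped_diagonal(self, rng):
        a = random_dna(rng, 30)
        b = random_dna(rng, 30)
        _ra, _rb, score = global_align(a, b)
        diagonal = sum(5.0 if x == y else -4.0 for x, y in zip(a, b))
        assert score >= diagonal

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACGT")


class TestIdentity:
    def test_identical(self, rng):
        seq = random_dna(rng, 100)
        rec = identity_after_n_removal(seq, seq)
        assert rec.identity == 1.0

    def test_one_mismatch_in_hundred(self, rng):
        a = random_dna(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        rec = identity_after_n_removal(a, b)
        assert rec.identity == pytest.approx(0.99)

    def test_n_removal_fixture(self, rng):
        """100 columns, 10 with N, 85 of the remaining 90 identical
        -> 85/90."""
        a = list(random_dna(rng, 100))
        b = list(a)
        for i in range(10):  # N columns (removed)
            b[i] = "N"
        for i in range(10, 15):  # mismatches among the kept 90
            b[i] = "A" if a[i] != "A" else "C"
        rec = identity_after_n_removal("".join(a), "".join(b))
        assert rec.columns_removed_N == 10
        assert rec.matches == 85
        assert rec.identity == pytest.approx(85 / 90)

    def test_gap_columns_count_in_denominator(self):
        rec = identity_after_n_removal("ACGT-ACGT", "ACGTTACGT")
        assert rec.identity == pytest.approx(8 / 9)

    def test_all_columns_removed_flagged_undefined(self):
        rec = identity_after_n_removal("NNNN", "ACGT")
        assert rec.identity is None and not rec.defined

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        assert (
            identity_after_n_removal(a, b).identity
            == identity_after_n_removal(b, a).identity
        )

    def test_monotone_in_substitutions(self, rng):
        """More planted substitutions never raise identity (in expectation,
        checked on seeded draws)."""
        base = random_dna(rng, 300)
        idents = []
        for rate in (0.02, 0.10, 0.25):
            mutated = "".join(
                "ACGT"[("ACGT".index(c) + 1) % 4] if rng.random() < rate else c
                for c in base
            )
            idents.append(identity_after_n_removal(base, mutated).identity)
        assert idents[0] > idents[1] > idents[2]


def _locus_in_gene(span_start, span_end, gene_len=1000):
    cr_l = ConservedRegion(("gA", "gB"), "A" * 25, (span_start, span_start + 25),
                           (span_start, span_start + 25))
    cr_r = ConservedRegion(("gA", "gB"), "A" * 25, (span_end - 25, span_end),
                           (span_end - 25, span_end))
    return CandidateLocus(
        locus_id="gA:0", cr_left=cr_l, cr_right=cr_r,
        ir_A=(span_start + 25, span_end - 25),
        ir_B=(span_start + 25, span_end - 25),
    )


@pytest.fixture()
def annotation():
    # gene with exons [0,300) and [700,1000), intron [300,700)
    gene = GeneModel(
        "gA", "chr1", "+", (0, 1000), ((0, 300), (700, 1000)), "A" * 1000
    )
    return GenomeAnnotation(sequences={"chr1": "A" * 1200}, genes=[gene])


class TestClassifyLocus:
    def test_wholly_exonic(self, annotation):
        rc = classify_locus(_locus_in_gene(10, 290), annotation)
        assert rc.region_class == "exon"

    def test_wholly_intronic(self, annotation):
        rc = classify_locus(_locus_in_gene(310, 690), annotation)
        assert rc.region_class == "intron"

    def test_spanning_junction_is_both(self, annotation):
        rc = classify_locus(_locus_in_gene(200, 600), annotation)
        assert rc.region_class == "both"

    def test_partition_sums(self, annotation):
        spans = [(10, 290), (310, 690), (200, 600), (250, 750), (320, 680)]
        classes = [
            classify_locus(_locus_in_gene(s, e), annotation).region_class
            for s, e in spans
        ]
        counts = {c: classes.count(c) for c in ("exon", "intron", "both")}
        assert sum(counts.values()) == len(spans)


class TestSelectCandidates:
    def test_band_inclusive_bounds(self):
        idents = {"l1": 0.74, "l2": 0.75, "l3": 0.90, "l4": 0.91}
        chroms = {k: "chr1" for k in idents}
        classes = {"l1": "exon", "l2": "exon", "l3": "intron", "l4": "both"}
        assert select_candidates(chroms, idents, classes) == ["l2", "l3"]

    def test_per_chromosome_quota(self):
        idents = {f"l{i}": 0.80 for i in range(5)}
        chroms = {k: "chr1" for k in idents}
        classes = {k: "exon" for k in idents}
        assert len(select_candidates(chroms, idents, classes)) == 2

    def test_round_robin_balances_classes(self):
        idents = {"a": 0.8, "b": 0.8, "c": 0.8}
        chroms = {k: "chr1" for k in idents}
        classes = {"a": "exon", "b": "exon", "c": "intron"}
        assert select_candidates(chroms, idents, classes) == ["a", "c"]

    def test_spread_across_chromosomes(self):
        idents = {f"l{i}": 0.8 for i in range(6)}
        chroms = {"l0": "chr1", "l1": "chr1", "l2": "chr2", "l3": "chr2",
                  "l4": "chr3", "l5": "chr3"}
        classes = {k: "exon" for k in idents}
        sel = select_candidates(chroms, idents, classes, per_chromosome=1)
        assert sel == ["l0", "l2", "l4"]

    def test_undefined_identity_excluded(self):
        sel = select_candidates(
            {"l1": "chr1"}, {"l1": None}, {"l1": "exon"}
        )
        assert sel == []


class TestIdentityHistogram:
    def test_terminal_bin_closed(self):
        edges, counts = identity_histogram([1.0, 1.0, 1.0])
        assert counts[-1] == 3 and counts.sum() == 3

    def test_counts_conserved(self, rng):
        vals = rng.uniform(0, 1, size=57)
        _edges, counts = identity_histogram(list(vals))
        assert counts.sum() == 57

    def test_divergence_shifts_mass_down(self, rng):
        """IRs simulated at 15% substitution concentrate at lower identity
        than IRs at 5%."""

        def idents(rate, n=40):
            out = []
            for _ in range(n):
                base = random_dna(rng, 400)
                mut = "".join(
                    "ACGT"[("ACGT".index(c) + 1) % 4]
                    if rng.random() < rate else c
                    for c in base
                )
                out.append(identity_after_n_removal(base, mut).identity)
            return out

        low = np.mean(idents(0.05))
        high_div = np.mean(idents(0.15))
        assert high_div < low
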