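"""Dummy-template assembly, nearest-neighbor Tm, and primer picking."""

import itertools

import pytest
from Bio.SeqUtils import MeltingTemp as mt

from conftest import random_dna
from crprimer import (
    DUMMY_SEQUENCE,
    PrimerConstraints,
    build_template,
    melting_temperature,
    pick_primer_pairs,
)
from crprimer.conserved_regions import CandidateLocus, ConservedRegion
from crprimer.primer_engine import (
    _max_complementary_run,
    gc_fraction,
    max_mononucleotide_run,
)
from crprimer.seqio import ValidationError, reverse_complement


def make_locus(left: str, right: str, ir_len: int = 400) -> CandidateLocus:
    la, ra = len(left), len(right)
    cr_l = ConservedRegion(("gA", "gB"), left, (0, la), (0, la))
    cr_r = ConservedRegion(
        ("gA", "gB"), right,
        (la + ir_len, la + ir_len + ra), (la + ir_len, la + ir_len + ra),
    )
    return CandidateLocus(
        locus_id="gA:0", cr_left=cr_l, cr_right=cr_r,
        ir_A=(la, la + ir_len), ir_B=(la, la + ir_len),
    )


class TestTemplate:
    def test_length_and_spans(self, rng):
        locus = make_locus(random_dna(rng, 30), random_dna(rng, 40))
        t = build_template(locus)
        assert len(t.sequence) == 30 + 108 + 40
        assert t.cr_left_span == (0, 30)
        assert t.cr_right_span == (138, 178)

    def test_dummy_slice(self, rng):
        locus = make_locus(random_dna(rng, 30), random_dna(rng, 40))
        t = build_template(locus)
        assert t.sequence[30:138] == "NNNN" + "AATT" * 25 + "NNNN"
        assert t.sequence[30:138] == DUMMY_SEQUENCE


class TestMeltingTemperature:
    def test_duplex_symmetry(self, rng):
        """An oligo and the sense strand read off its complement form the
        same duplex, hence identical Tm."""
        for _ in range(10):
            oligo = random_dna(rng, 22)
            assert melting_temperature(oligo) == pytest.approx(
                melting_temperature(reverse_complement(oligo)), abs=1e-9
            )

    def test_agrees_with_independent_nn_calculator(self, rng):
        """Panel of random 18-27-mers vs Biopython's Tm_NN under the same
        parameter table (unified NN) and solution conditions (50 mM Na+,
        1.5 mM Mg2+, 0.6 mM dNTP, 50 nM total strand)."""
        for _ in range(20):
            length = int(rng.integers(18, 28))
            oligo = random_dna(rng, length)
            ours = melting_temperature(oligo)
            ref = mt.Tm_NN(
                oligo, nn_table=mt.DNA_NN3, Na=50, Mg=1.5, dNTPs=0.6,
                dnac1=25, dnac2=25, saltcorr=5,
            )
            assert ours == pytest.approx(ref, abs=1.0)

    def test_gc_extension_never_cools_at_core(self):
        """Appending a G or C to any A/T-only 12-mer raises (or keeps) Tm.

        Exhaustive over all 4096 A/T 12-mers and both G/C extensions.
        """
        for bits in itertools.product("AT", repeat=12):
            core = "".join(bits)
            base_tm = melting_temperature(core)
            for ext in "GC":
                assert melting_temperature(core + ext) >= base_tm

    def test_rejects_n(self):
        with pytest.raises(ValidationError):
            melting_temperature("ACGTNACGTACG")

    def test_rejects_short(self):
        with pytest.raises(ValidationError):
            melting_temperature("ACGTACG")


def exhaustive_best_pair(template, cons):
    """Independent oracle: enumerate every legal (forward, reverse-site)
    substring pair, apply all hard constraints, recompute penalties."""
    seq = template.sequence
    ls, le = template.cr_left_span
    rs, re_ = template.cr_right_span

    def feasible(oligo):
        tm = melting_temperature(oligo, cons.thermo)
        if not (cons.min_tm <= tm <= cons.max_tm):
            return None
        gc = gc_fraction(oligo)
        if not (cons.min_gc <= gc <= cons.max_gc):
            return None
        if max_mononucleotide_run(oligo) > cons.max_poly_run:
            return None
        s_any, s_end = _max_complementary_run(oligo, oligo)
        if s_any > cons.max_self_any or s_end > cons.max_self_end:
            return None
        pen = (
            cons.weight_len * abs(len(oligo) - cons.opt_len)
            + cons.weight_tm * abs(tm - cons.opt_tm)
            + cons.weight_gc * abs(gc - cons.opt_gc)
        )
        return tm, pen

    best = None
    for fl in range(cons.min_len, cons.max_len + 1):
        for fs in range(ls, le - fl + 1):
            f = seq[fs : fs + fl]
            ff = feasible(f)
            if ff is None:
                continue
            for rl in range(cons.min_len, cons.max_len + 1):
                for rstart in range(rs, re_ - rl + 1):
                    r = reverse_complement(seq[rstart : rstart + rl])
                    rf = feasible(r)
                    if rf is None:
                        continue
                    if abs(ff[0] - rf[0]) > cons.max_tm_diff:
                        continue
                    p_any, p_end = _max_complementary_run(f, r)
                    if p_any > cons.max_pair_any or p_end > cons.max_pair_end:
                        continue
                    pen = ff[1] + rf[1] + cons.weight_tm_diff * abs(ff[0] - rf[0])
                    key = (pen, fs, fl, rstart, rl)
                    if best is None or key < best[0]:
                        best = (key, f, r)
    return best


class TestPickPrimerPairs:
    def test_short_cr_infeasible(self, rng):
        locus = make_locus(random_dna(rng, 17), random_dna(rng, 30))
        assert pick_primer_pairs(build_template(locus)) == []

    def test_forward_confined_to_left_cr(self):
        # moderately GC-rich 27-mers so the Tm window is reachable
        left = "GACGTCAGCATGCGTACCGGATCAGCG"
        right = "CCTGACGGTATGCACGGCTAGTCAGCG"
        locus = make_locus(left, right)
        for pair in pick_primer_pairs(build_template(locus)):
            assert pair.forward in left
            assert reverse_complement(pair.reverse) in right
            assert "N" not in pair.forward + pair.reverse

    def test_best_pair_matches_exhaustive_enumeration(self, rng):
        """On a fixed 30/30 bp fixture the returned best pair equals the
        brute-force optimum over all legal substring pairs."""
        rng_local = rng
        found = 0
        for _ in range(6):
            left = random_dna(rng_local, 30)
            right = random_dna(rng_local, 30)
            cons = PrimerConstraints(max_candidates_per_side=10_000)
            template = build_template(make_locus(left, right))
            pairs = pick_primer_pairs(template, cons)
            oracle = exhaustive_best_pair(template, cons)
            if oracle is None:
                assert pairs == []
                continue
            found += 1
            assert pairs, "picker missed a feasible pair the oracle found"
            assert (pairs[0].forward, pairs[0].reverse) == (oracle[1], oracle[2])
            assert pairs[0].penalty == pytest.approx(oracle[0][0])
        assert found >= 1  # the fixture panel must exercise the feasible path

    def test_no_primer_touches_dummy(self, rng):
        locus = make_locus(random_dna(rng, 35), random_dna(rng, 35))
        t = build_template(locus)
        for pair in pick_primer_pairs(t):
            assert pair.forward_span[1] <= t.cr_left_span[1]
            assert pair.reverse_span[0] >= t.cr_right_span[0]

    def test_determinism(self, rng):
        left, right = random_dna(rng, 40), random_dna(rng, 40)
        t = build_template(make_locus(left, right))
        first = pick_primer_pairs(t)
        second = pick_primer_pairs(t)
        assert first == second

    def test_product_range_arithmetic(self, rng):
        locus = make_locus(random_dna(rng, 30), random_dna(rng, 30), ir_len=450)
        t = build_template(locus)
        for pair in pick_primer_pairs(t):
            off_left = t.cr_left_span[1] - pair.forward_span[0]
            off_right = pair.reverse_span[1] - t.cr_right_span[0]
            assert pair.product_range == (
                450 + off_left + off_right, 450 + off_left + off_right
            )
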