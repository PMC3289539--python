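"""Primer picking confined to the two conserved regions of a candidate locus.

The interval region between the CRs is unknown in the target species, so it
must never contribute primer sequence.  A fixed 108-bp dummy spacer,
``NNNN + (AATT)x25 + NNNN``, replaces the interval before picking: its
terminal Ns make any primer leaking out of a CR detectable, and its
monotonous AT body is unpickable under the Tm/GC constraints anyway.

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia 1998 / Allawi & SantaLucia 1997) with an entropic salt
correction; defaults are 50 mM monovalent cation and 50 nM total oligo.
Constraint defaults mirror common primer3 practice (length 18-27 opt 20,
Tm 57-63 opt 60 deg C, GC 20-80%, pair Tm difference <= 3 deg C); everything
is exposed through :class:`PrimerConstraints`.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from functools import lru_cache

from .conserved_regions import CandidateLocus
from .seqio import Interval, ValidationError, reverse_complement

DUMMY_SEQUENCE = "NNNN" + "AATT" * 25 + "NNNN"  # 108 bp
assert len(DUMMY_SEQUENCE) == 108

# Unified NN parameters: (dH kcal/mol, dS cal/(mol*K)) per 5'->3' doublet.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation with a terminal G/C vs terminal A/T
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

R_GAS = 1.987  # cal/(mol*K)


@dataclass(frozen=True)
class ThermoParams:
    """Solution conditions for the nearest-neighbor Tm model.

    Defaults follow primer3's default PCR conditions: 50 mM monovalent
    cation, 1.5 mM Mg2+, 0.6 mM dNTP and 50 nM total oligo.  Divalent
    cations enter through the von Ahsen/Owczarzy conversion
    ``mono + 120*sqrt(Mg - dNTP)``; without it the standard 57-63 deg C
    picking window is unreachable for much of random sequence space.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.6
    oligo_nM: float = 50.0  # total strand concentration, non-self-complementary

    @property
    def effective_monovalent_mM(self) -> float:
        excess = max(0.0, self.divalent_mM - self.dntp_mM)
        return self.monovalent_mM + 120.0 * math.sqrt(excess)


def melting_temperature(oligo: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Tm = 1000*dH / (dS + R ln(C_T/4)) - 273.15 with the entropic salt
    correction dS += 0.368 (L-1) ln[Na+].  Deterministic; rejects any base
    outside {A,C,G,T}.
    """
    params = params or ThermoParams()
    if len(oligo) < 8:
        raise ValidationError("oligo shorter than 8 bases")
    if set(oligo) - set("ACGT"):
        raise ValidationError(f"oligo contains non-ACGT characters: {oligo!r}")
    dh, ds = 0.0, 0.0
    for i in range(len(oligo) - 1):
        h, s = NN_UNIFIED[oligo[i : i + 2]]
        dh += h
        ds += s
    for terminal in (oligo[0], oligo[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    na = params.effective_monovalent_mM / 1000.0
    ds += 0.368 * (len(oligo) - 1) * math.log(na)
    ct = params.oligo_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / 4.0)) - 273.15


def gc_fraction(oligo: str) -> float:
    """GC content in percent."""
    return 100.0 * sum(1 for b in oligo if b in "GC") / len(oligo)


def max_mononucleotide_run(oligo: str) -> int:
    best = run = 1
    for i in range(1, len(oligo)):
        run = run + 1 if oligo[i] == oligo[i - 1] else 1
        best = max(best, run)
    return best


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _max_complementary_run(s1: str, s2: str) -> tuple[int, int]:
    """Longest contiguous complementary stretch between two oligos in any
    antiparallel annealing register.

    Returns ``(anywhere, at_3prime)`` where ``at_3prime`` is the longest run
    that includes the 3'-terminal base of either oligo.  This is a
    simplified, deterministic stand-in for primer3's alignment-based
    self/pair complementarity scores.
    """
    r2 = s2[::-1]  # antiparallel
    best_any = 0
    best_end = 0
    for off in range(-(len(r2) - 1), len(s1)):
        run = 0
        for i in range(len(s1)):
            j = i - off
            if 0 <= j < len(r2) and _COMPLEMENT[s1[i]] == r2[j]:
                run += 1
                best_any = max(best_any, run)
                # run touching s1's 3' end or s2's 3' end (j == len(r2)-1 is
                # s2[0]; s2's 3' end is j == 0)
                if i == len(s1) - 1 or j == 0:
                    best_end = max(best_end, run)
            else:
                run = 0
    return best_any, best_end


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard constraints and penalty weights for primer picking."""

    min_len: int = 18
    opt_len: int = 20
    max_len: int = 27
    min_tm: float = 57.0
    opt_tm: float = 60.0
    max_tm: float = 63.0
    min_gc: float = 20.0
    opt_gc: float = 50.0
    max_gc: float = 80.0
    max_tm_diff: float = 3.0
    max_poly_run: int = 4
    max_self_any: int = 8
    max_self_end: int = 3
    max_pair_any: int = 8
    max_pair_end: int = 3
    weight_len: float = 1.0
    weight_tm: float = 1.0
    weight_gc: float = 0.0
    weight_tm_diff: float = 0.0
    max_candidates_per_side: int = 30
    num_return: int = 5
    thermo: ThermoParams = field(default_factory=ThermoParams)


@dataclass(frozen=True)
class DesignTemplate:
    """cr_left + dummy + cr_right, the sequence handed to primer picking."""

    locus: CandidateLocus
    sequence: str
    cr_left_span: Interval
    cr_right_span: Interval


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair with thermodynamics and template coords.

    ``forward`` is a verbatim substring of the left CR.  ``reverse`` is the
    reverse complement of its binding site, a substring of the right CR; it
    is stored 5'->3' as it would be synthesised.  ``product_range`` is the
    (min, max) predicted product size over the two reference genomes:
    IR length plus the primer-to-inner-CR-edge offsets.
    """

    forward: str
    reverse: str
    forward_span: Interval  # within template
    reverse_span: Interval  # binding site within template
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_range: tuple[int, int]
    penalty: float


def build_template(locus: CandidateLocus) -> DesignTemplate:
    """Assemble the design template for one candidate locus."""
    left = locus.cr_left.seq
    right = locus.cr_right.seq
    seq = left + DUMMY_SEQUENCE + right
    return DesignTemplate(
        locus=locus,
        sequence=seq,
        cr_left_span=(0, len(left)),
        cr_right_span=(len(left) + len(DUMMY_SEQUENCE), len(seq)),
    )


@dataclass(frozen=True)
class _Candidate:
    start: int
    length: int
    oligo: str  # 5'->3' as synthesised
    tm: float
    gc: float
    penalty: float


def _single_primer_candidates(
    region: str,
    region_offset: int,
    cons: PrimerConstraints,
    reverse: bool,
) -> list[_Candidate]:
    """Feasible oligos fully inside one CR, sorted by penalty then position.

    The quadratic self-complementarity check runs lazily, on the
    penalty-sorted prefix, until ``max_candidates_per_side`` survivors are
    found — equivalent to filtering everything first and then truncating.
    """
    pre: list[_Candidate] = []
    n = len(region)
    for length in range(cons.min_len, cons.max_len + 1):
        for start in range(0, n - length + 1):
            site = region[start : start + length]
            oligo = reverse_complement(site) if reverse else site
            if "N" in oligo:
                continue
            tm = melting_temperature(oligo, cons.thermo)
            if not (cons.min_tm <= tm <= cons.max_tm):
                continue
            gc = gc_fraction(oligo)
            if not (cons.min_gc <= gc <= cons.max_gc):
                continue
            if max_mononucleotide_run(oligo) > cons.max_poly_run:
                continue
            penalty = (
                cons.weight_len * abs(length - cons.opt_len)
                + cons.weight_tm * abs(tm - cons.opt_tm)
                + cons.weight_gc * abs(gc - cons.opt_gc)
            )
            pre.append(
                _Candidate(region_offset + start, length, oligo, tm, gc, penalty)
            )
    pre.sort(key=lambda c: (c.penalty, c.start, c.length))
    out: list[_Candidate] = []
    for cand in pre:
        s_any, s_end = _self_complementarity(cand.oligo)
        if s_any > cons.max_self_any or s_end > cons.max_self_end:
            continue
        out.append(cand)
        if len(out) >= cons.max_candidates_per_side:
            break
    return out


@lru_cache(maxsize=65536)
def _self_complementarity(oligo: str) -> tuple[int, int]:
    return _max_complementary_run(oligo, oligo)


def pick_primer_pairs(
    template: DesignTemplate, constraints: PrimerConstraints | None = None
) -> list[PrimerPair]:
    """Enumerate constraint-satisfying primer pairs, best (lowest penalty) first.

    The forward primer is confined to the left CR and the reverse primer's
    binding site to the right CR.  Pair feasibility adds the Tm-difference
    and cross-complementarity limits.  The per-side candidate lists are
    truncated to ``max_candidates_per_side`` (by single-primer penalty)
    before pairing; since the pair penalty is separable this returns the
    optimal pair whenever both its members rank within the truncation.
    Returns at most ``num_return`` pairs; an empty list signals design
    failure for the locus.
    """
    cons = constraints or PrimerConstraints()
    seq = template.sequence
    ls, le = template.cr_left_span
    rs, re_ = template.cr_right_span
    fwd = _single_primer_candidates(seq[ls:le], ls, cons, reverse=False)
    rev = _single_primer_candidates(seq[rs:re_], rs, cons, reverse=True)
    if not fwd or not rev:
        return []

    # best-first search over candidate index pairs: f.penalty + r.penalty is
    # a lower bound on the pair penalty, so popping in bound order and
    # stopping once the bound exceeds the current num_return-th best actual
    # penalty is exact
    locus = template.locus
    heap: list[tuple[float, int, int]] = [(fwd[0].penalty + rev[0].penalty, 0, 0)]
    pushed = {(0, 0)}
    accepted: list[tuple[tuple, _Candidate, _Candidate, float]] = []
    while heap:
        bound, fi, ri = heapq.heappop(heap)
        if len(accepted) >= cons.num_return:
            kth = sorted(a[3] for a in accepted)[cons.num_return - 1]
            if bound > kth:
                break
        f, r = fwd[fi], rev[ri]
        if abs(f.tm - r.tm) <= cons.max_tm_diff:
            p_any, p_end = _max_complementary_run(f.oligo, r.oligo)
            if p_any <= cons.max_pair_any and p_end <= cons.max_pair_end:
                penalty = (
                    f.penalty + r.penalty + cons.weight_tm_diff * abs(f.tm - r.tm)
                )
                key = (penalty, f.start, f.length, r.start, r.length)
                accepted.append((key, f, r, penalty))
        for nfi, nri in ((fi + 1, ri), (fi, ri + 1)):
            if nfi < len(fwd) and nri < len(rev) and (nfi, nri) not in pushed:
                pushed.add((nfi, nri))
                heapq.heappush(
                    heap, (fwd[nfi].penalty + rev[nri].penalty, nfi, nri)
                )
    accepted.sort(key=lambda t: t[0])

    pairs: list[PrimerPair] = []
    for _key, f, r, penalty in accepted[: cons.num_return]:
        # offsets from the primer to the inner CR edge, per product arithmetic
        off_left = le - f.start
        off_right = (r.start - rs) + r.length
        sizes = (
            off_left + locus.ir_len_A + off_right,
            off_left + locus.ir_len_B + off_right,
        )
        pairs.append(
            PrimerPair(
                forward=f.oligo,
                reverse=r.oligo,
                forward_span=(f.start, f.start + f.length),
                reverse_span=(r.start, r.start + r.length),
                tm_f=f.tm,
                tm_r=r.tm,
                gc_f=f.gc,
                gc_r=r.gc,
                product_range=(min(sizes), max(sizes)),
                penalty=penalty,
            )
        )
    return pairs
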