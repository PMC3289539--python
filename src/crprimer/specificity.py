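"""Genome-wide specificity screening of primer sequences.

Each primer is searched against both whole reference genomes with an
ungapped seed-and-extend local search (word size 11, match +1 / mismatch -2
by default) and hits are assigned Karlin-Altschul expectation values,
E = K * m * n * exp(-lambda * S).  At primer scale (<= 27 bases) gapped
alignment adds nothing, so the search is a faithful, deterministic
equivalent of a word-based heuristic search engine for these queries.

A primer pair passes the screen only if, in *both* genomes, every hit with
E below the threshold (default 0.1) coincides with the site the primer was
designed from (the genomic projection of its conserved region).  Because a
local hit and its reverse-orientation twin describe the same physical
duplex site, self-site overlap is tested irrespective of hit strand.

lambda and K are computed numerically for the configured scoring scheme at
startup: lambda as the positive root of sum_s p_s exp(lambda s) = 1 and K
through the lattice-case series of the asymptotic theory of maximal
segment scores.  For +1/-2 this yields lambda = 1.33, K = 0.621, matching
the published ungapped constants.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from scipy.optimize import brentq

from .seqio import Interval, ValidationError, reverse_complement


@dataclass(frozen=True)
class SearchScoring:
    """Ungapped local-search scoring scheme and statistics knobs."""

    match: int = 1
    mismatch: int = -2
    word_size: int = 11
    xdrop: int = 20
    evalue_ceiling: float = 10.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValidationError("need match > 0 and mismatch < 0")


@lru_cache(maxsize=16)
def karlin_altschul_params(
    match: int, mismatch: int, p_match: float = 0.25
) -> tuple[float, float, float]:
    """(lambda, K, H) for an ungapped two-score scheme under uniform
    background composition.

    lambda solves E[exp(lambda X)] = 1.  K uses the lattice-case constant
    K = d exp(-2 sigma) / (E[X exp(lambda X)] (1 - exp(-lambda d))) with
    d = gcd of the scores and sigma the partial-sum series
    sum_k (1/k)[P(S_k >= 0) + P~(S_k < 0)], P~ the lambda-tilted walk.
    """
    p = {match: p_match, mismatch: 1.0 - p_match}

    def f(lam: float) -> float:
        return sum(pr * math.exp(lam * s) for s, pr in p.items()) - 1.0

    lam = brentq(f, 1e-9, 20.0, xtol=1e-14)
    exs = sum(pr * s * math.exp(lam * s) for s, pr in p.items())
    H = lam * exs
    d = math.gcd(abs(match), abs(mismatch))
    tilted = {s: pr * math.exp(lam * s) for s, pr in p.items()}

    dist: dict[int, float] = {0: 1.0}
    dist_t: dict[int, float] = {0: 1.0}
    sigma = 0.0
    for k in range(1, 500):
        nd: dict[int, float] = defaultdict(float)
        for v, pr in dist.items():
            for s, ps in p.items():
                nd[v + s] += pr * ps
        dist = dict(nd)
        ndt: dict[int, float] = defaultdict(float)
        for v, pr in dist_t.items():
            for s, ps in tilted.items():
                ndt[v + s] += pr * ps
        dist_t = dict(ndt)
        term = (
            sum(pr for v, pr in dist.items() if v >= 0)
            + sum(pr for v, pr in dist_t.items() if v < 0)
        )
        sigma += term / k
        if term / k < 1e-12 and k > 30:
            break
    K = d * math.exp(-2.0 * sigma) / (exs * (1.0 - math.exp(-lam * d)))
    return lam, K, H


@dataclass(frozen=True)
class SearchHit:
    """One ungapped local hit of a query in a genome."""

    query_id: str
    chromosome: str
    strand: str  # strand of the genome the query matches as given
    query_span: Interval
    subject_span: Interval  # plus-strand genomic coordinates
    score: int
    evalue: float


class GenomeIndex:
    """A genome with a reusable word index for seed lookups."""

    def __init__(self, sequences: Mapping[str, str], word_size: int = 11):
        self.sequences = dict(sequences)
        self.word_size = word_size
        self.total_length = sum(len(s) for s in self.sequences.values())
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(self.sequences):
            seq = self.sequences[chrom]
            for i in range(len(seq) - word_size + 1):
                word = seq[i : i + word_size]
                if "N" not in word:
                    self._index[word].append((chrom, i))

    def seed_positions(self, word: str) -> list[tuple[str, int]]:
        return self._index.get(word, [])


def _extend_on_diagonal(
    query: str, subject: str, qpos: int, spos: int, word: int,
    scoring: SearchScoring,
) -> tuple[int, int, int]:
    """Maximal-scoring ungapped segment around an exact word seed.

    Returns ``(query_start, subject_start, score)`` of the best-scoring
    segment containing the seed; the segment length is recovered from the
    symmetric right extension.  X-drop terminates extension once the
    running score falls ``xdrop`` below the best seen.
    """
    m, n = len(query), len(subject)
    score = word * scoring.match

    # right extension
    best_right, run = 0, 0
    i, j = qpos + word, spos + word
    while i < m and j < n:
        run += scoring.match if query[i] == subject[j] and query[i] != "N" else scoring.mismatch
        if run > best_right:
            best_right = run
        if run < best_right - scoring.xdrop:
            break
        i += 1
        j += 1
    # left extension
    best_left, run = 0, 0
    li, lj = qpos - 1, spos - 1
    best_li = qpos
    while li >= 0 and lj >= 0:
        run += scoring.match if query[li] == subject[lj] and query[li] != "N" else scoring.mismatch
        if run > best_left:
            best_left = run
            best_li = li
        if run < best_left - scoring.xdrop:
            break
        li -= 1
        lj -= 1
    qstart = best_li if best_left > 0 else qpos
    shift = qpos - qstart
    return qstart, spos - shift, score + best_right + best_left


def search_genome(
    query: str,
    genome: GenomeIndex | Mapping[str, str],
    scoring: SearchScoring | None = None,
    query_id: str = "query",
) -> list[SearchHit]:
    """All ungapped local hits of ``query`` in a genome, both strands,
    with E-value below the report ceiling.

    E = K*m*n*exp(-lambda*S) with m the query length and n the total
    length of both strands of the genome.
    """
    scoring = scoring or SearchScoring()
    if len(query) < scoring.word_size:
        raise ValidationError(
            f"query length {len(query)} < word size {scoring.word_size}"
        )
    if not isinstance(genome, GenomeIndex):
        genome = GenomeIndex(genome, scoring.word_size)
    lam, K, _H = karlin_altschul_params(scoring.match, scoring.mismatch)
    m = len(query)
    n_db = 2 * genome.total_length  # both strands are searched

    hits: list[SearchHit] = []
    seen: set[tuple[str, str, int, int]] = set()
    w = scoring.word_size
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        for qpos in range(m - w + 1):
            word = q[qpos : qpos + w]
            if "N" in word:
                continue
            for chrom, spos in genome.seed_positions(word):
                subject = genome.sequences[chrom]
                qstart, sstart, score = _extend_on_diagonal(
                    q, subject, qpos, spos, w, scoring
                )
                key = (chrom, strand, sstart, score)
                if key in seen:
                    continue
                seen.add(key)
                evalue = K * m * n_db * math.exp(-lam * score)
                if evalue >= scoring.evalue_ceiling:
                    continue
                # recover segment length by rescanning from the start
                length = _segment_length(q, subject, qstart, sstart, score, scoring)
                qs, qe = qstart, qstart + length
                if strand == "-":
                    qs, qe = m - qe, m - qs  # report in query coordinates
                hits.append(
                    SearchHit(
                        query_id=query_id,
                        chromosome=chrom,
                        strand=strand,
                        query_span=(qs, qe),
                        subject_span=(sstart, sstart + length),
                        score=score,
                        evalue=evalue,
                    )
                )
    hits.sort(key=lambda h: (h.chromosome, h.subject_span, h.strand))
    return hits


def _segment_length(
    query: str, subject: str, qstart: int, sstart: int, target_score: int,
    scoring: SearchScoring,
) -> int:
    """Length of the maximal-scoring segment starting at (qstart, sstart)."""
    score = 0
    best, best_len = -(10**9), 0
    i, j, length = qstart, sstart, 0
    while i < len(query) and j < len(subject):
        score += (
            scoring.match
            if query[i] == subject[j] and query[i] != "N"
            else scoring.mismatch
        )
        length += 1
        if score > best:
            best, best_len = score, length
        if score == target_score:
            best_len = length
            break
        i += 1
        j += 1
    return best_len


@dataclass(frozen=True)
class SpecificityVerdict:
    primer_pair_id: str
    passed: bool
    offending_hits: tuple[SearchHit, ...] = ()


@dataclass(frozen=True)
class PrimerSelfSites:
    """Genomic projections of a primer pair's design sites in one genome.

    Each entry is ``(chromosome, start, end)`` on the plus strand — the
    projection of the primer's position within its conserved region onto
    the genome via the host gene model.
    """

    forward: tuple[str, int, int]
    reverse: tuple[str, int, int]

    def overlaps(self, hit: SearchHit) -> bool:
        for chrom, s, e in (self.forward, self.reverse):
            if hit.chromosome == chrom and hit.subject_span[0] < e and s < hit.subject_span[1]:
                return True
        return False


def screen_primer_pair(
    forward: str,
    reverse: str,
    genomes: Mapping[str, GenomeIndex],
    self_sites: Mapping[str, PrimerSelfSites],
    evalue_threshold: float = 0.1,
    scoring: SearchScoring | None = None,
    primer_pair_id: str = "pair",
) -> SpecificityVerdict:
    """Pass iff every sub-threshold hit in *both* genomes is a self-site.

    ``self_sites`` maps genome name -> the projected design-site intervals;
    a hit overlapping a projected site by at least one base counts as self
    (coordinate jitter from extension must not cause false failures).
    A genome missing from ``self_sites`` raises :class:`ValidationError` —
    a locus without a genomic projection cannot be screened.
    """
    scoring = scoring or SearchScoring()
    offending: list[SearchHit] = []
    for name in sorted(genomes):
        if name not in self_sites:
            raise ValidationError(f"no genomic projection for genome {name!r}")
        sites = self_sites[name]
        for oligo, qid in ((forward, "forward"), (reverse, "reverse")):
            for hit in search_genome(
                oligo, genomes[name], scoring, query_id=f"{primer_pair_id}/{qid}"
            ):
                if hit.evalue < evalue_threshold and not sites.overlaps(hit):
                    offending.append(hit)
    return SpecificityVerdict(
        primer_pair_id=primer_pair_id,
        passed=not offending,
        offending_hits=tuple(offending),
    )


@dataclass(frozen=True)
class Amplicon:
    chromosome: str
    span: Interval  # outer span, plus-strand
    forward_is_left: bool


def _find_occurrences(pattern: str, text: str, max_mismatch: int = 0) -> list[int]:
    if max_mismatch == 0:
        out = []
        i = text.find(pattern)
        while i != -1:
            out.append(i)
            i = text.find(pattern, i + 1)
        return out
    out = []
    m = len(pattern)
    for i in range(len(text) - m + 1):
        mism = sum(1 for a, b in zip(pattern, text[i : i + m]) if a != b)
        if mism <= max_mismatch:
            out.append(i)
    return out


def insilico_pcr(
    forward: str,
    reverse: str,
    genome: Mapping[str, str],
    max_product: int = 2000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predicted amplicons: convergent primer binding sites within
    ``max_product`` bases.

    An occurrence of a primer's sequence verbatim primes rightward
    synthesis; an occurrence of its reverse complement primes leftward.
    Any rightward site of either primer paired with a downstream leftward
    site of either primer yields an amplicon (the outer span).
    """
    out: list[Amplicon] = []
    sequences = genome.sequences if isinstance(genome, GenomeIndex) else genome
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        rightward = [
            (pos, len(forward), True)
            for pos in _find_occurrences(forward, seq, max_mismatch)
        ] + [
            (pos, len(reverse), False)
            for pos in _find_occurrences(reverse, seq, max_mismatch)
        ]
        leftward = [
            (pos, len(forward), True)
            for pos in _find_occurrences(reverse_complement(forward), seq, max_mismatch)
        ] + [
            (pos, len(reverse), False)
            for pos in _find_occurrences(reverse_complement(reverse), seq, max_mismatch)
        ]
        for rpos, rlen, r_is_f in rightward:
            for lpos, llen, _l_is_f in leftward:
                if rpos > lpos:
                    continue  # not convergent
                length = (lpos + llen) - rpos
                if rlen <= length <= max_product:
                    out.append(
                        Amplicon(
                            chromosome=chrom,
                            span=(rpos, rpos + length),
                            forward_is_left=r_is_f,
                        )
                    )
    out.sort(key=lambda a: (a.chromosome, a.span))
    return out
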