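"""Conserved-region detection between orthologous unspliced gene pairs.

A conserved region (CR) is a maximal, perfectly identical block of at least
``min_cr_len`` bases (default 20) shared between the two unspliced gene
sequences.  ``N`` never matches anything, including another ``N``, so a CR
is always N-free.  Two CRs whose inner gap lies within the candidate
interval (default 300-700 bp, inclusive, on *both* genes) flank an interval
region (IR) — the putatively polymorphic amplification target.

Detection is exact k-mer seeding (k = ``min_cr_len``) with bidirectional
maximal extension, deduplicated to maximal blocks.  Because the criterion is
perfect identity, this enumerates exactly the same set of blocks a
heuristic word-based search engine would find, but deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import Interval, OrthologTable, ValidationError

MATCHABLE = frozenset("ACGT")


@dataclass(frozen=True)
class ConservedRegion:
    """A maximal perfectly identical block between an orthologous gene pair."""

    gene_pair: tuple[str, str]
    seq: str
    posA: Interval  # on unspliced gene A, transcript orientation
    posB: Interval  # on unspliced gene B

    def __post_init__(self) -> None:
        if "N" in self.seq:
            raise ValidationError("conserved region may not contain N")
        la = self.posA[1] - self.posA[0]
        lb = self.posB[1] - self.posB[0]
        if not (la == lb == len(self.seq)):
            raise ValidationError("conserved region coordinates inconsistent")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CandidateLocus:
    """Two CRs flanking an interval region on both genes."""

    locus_id: str
    cr_left: ConservedRegion
    cr_right: ConservedRegion
    ir_A: Interval
    ir_B: Interval
    interval_bounds: tuple[int, int] = (300, 700)
    overlapping: bool = False  # shares gene-A territory with another locus

    @property
    def gene_pair(self) -> tuple[str, str]:
        return self.cr_left.gene_pair

    @property
    def ir_len_A(self) -> int:
        return self.ir_A[1] - self.ir_A[0]

    @property
    def ir_len_B(self) -> int:
        return self.ir_B[1] - self.ir_B[0]

    def amplified_span_A(self) -> Interval:
        """Outer CR edge to outer CR edge on gene A (the amplified span)."""
        return (self.cr_left.posA[0], self.cr_right.posA[1])

    def amplified_span_B(self) -> Interval:
        return (self.cr_left.posB[0], self.cr_right.posB[1])


def filter_orthologs(table: OrthologTable) -> list[tuple[str, str]]:
    """Keep only one-to-one ortholog rows.

    One-to-many and many-to-many relationships are dropped to avoid genes
    with lineage-specific duplications, whose primers could co-amplify
    paralogous fragments.  A gene id appearing twice among the retained rows
    contradicts the one-to-one claim and raises :class:`ValidationError`.
    """
    kept = [(a, b) for a, b, ht in table.rows if ht == "one2one"]
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a, b in kept:
        if a in seen_a:
            raise ValidationError(f"gene {a!r} appears in multiple one2one rows")
        if b in seen_b:
            raise ValidationError(f"gene {b!r} appears in multiple one2one rows")
        seen_a.add(a)
        seen_b.add(b)
    return kept


def find_conserved_regions(
    seqA: str,
    seqB: str,
    min_cr_len: int = 20,
    gene_pair: tuple[str, str] = ("A", "B"),
) -> list[ConservedRegion]:
    """All maximal exact matches of length >= ``min_cr_len`` between two
    sequences, sorted by start on sequence A (ties by start on B).

    A block is maximal when it cannot be extended by one base on either side
    without hitting a mismatch, an ``N``, or a sequence end.  Repeated
    occurrences of the same subsequence generate all placements; the
    downstream specificity screen is responsible for rejecting non-unique
    primer sites.
    """
    k = min_cr_len
    n, m = len(seqA), len(seqB)
    if n < k or m < k:
        return []

    # index k-mers of B (N-free only)
    index: dict[str, list[int]] = {}
    for j in range(m - k + 1):
        word = seqB[j : j + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)

    seen: set[tuple[int, int]] = set()
    out: list[ConservedRegion] = []
    for i in range(n - k + 1):
        word = seqA[i : i + k]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            # extend left
            li, lj = i, j
            while (
                li > 0
                and lj > 0
                and seqA[li - 1] == seqB[lj - 1]
                and seqA[li - 1] in MATCHABLE
            ):
                li -= 1
                lj -= 1
            key = (li, lj)
            if key in seen:
                continue
            seen.add(key)
            # extend right
            ri, rj = i + k, j + k
            while (
                ri < n
                and rj < m
                and seqA[ri] == seqB[rj]
                and seqA[ri] in MATCHABLE
            ):
                ri += 1
                rj += 1
            out.append(
                ConservedRegion(
                    gene_pair=gene_pair,
                    seq=seqA[li:ri],
                    posA=(li, ri),
                    posB=(lj, rj),
                )
            )
    out.sort(key=lambda cr: (cr.posA, cr.posB))
    return out


def enumerate_candidate_loci(
    crs: list[ConservedRegion],
    seqA_len: int | None = None,
    seqB_len: int | None = None,
    interval: tuple[int, int] = (300, 700),
) -> list[CandidateLocus]:
    """All ordered CR pairs whose inner gap lies in ``interval`` on both genes.

    The gap is measured between the inner edges (end of the left CR to start
    of the right CR) and the bounds are inclusive.  The constraint applies on
    both genes, since the interval region must exist at comparable scale in
    both references for its identity to be informative.  Loci sharing gene-A
    territory with another locus are flagged ``overlapping``.
    """
    lo, hi = interval
    loci: list[CandidateLocus] = []
    ordered = sorted(crs, key=lambda cr: (cr.posA, cr.posB))
    for a in ordered:
        for b in ordered:
            if a is b:
                continue
            if a.posA[1] > b.posA[0] or a.posB[1] > b.posB[0]:
                continue  # must precede without overlap on both genes
            gap_a = b.posA[0] - a.posA[1]
            gap_b = b.posB[0] - a.posB[1]
            if lo <= gap_a <= hi and lo <= gap_b <= hi:
                loci.append(
                    CandidateLocus(
                        locus_id="",
                        cr_left=a,
                        cr_right=b,
                        ir_A=(a.posA[1], b.posA[0]),
                        ir_B=(a.posB[1], b.posB[0]),
                        interval_bounds=interval,
                    )
                )
    loci.sort(key=lambda lc: (lc.ir_A, lc.ir_B))

    # assign ids and flag gene-A overlaps among amplified spans
    spans = [lc.amplified_span_A() for lc in loci]
    final: list[CandidateLocus] = []
    gene_a = crs[0].gene_pair[0] if crs else "A"
    for idx, lc in enumerate(loci):
        s, e = spans[idx]
        overlaps = any(
            i != idx and spans[i][0] < e and s < spans[i][1]
            for i in range(len(spans))
        )
        final.append(
            CandidateLocus(
                locus_id=f"{gene_a}:{idx}",
                cr_left=lc.cr_left,
                cr_right=lc.cr_right,
                ir_A=lc.ir_A,
                ir_B=lc.ir_B,
                interval_bounds=interval,
                overlapping=overlaps,
            )
        )
    return final
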