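"""Interval-region identity, exon/intron classification, candidate selection.

The two reference IR sequences are globally aligned (Needleman-Wunsch with
affine gaps; the pairwise special case of a progressive multiple aligner)
and their identity computed after removing every alignment column that
contains an unknown base (N) in either row.  Gap columns stay in the
denominator — the most conservative reading of "identity".

Loci are classified by where their amplified span (outer CR edge to outer
CR edge) falls in the anchor genome's annotation: exon only, intron only,
or both.  Selection then applies the three candidate criteria: identity
within the band (default 75-90%, inclusive), at most ``per_chromosome``
loci per anchor chromosome, and a round-robin balance over the three
region classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .conserved_regions import CandidateLocus
from .seqio import GenomeAnnotation, Interval, ValidationError


@dataclass(frozen=True)
class AlignScoring:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0   # score of a length-1 gap
    gap_extend: float = -0.5  # each additional gap position


def global_align(
    irA: str, irB: str, scoring: AlignScoring | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment of two IR sequences.

    Returns ``(rowA, rowB, score)`` where the rows are equal-length gapped
    strings.  End gaps are penalised like internal gaps.  Tie-breaking
    follows the aligner's canonical traceback order and is deterministic
    for fixed inputs.
    """
    if not irA or not irB:
        raise ValidationError("cannot align an empty sequence")
    scoring = scoring or AlignScoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # N is an unknown base, not a match to itself: score every N column as
    # a mismatch so alignment placement is unaffected by N runs
    if "N" in irA or "N" in irB:
        from Bio.Align import substitution_matrices

        alphabet = "ACGTN"
        mat = substitution_matrices.Array(alphabet, dims=2)
        for x in alphabet:
            for y in alphabet:
                if x == y and x != "N":
                    mat[x, y] = scoring.match
                else:
                    mat[x, y] = scoring.mismatch
        aligner.substitution_matrix = mat
    aln = aligner.align(irA, irB)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


@dataclass(frozen=True)
class IdentityRecord:
    """Identity of one aligned IR pair after N-column removal."""

    locus_id: str
    rowA: str
    rowB: str
    columns_total: int
    columns_removed_N: int
    matches: int
    identity: float | None  # None when every column was removed

    @property
    def defined(self) -> bool:
        return self.identity is not None


def identity_after_n_removal(
    rowA: str, rowB: str, locus_id: str = ""
) -> IdentityRecord:
    """Fraction of identical columns after dropping columns with an N.

    A column counts as a match only when both rows carry the same A/C/G/T
    base; gap columns count in the denominator.  If every column contains
    an N the identity is undefined and flagged as ``None`` (neither 0 nor
    1 would be honest).
    """
    if len(rowA) != len(rowB):
        raise ValidationError("alignment rows differ in length")
    total = len(rowA)
    removed = 0
    matches = 0
    for a, b in zip(rowA, rowB):
        if a == "N" or b == "N":
            removed += 1
        elif a == b and a != "-":
            matches += 1
    kept = total - removed
    identity = None if kept == 0 else matches / kept
    return IdentityRecord(
        locus_id=locus_id,
        rowA=rowA,
        rowB=rowB,
        columns_total=total,
        columns_removed_N=removed,
        matches=matches,
        identity=identity,
    )


@dataclass(frozen=True)
class RegionClass:
    locus_id: str
    region_class: str  # "exon" | "intron" | "both"
    basis: dict[str, tuple[bool, bool]]  # genome -> (overlaps_exon, overlaps_intron)


def _overlaps_any(span: Interval, intervals: Sequence[Interval]) -> bool:
    s, e = span
    return any(s < ie and is_ < e for is_, ie in intervals)


def classify_locus(
    locus: CandidateLocus,
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation | None = None,
) -> RegionClass:
    """Classify the amplified span as exonic, intronic, or both.

    The class is computed on the anchor (species A) gene model; evidence
    from the second genome, when available, is recorded in ``basis`` for
    transparency but does not change the class.
    """
    gene_a_id, gene_b_id = locus.gene_pair
    if gene_a_id not in annotation_a:
        raise ValidationError(f"locus {locus.locus_id}: gene {gene_a_id} not annotated")
    gene_a = annotation_a.gene(gene_a_id)
    span_a = locus.amplified_span_A()
    if span_a[1] > gene_a.length:
        raise ValidationError(f"locus {locus.locus_id}: span outside gene {gene_a_id}")
    ex_a = _overlaps_any(span_a, gene_a.local_exons())
    in_a = _overlaps_any(span_a, gene_a.local_introns())
    basis = {"A": (ex_a, in_a)}
    if annotation_b is not None and gene_b_id in annotation_b:
        gene_b = annotation_b.gene(gene_b_id)
        span_b = locus.amplified_span_B()
        basis["B"] = (
            _overlaps_any(span_b, gene_b.local_exons()),
            _overlaps_any(span_b, gene_b.local_introns()),
        )
    if ex_a and not in_a:
        cls = "exon"
    elif in_a and not ex_a:
        cls = "intron"
    else:
        cls = "both"
    return RegionClass(locus_id=locus.locus_id, region_class=cls, basis=basis)


CLASS_ORDER = ("exon", "intron", "both")


def select_candidates(
    chromosomes: Mapping[str, str],
    identities: Mapping[str, float | None],
    classes: Mapping[str, str],
    band: tuple[float, float] = (0.75, 0.90),
    per_chromosome: int = 2,
) -> list[str]:
    """Apply the three selection criteria and return chosen locus ids.

    ``chromosomes``, ``identities`` and ``classes`` map locus id to the
    anchor chromosome, IR identity and region class.  Loci with identity
    inside the (inclusive) band qualify; within each chromosome at most
    ``per_chromosome`` are chosen, cycling over the region classes in the
    order exon, intron, both (ties inside a class broken by locus id) so
    the picks balance exonic and intronic targets.  Deterministic.
    """
    lo, hi = band
    qualifying = [
        lid
        for lid in sorted(chromosomes)
        if identities.get(lid) is not None and lo <= identities[lid] <= hi
    ]
    by_chrom: dict[str, dict[str, list[str]]] = {}
    for lid in qualifying:
        queues = by_chrom.setdefault(chromosomes[lid], {c: [] for c in CLASS_ORDER})
        queues.setdefault(classes[lid], []).append(lid)

    selected: list[str] = []
    for chrom in sorted(by_chrom):
        queues = by_chrom[chrom]
        for cls in CLASS_ORDER:
            queues[cls] = sorted(queues.get(cls, []))
        taken = 0
        while taken < per_chromosome and any(queues[c] for c in CLASS_ORDER):
            for cls in CLASS_ORDER:
                if taken >= per_chromosome:
                    break
                if queues[cls]:
                    selected.append(queues[cls].pop(0))
                    taken += 1
    return sorted(selected)


def identity_histogram(
    identities: Sequence[float], bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of identities over [0, 1] in half-open bins (last closed).

    Returns ``(edges, counts)``; counts sum to the number of records.
    """
    if not len(identities):
        raise ValidationError("no identity records to bin")
    nbins = round(1.0 / bin_width)
    counts, edges = np.histogram(
        np.asarray(identities, dtype=float), bins=nbins, range=(0.0, 1.0)
    )
    return edges, counts
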