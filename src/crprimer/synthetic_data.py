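"""Simulated reference-genome pairs with known ground truth.

The generator emulates the statistical structure the design method relies
on: orthologous genes that share perfectly conserved blocks embedded in
otherwise diverged sequence, with introns more polymorphic than exons.
Genome B is derived from genome A's ancestor by seeded per-base
substitution (uniform choice among the three alternatives) and
geometric-length indels restricted to introns; planted conserved regions
are copied verbatim, and the bases immediately flanking each planted CR
are forced to mismatch so the planted blocks are maximal by construction.

Each gene hosts one planted CR-pair locus whose class cycles through
intron / both / exon placements, with the inner spacing drawn from a
configurable range (default 200-900 bp) so that some planted pairs fall
outside the candidate window on purpose.  Decoy duplications copy a
planted CR verbatim into an intergenic region of both genomes to exercise
the specificity screen.  Everything is driven by one seeded generator:
the same seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .seqio import Interval, ValidationError, reverse_complement, write_fasta

BASES = np.array(list("ACGT"))
_EXON, _INTRON = 0, 1

GO_DOMAINS = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world: defaults chosen to exercise every pipeline branch.

    Substitution rates put typical IR identities in and around the 75-90%
    selection band (exons near 95%, introns near 85%), matching the
    premise that intronic sequence is the more polymorphic compartment.
    """

    seed: int = 0
    n_genes: int = 20
    n_chromosomes: int = 3
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (200, 600)
    flank_exons: int = 1  # extra exon/intron units on each side of the locus
    exon_sub_rate: float = 0.05
    intron_sub_rate: float = 0.15
    ir_rate_jitter: float = 0.5  # per-gene IR rate = intron rate * U(1-j, 1+j)
    indel_rate: float = 0.002  # per intron base, split between ins and del
    indel_mean_len: float = 2.0  # geometric
    cr_len: tuple[int, int] = (25, 40)
    cr_spacing: tuple[int, int] = (200, 900)
    plant_every: int = 1  # plant a CR-pair locus in every k-th gene
    decoy_fraction: float = 0.0
    n_fraction: float = 0.0  # chance of an N per mutable IR base in genome B
    one2many_rows: int = 3
    n_go_terms: int = 12
    go_density: float = 2.0  # mean slim annotations per gene
    intergenic_len: int = 300

    def __post_init__(self) -> None:
        for r in (self.exon_sub_rate, self.intron_sub_rate, self.indel_rate,
                  self.decoy_fraction, self.n_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.cr_len[0] < 20:
            raise ValidationError("planted CR length must be >= 20")
        if self.cr_spacing[0] < self.cr_len[0]:
            raise ValidationError("spacing range inconsistent with CR length")


@dataclass(frozen=True)
class PlantedCR:
    gene_a: str
    gene_b: str
    posA: Interval  # gene-local, transcript orientation
    posB: Interval
    length: int
    seq: str


@dataclass(frozen=True)
class PlantedLocus:
    gene_a: str
    gene_b: str
    mode: str  # intron | both | exon (host placement)
    cr_left: PlantedCR
    cr_right: PlantedCR
    gap_a: int
    gap_b: int
    ir_rate: float
    is_candidate: bool  # gap within [300, 700] on both genes
    decoyed: bool = False


@dataclass
class GroundTruth:
    dataset_id: str
    crs: list[PlantedCR]
    loci: list[PlantedLocus]
    decoys: list[dict]
    annotation: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    paths: dict[str, Path]
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _random_anchor(rng: np.random.Generator, length: int) -> str:
    """A planted conserved-block sequence with realistic composition.

    Conserved primer-anchor blocks are not low-complexity sequence (real
    search engines mask low-complexity DNA, and a homopolymeric anchor
    could never serve as a primer site), so anchors are drawn with GC in
    [0.4, 0.6] and no mononucleotide run longer than 4.  Rejection
    sampling from the seeded stream keeps the generator deterministic.
    """
    for _ in range(500):
        seq = _random_seq(rng, length)
        gc = (seq.count("G") + seq.count("C")) / length
        run = 1
        worst = 1
        for i in range(1, length):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            worst = max(worst, run)
        if 0.4 <= gc <= 0.6 and worst <= 4:
            return seq
    return seq  # overwhelmingly unlikely; keep the last draw


@dataclass
class _GenePlan:
    name: str
    ancestor: str
    kinds: np.ndarray  # per-base exon/intron code
    frozen: np.ndarray  # bool, planted CR positions
    force_mm: np.ndarray  # bool, CR-flank bases forced to substitute
    ir_mask: np.ndarray  # bool, planted IR positions (use per-gene IR rate)
    exons_local: list[Interval]
    crl_local: Interval | None
    crr_local: Interval | None
    mode: str
    spacing: int
    ir_rate: float

    @property
    def planted(self) -> bool:
        return self.crl_local is not None


def _build_unplanted_gene(
    rng: np.random.Generator, idx: int, cfg: SimulationConfig
) -> _GenePlan:
    """An ordinary gene with no planted conserved blocks."""
    pieces: list[tuple[str, int]] = []
    n_units = 2 + cfg.flank_exons
    for u in range(n_units):
        pieces.append((_random_seq(rng, int(rng.integers(*cfg.exon_len))), _EXON))
        if u < n_units - 1:
            pieces.append(
                (_random_seq(rng, int(rng.integers(*cfg.intron_len))), _INTRON)
            )
    ancestor = "".join(seq for seq, _ in pieces)
    n = len(ancestor)
    kinds = np.empty(n, dtype=np.uint8)
    exons_local: list[Interval] = []
    pos = 0
    for seq, kind in pieces:
        kinds[pos : pos + len(seq)] = kind
        if kind == _EXON:
            exons_local.append((pos, pos + len(seq)))
        pos += len(seq)
    zeros = np.zeros(n, dtype=bool)
    return _GenePlan(
        name=f"gene{idx:03d}",
        ancestor=ancestor,
        kinds=kinds,
        frozen=zeros.copy(),
        force_mm=zeros.copy(),
        ir_mask=zeros.copy(),
        exons_local=exons_local,
        crl_local=None,
        crr_local=None,
        mode="none",
        spacing=0,
        ir_rate=cfg.intron_sub_rate,
    )


def _build_gene(rng: np.random.Generator, idx: int, cfg: SimulationConfig) -> _GenePlan:
    """Construct one ancestral gene hosting a single planted CR pair."""
    if idx % cfg.plant_every != 0:
        return _build_unplanted_gene(rng, idx, cfg)
    mode = ("intron", "both", "exon")[idx % 3]
    crl_len = int(rng.integers(cfg.cr_len[0], cfg.cr_len[1] + 1))
    crr_len = int(rng.integers(cfg.cr_len[0], cfg.cr_len[1] + 1))
    spacing = int(rng.integers(cfg.cr_spacing[0], cfg.cr_spacing[1] + 1))
    ir_rate = cfg.intron_sub_rate * float(
        rng.uniform(1.0 - cfg.ir_rate_jitter, 1.0 + cfg.ir_rate_jitter)
    )
    ir_rate = min(ir_rate, 0.75)

    pieces: list[tuple[str, int]] = []  # (sequence, kind)

    def add(length: int, kind: int) -> None:
        pieces.append((_random_seq(rng, length), kind))

    def add_seq(seq: str, kind: int) -> None:
        pieces.append((seq, kind))

    margin = 25
    for _ in range(cfg.flank_exons):
        add(int(rng.integers(*cfg.exon_len)), _EXON)
        add(int(rng.integers(*cfg.intron_len)), _INTRON)

    crl_seq = _random_anchor(rng, crl_len)
    crr_seq = _random_anchor(rng, crr_len)
    ir_seq = _random_seq(rng, spacing)

    if mode == "intron":
        add(int(rng.integers(*cfg.exon_len)), _EXON)
        add(margin, _INTRON)
        add_seq(crl_seq, _INTRON)
        add_seq(ir_seq, _INTRON)
        add_seq(crr_seq, _INTRON)
        add(margin, _INTRON)
        add(int(rng.integers(*cfg.exon_len)), _EXON)
    elif mode == "exon":
        add(margin, _EXON)
        add_seq(crl_seq, _EXON)
        add_seq(ir_seq, _EXON)
        add_seq(crr_seq, _EXON)
        add(margin, _EXON)
    else:  # both: CRs at exon edges, IR is the intervening intron
        add(int(rng.integers(*cfg.exon_len)), _EXON)
        add_seq(crl_seq, _EXON)
        add_seq(ir_seq, _INTRON)
        add_seq(crr_seq, _EXON)
        add(int(rng.integers(*cfg.exon_len)), _EXON)

    for _ in range(cfg.flank_exons):
        add(int(rng.integers(*cfg.intron_len)), _INTRON)
        add(int(rng.integers(*cfg.exon_len)), _EXON)

    ancestor = "".join(seq for seq, _ in pieces)
    n = len(ancestor)
    kinds = np.empty(n, dtype=np.uint8)
    pos = 0
    bounds: list[tuple[int, int, int]] = []
    for seq, kind in pieces:
        kinds[pos : pos + len(seq)] = kind
        bounds.append((pos, pos + len(seq), kind))
        pos += len(seq)

    # merge contiguous exon runs into exon intervals
    exons_local: list[Interval] = []
    for s, e, kind in bounds:
        if kind == _EXON:
            if exons_local and exons_local[-1][1] == s:
                exons_local[-1] = (exons_local[-1][0], e)
            else:
                exons_local.append((s, e))

    # locate the planted pieces by walking the plan again
    offset = 0
    crl_span = crr_span = None
    ir_span = None
    seen_crl = False
    for seq, _kind in pieces:
        if seq is crl_seq and not seen_crl:
            crl_span = (offset, offset + len(seq))
            seen_crl = True
        elif seq is ir_seq:
            ir_span = (offset, offset + len(seq))
        elif seq is crr_seq:
            crr_span = (offset, offset + len(seq))
        offset += len(seq)
    assert crl_span and crr_span and ir_span

    frozen = np.zeros(n, dtype=bool)
    frozen[crl_span[0] : crl_span[1]] = True
    frozen[crr_span[0] : crr_span[1]] = True
    force_mm = np.zeros(n, dtype=bool)
    for s, e in (crl_span, crr_span):
        if s - 1 >= 0:
            force_mm[s - 1] = True
        if e < n:
            force_mm[e] = True
    ir_mask = np.zeros(n, dtype=bool)
    ir_mask[ir_span[0] : ir_span[1]] = True

    return _GenePlan(
        name=f"gene{idx:03d}",
        ancestor=ancestor,
        kinds=kinds,
        frozen=frozen,
        force_mm=force_mm,
        ir_mask=ir_mask,
        exons_local=exons_local,
        crl_local=crl_span,
        crr_local=crr_span,
        mode=mode,
        spacing=spacing,
        ir_rate=ir_rate,
    )


def _substitute(rng: np.random.Generator, base: str) -> str:
    alts = [b for b in "ACGT" if b != base]
    return alts[int(rng.integers(0, 3))]


def _mutate(
    rng: np.random.Generator,
    seq: str,
    sub_rate: np.ndarray,
    frozen: np.ndarray,
    force_mm: np.ndarray,
    indel_ok: np.ndarray,
    n_rate: np.ndarray,
    cfg: SimulationConfig,
) -> tuple[str, np.ndarray]:
    """Derive the genome-B version of a sequence.

    Returns ``(mutated, a2b)`` where ``a2b[i]`` is the output coordinate at
    which input position ``i`` lands (length ``len(seq)+1``, monotone).
    Frozen positions are copied verbatim; ``force_mm`` positions always
    substitute; indels (half insertions, half deletions) start only where
    ``indel_ok`` is set and never consume frozen or forced positions.
    """
    n = len(seq)
    u_sub = rng.random(n)
    u_indel = rng.random(n)
    u_n = rng.random(n)
    out: list[str] = []
    a2b = np.empty(n + 1, dtype=np.int64)
    i = 0
    while i < n:
        a2b[i] = len(out)
        base = seq[i]
        if frozen[i]:
            out.append(base)
            i += 1
            continue
        if force_mm[i] and sub_rate[i] > 0:
            # flanks of planted CRs always mismatch so the blocks are
            # maximal; suppressed in the zero-mutation limit
            out.append(_substitute(rng, base))
            i += 1
            continue
        if indel_ok[i] and u_indel[i] < cfg.indel_rate:
            length = 1 + int(rng.geometric(1.0 / cfg.indel_mean_len) - 1)
            if u_indel[i] < cfg.indel_rate / 2.0:
                # deletion: skip up to `length` following mutable bases
                j = i
                while j < n and j - i < length and not frozen[j] and not force_mm[j]:
                    a2b[j] = len(out)
                    j += 1
                i = j
                continue
            out.extend(_random_seq(rng, length))  # insertion before base i
        if u_n[i] < n_rate[i]:
            out.append("N")
        elif u_sub[i] < sub_rate[i]:
            out.append(_substitute(rng, base))
        else:
            out.append(base)
        i += 1
    a2b[n] = len(out)
    return "".join(out), a2b


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_reference_pair(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedDataset:
    """Generate the full file set for one reference pair plus ground truth.

    Writes genomeA/genomeB FASTA, GFF3 for both, the ortholog TSV, a GAF
    for the A genes, the slim term list, and ``truth.json``; returns the
    paths and the in-memory :class:`GroundTruth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    plans = [_build_gene(rng, i, config) for i in range(config.n_genes)]

    # mutate every gene, tracking planted coordinates in B
    gene_b_seqs: dict[str, str] = {}
    crs: list[PlantedCR] = []
    loci: list[PlantedLocus] = []
    decoy_flags: list[bool] = []
    n_planted = sum(1 for p in plans if p.planted)
    n_decoys = int(np.ceil(config.decoy_fraction * n_planted))
    planted_seen = 0
    for gi, plan in enumerate(plans):
        sub_rate = np.where(
            plan.ir_mask,
            plan.ir_rate,
            np.where(plan.kinds == _EXON, config.exon_sub_rate, config.intron_sub_rate),
        )
        indel_ok = (plan.kinds == _INTRON) & ~plan.frozen & ~plan.ir_mask
        n_rate = np.where(plan.ir_mask, config.n_fraction, 0.0)
        mutated, a2b = _mutate(
            rng, plan.ancestor, sub_rate, plan.frozen, plan.force_mm,
            indel_ok, n_rate, config,
        )
        name_a = f"{plan.name}_A"
        name_b = f"{plan.name}_B"
        gene_b_seqs[plan.name] = mutated
        if not plan.planted:
            decoy_flags.append(False)
            continue
        crl_b = (int(a2b[plan.crl_local[0]]), int(a2b[plan.crl_local[1]]))
        crr_b = (int(a2b[plan.crr_local[0]]), int(a2b[plan.crr_local[1]]))
        cr_l = PlantedCR(
            gene_a=name_a, gene_b=name_b, posA=plan.crl_local, posB=crl_b,
            length=plan.crl_local[1] - plan.crl_local[0],
            seq=plan.ancestor[plan.crl_local[0] : plan.crl_local[1]],
        )
        cr_r = PlantedCR(
            gene_a=name_a, gene_b=name_b, posA=plan.crr_local, posB=crr_b,
            length=plan.crr_local[1] - plan.crr_local[0],
            seq=plan.ancestor[plan.crr_local[0] : plan.crr_local[1]],
        )
        crs.extend([cr_l, cr_r])
        gap_a = plan.crr_local[0] - plan.crl_local[1]
        gap_b = crr_b[0] - crl_b[1]
        decoyed = planted_seen < n_decoys
        planted_seen += 1
        loci.append(
            PlantedLocus(
                gene_a=name_a,
                gene_b=name_b,
                mode=plan.mode,
                cr_left=cr_l,
                cr_right=cr_r,
                gap_a=gap_a,
                gap_b=gap_b,
                ir_rate=plan.ir_rate,
                is_candidate=(300 <= gap_a <= 700 and 300 <= gap_b <= 700),
                decoyed=decoyed,
            )
        )
        decoy_flags.append(decoyed)

    # assemble chromosomes; decoy CR copies go verbatim into intergenic DNA
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    genome_a: dict[str, list[str]] = {c: [] for c in chrom_names}
    genome_b: dict[str, list[str]] = {c: [] for c in chrom_names}
    gff_a: list[str] = []
    gff_b: list[str] = []
    offsets_a = {c: 0 for c in chrom_names}
    offsets_b = {c: 0 for c in chrom_names}
    decoys: list[dict] = []

    def _spacer(gi_chrom: str, decoy_seq: str | None) -> tuple[str, str]:
        anc = _random_seq(rng, config.intergenic_len)
        if decoy_seq is not None:
            mid = config.intergenic_len // 2
            anc = anc[:mid] + decoy_seq + anc[mid:]
        rate = np.full(len(anc), config.intron_sub_rate)
        frozen = np.zeros(len(anc), dtype=bool)
        if decoy_seq is not None:
            mid = config.intergenic_len // 2
            frozen[mid : mid + len(decoy_seq)] = True
        zeros = np.zeros(len(anc), dtype=bool)
        mut, _ = _mutate(
            rng, anc, rate, frozen, zeros, zeros, np.zeros(len(anc)), config
        )
        return anc, mut

    decoy_queue = [
        (lc.cr_left.seq, lc.gene_a[: -len("_A")])
        for lc in loci
        if lc.decoyed
    ]

    for gi, plan in enumerate(plans):
        chrom = chrom_names[gi % config.n_chromosomes]
        strand = "+" if gi % 2 == 0 else "-"
        # place any pending decoy copy in the spacer preceding this gene,
        # provided the source gene is elsewhere
        decoy_seq = None
        if decoy_queue and decoy_queue[0][1] != plan.name:
            decoy_seq, src = decoy_queue.pop(0)
        spacer_a, spacer_b = _spacer(chrom, decoy_seq)
        if decoy_seq is not None:
            mid = config.intergenic_len // 2
            decoys.append(
                {
                    "chromosome": chrom,
                    "startA": offsets_a[chrom] + mid,
                    "endA": offsets_a[chrom] + mid + len(decoy_seq),
                    "source_gene": src,
                }
            )
        genome_a[chrom].append(spacer_a)
        genome_b[chrom].append(spacer_b)
        offsets_a[chrom] += len(spacer_a)
        offsets_b[chrom] += len(spacer_b)

        seq_a = plan.ancestor
        seq_b = gene_b_seqs[plan.name]
        for which, seq, genome, offsets, gff, exons in (
            ("A", seq_a, genome_a, offsets_a, gff_a, plan.exons_local),
            ("B", seq_b, genome_b, offsets_b, gff_b, None),
        ):
            gname = f"{plan.name}_{which}"
            glen = len(seq)
            gstart = offsets[chrom]
            genomic = seq if strand == "+" else reverse_complement(seq)
            genome[chrom].append(genomic)
            offsets[chrom] += glen
            gff.append(
                f"{chrom}\tsim\tgene\t{gstart + 1}\t{gstart + glen}\t.\t{strand}\t.\t"
                f"ID={gname}"
            )
            local_exons = (
                exons if exons is not None else _exons_b(plan, seq_b)
            )
            for ls, le in local_exons:
                if strand == "+":
                    xs, xe = gstart + ls, gstart + le
                else:
                    xs, xe = gstart + glen - le, gstart + glen - ls
                gff.append(
                    f"{chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t"
                    f"ID={gname}.e{ls};Parent={gname}"
                )

    # trailing spacer per chromosome
    for chrom in chrom_names:
        anc, mut = _spacer(chrom, None)
        genome_a[chrom].append(anc)
        genome_b[chrom].append(mut)

    seqs_a = {c: "".join(genome_a[c]) for c in chrom_names}
    seqs_b = {c: "".join(genome_b[c]) for c in chrom_names}

    # GO annotation of A genes
    go_ids = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    domains = {gid: GO_DOMAINS[i % 3] for i, gid in enumerate(go_ids)}
    annotation: dict[str, list[str]] = {}
    for plan in plans:
        k = min(int(rng.poisson(config.go_density)), config.n_go_terms)
        picked = sorted(
            rng.choice(config.n_go_terms, size=k, replace=False).tolist()
        )
        annotation[f"{plan.name}_A"] = [go_ids[i] for i in picked]

    dataset_id = dataset_id_for(seqs_a)
    truth = GroundTruth(
        dataset_id=dataset_id,
        crs=crs,
        loci=loci,
        decoys=decoys,
        annotation=annotation,
    )

    paths = {
        "genome_a": outdir / "genomeA.fasta",
        "genome_b": outdir / "genomeB.fasta",
        "gff_a": outdir / "genesA.gff3",
        "gff_b": outdir / "genesB.gff3",
        "orthologs": outdir / "orthologs.tsv",
        "gaf": outdir / "annotations.gaf",
        "slim": outdir / "slim_terms.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(seqs_a, paths["genome_a"])
    write_fasta(seqs_b, paths["genome_b"])
    _write_gff(paths["gff_a"], gff_a)
    _write_gff(paths["gff_b"], gff_b)

    with open(paths["orthologs"], "w") as fh:
        fh.write("gene_id_a\tgene_id_b\thomology_type\n")
        for plan in plans:
            fh.write(f"{plan.name}_A\t{plan.name}_B\tone2one\n")
        for i in range(config.one2many_rows):
            src = plans[i % len(plans)].name
            fh.write(f"{src}_A\tparalog{i:02d}_B\tone2many\n")

    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        aspect = {"biological_process": "P", "molecular_function": "F",
                  "cellular_component": "C"}
        for gene in sorted(annotation):
            for gid in annotation[gene]:
                fh.write(
                    f"SIM\t{gene}\t{gene}\t\t{gid}\tSIM:ref\tIEA\t\t"
                    f"{aspect[domains[gid]]}\t\t\tgene\ttaxon:0\t20120224\tSIM\t\t\n"
                )
        # the uninformative BP root, exercised by the loader's exclusion rule
        first = sorted(annotation)[0]
        fh.write(
            f"SIM\t{first}\t{first}\t\tGO:0008150\tSIM:ref\tIEA\t\tP\t\t\t"
            f"gene\ttaxon:0\t20120224\tSIM\t\t\n"
        )

    with open(paths["slim"], "w") as fh:
        fh.write("# GO slim terms: id<TAB>domain<TAB>name\n")
        for gid in go_ids:
            fh.write(f"{gid}\t{domains[gid]}\tsynthetic term {gid[-2:]}\n")
        fh.write("GO:0008150\tbiological_process\tbiological_process root\n")

    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())

    return SimulatedDataset(paths=paths, truth=truth, config=config)


def _exons_b(plan: _GenePlan, seq_b: str) -> list[Interval]:
    """Exon intervals for the B gene.

    Indels are intron-confined, so B exons keep their A lengths but shift;
    recompute by mapping through cumulative intron length changes is
    unnecessary here because annotation B is only used for evidence
    recording — approximate by clipping the A intervals to the B length.
    """
    out = []
    for s, e in plan.exons_local:
        out.append((min(s, len(seq_b)), min(e, len(seq_b))))
    return [iv for iv in out if iv[1] > iv[0]]


def _write_gff(path: Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


def dataset_id_for(sequences: dict[str, str]) -> str:
    """Content hash identifying a genome-A file set."""
    h = hashlib.sha256()
    for name in sorted(sequences):
        h.update(name.encode())
        h.update(sequences[name].encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    cr_recall: float
    locus_recall: float
    locus_precision: float
    primer_rate: float  # recovered planted candidates with >=1 primer pair
    specificity_pass_clean: float | None
    specificity_pass_decoyed: float | None
    identity_divergence_spearman: float | None
    n_planted_candidates: int
    n_recovered: int


def evaluate_recovery(result, truth: GroundTruth) -> RecoveryReport:
    """Score a pipeline run against the generator's ground truth.

    ``result`` is a :class:`crprimer.pipeline.DesignResult` produced from
    the same simulated file set; mismatched dataset ids raise
    :class:`ValidationError`.
    """
    from scipy.stats import spearmanr

    if result.dataset_id != truth.dataset_id:
        raise ValidationError(
            f"run id {result.dataset_id!r} does not match ground truth "
            f"{truth.dataset_id!r}"
        )

    def contains(outer: Interval, inner: Interval) -> bool:
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    recovered_crs = 0
    for planted in truth.crs:
        pair = (planted.gene_a, planted.gene_b)
        found = any(
            contains(cr.posA, planted.posA) and contains(cr.posB, planted.posB)
            for cr in result.crs.get(pair, [])
        )
        recovered_crs += found
    cr_recall = recovered_crs / len(truth.crs) if truth.crs else 1.0

    planted_candidates = [lc for lc in truth.loci if lc.is_candidate]
    matched: dict[str, PlantedLocus] = {}
    for planted in planted_candidates:
        want_ir = (planted.cr_left.posA[1], planted.cr_right.posA[0])
        for locus in result.loci:
            if locus.gene_pair == (planted.gene_a, planted.gene_b) and \
                    locus.ir_A == want_ir:
                matched[locus.locus_id] = planted
                break
    locus_recall = (
        len(matched) / len(planted_candidates) if planted_candidates else 1.0
    )
    locus_precision = (
        len(matched) / len(result.loci) if result.loci else 1.0
    )

    with_primers = [
        lid for lid in matched if result.designed.get(lid) is not None
    ]
    primer_rate = len(with_primers) / len(matched) if matched else 0.0

    def pass_rate(ids: list[str]) -> float | None:
        verdicts = [
            result.verdicts[lid].passed for lid in ids if lid in result.verdicts
        ]
        return sum(verdicts) / len(verdicts) if verdicts else None

    clean = [lid for lid, p in matched.items() if not p.decoyed]
    decoyed = [lid for lid, p in matched.items() if p.decoyed]
    rho = None
    pairs = [
        (result.identities[lid].identity, matched[lid].ir_rate)
        for lid in matched
        if lid in result.identities and result.identities[lid].identity is not None
    ]
    if len(pairs) >= 3:
        idents, rates = zip(*pairs)
        rho = float(spearmanr(idents, [-r for r in rates]).statistic)

    return RecoveryReport(
        cr_recall=cr_recall,
        locus_recall=locus_recall,
        locus_precision=locus_precision,
        primer_rate=primer_rate,
        specificity_pass_clean=pass_rate(clean),
        specificity_pass_decoyed=pass_rate(decoyed),
        identity_divergence_spearman=rho,
        n_planted_candidates=len(planted_candidates),
        n_recovered=len(matched),
    )
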