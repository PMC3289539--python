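"""End-to-end orchestration of the primer-design pipeline.

Stage order: ortholog filtering -> conserved-region detection -> candidate
locus enumeration -> primer picking on the dummy template -> genome-wide
specificity screening -> IR alignment and identity -> exon/intron
classification -> candidate selection -> (optionally) GO enrichment of the
genes contributing selected primer pairs.

Every run writes a manifest (config hash, seed, package version, content
id of genome A) plus TSV/BED outputs; identical inputs and configuration
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .conserved_regions import (
    CandidateLocus,
    ConservedRegion,
    enumerate_candidate_loci,
    filter_orthologs,
    find_conserved_regions,
)
from .go_enrichment import EnrichmentInput, EnrichmentResult, enrich
from .interval_analysis import (
    AlignScoring,
    IdentityRecord,
    RegionClass,
    classify_locus,
    global_align,
    identity_after_n_removal,
    identity_histogram,
    select_candidates,
)
from .primer_engine import (
    DUMMY_SEQUENCE,
    PrimerConstraints,
    PrimerPair,
    build_template,
    pick_primer_pairs,
)
from .seqio import (
    GenomeAnnotation,
    ValidationError,
    read_fasta,
    read_gaf,
    read_gff3,
    read_ortholog_table,
    read_slim_terms,
    write_bed,
    write_primer_table,
)
from .specificity import (
    GenomeIndex,
    PrimerSelfSites,
    SearchScoring,
    SpecificityVerdict,
    screen_primer_pair,
)
from .synthetic_data import dataset_id_for


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    genome_a: Path
    genome_b: Path
    gff_a: Path
    gff_b: Path
    orthologs: Path
    outdir: Path
    gaf: Path | None = None
    slim: Path | None = None
    min_cr_len: int = 20
    interval: tuple[int, int] = (300, 700)
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    scoring: SearchScoring = field(default_factory=SearchScoring)
    evalue_threshold: float = 0.1
    align_scoring: AlignScoring = field(default_factory=AlignScoring)
    band: tuple[float, float] = (0.75, 0.90)
    per_chromosome: int = 2
    go_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_a", "genome_b", "gff_a", "gff_b", "orthologs",
                     "outdir", "gaf", "slim"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.min_cr_len <= 0 or self.evalue_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.interval[0] > self.interval[1]:
            raise ValidationError("interval min must not exceed max")
        if not (0.0 <= self.band[0] <= self.band[1] <= 1.0):
            raise ValidationError("identity band must lie within [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("interval", "band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "constraints" in raw:
            raw["constraints"] = PrimerConstraints(**raw["constraints"])
        if "scoring" in raw:
            raw["scoring"] = SearchScoring(**raw["scoring"])
        if "align_scoring" in raw:
            raw["align_scoring"] = AlignScoring(**raw["align_scoring"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclass
class DesignResult:
    """Everything a design run produced, keyed by locus id."""

    dataset_id: str
    ortholog_pairs: list[tuple[str, str]]
    crs: dict[tuple[str, str], list[ConservedRegion]]
    loci: list[CandidateLocus]
    designed: dict[str, PrimerPair | None]
    verdicts: dict[str, SpecificityVerdict]
    identities: dict[str, IdentityRecord]
    classes: dict[str, RegionClass]
    chromosomes: dict[str, str]
    selected: list[str]
    stage_counts: dict[str, int]
    rejections: list[tuple[str, str]]

    def locus(self, locus_id: str) -> CandidateLocus:
        return next(lc for lc in self.loci if lc.locus_id == locus_id)


REJECTION_REASONS = (
    "no-primer", "specificity-fail", "identity-undefined", "band-fail",
    "chromosome-quota",
)


def run_design(config: RunConfig) -> DesignResult:
    """Execute the design stages end to end and write all reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome_a = read_fasta(config.genome_a)
    genome_b = read_fasta(config.genome_b)
    ann_a = read_gff3(config.gff_a, genome_a)
    ann_b = read_gff3(config.gff_b, genome_b)
    table = read_ortholog_table(config.orthologs)
    pairs = [
        (a, b) for a, b in filter_orthologs(table) if a in ann_a and b in ann_b
    ]

    crs: dict[tuple[str, str], list[ConservedRegion]] = {}
    loci: list[CandidateLocus] = []
    for a, b in pairs:
        found = find_conserved_regions(
            ann_a.gene(a).unspliced_sequence,
            ann_b.gene(b).unspliced_sequence,
            min_cr_len=config.min_cr_len,
            gene_pair=(a, b),
        )
        crs[(a, b)] = found
        loci.extend(enumerate_candidate_loci(found, interval=config.interval))

    rejections: list[tuple[str, str]] = []
    candidates: dict[str, list[PrimerPair]] = {}
    for locus in loci:
        picked = pick_primer_pairs(build_template(locus), config.constraints)
        candidates[locus.locus_id] = picked
        if not picked:
            rejections.append((locus.locus_id, "no-primer"))

    # screen the ranked candidate pairs in order and report the first that
    # is genome-wide specific; if every candidate has an off-site the locus
    # fails with the best pair's verdict
    index_a = GenomeIndex(genome_a, config.scoring.word_size)
    index_b = GenomeIndex(genome_b, config.scoring.word_size)
    designed: dict[str, PrimerPair | None] = {}
    verdicts: dict[str, SpecificityVerdict] = {}
    for locus in loci:
        picked = candidates[locus.locus_id]
        if not picked:
            designed[locus.locus_id] = None
            continue
        chosen, chosen_verdict = picked[0], None
        for pair in picked:
            sites = {
                "A": _self_sites(locus, pair, ann_a, which="A"),
                "B": _self_sites(locus, pair, ann_b, which="B"),
            }
            verdict = screen_primer_pair(
                pair.forward,
                pair.reverse,
                {"A": index_a, "B": index_b},
                sites,
                evalue_threshold=config.evalue_threshold,
                scoring=config.scoring,
                primer_pair_id=locus.locus_id,
            )
            if chosen_verdict is None:
                chosen, chosen_verdict = pair, verdict
            if verdict.passed:
                chosen, chosen_verdict = pair, verdict
                break
        designed[locus.locus_id] = chosen
        verdicts[locus.locus_id] = chosen_verdict
        if not chosen_verdict.passed:
            rejections.append((locus.locus_id, "specificity-fail"))

    identities: dict[str, IdentityRecord] = {}
    classes: dict[str, RegionClass] = {}
    chromosomes: dict[str, str] = {}
    for locus in loci:
        if designed[locus.locus_id] is None:
            continue
        a, b = locus.gene_pair
        ir_a = ann_a.gene(a).unspliced_sequence[locus.ir_A[0] : locus.ir_A[1]]
        ir_b = ann_b.gene(b).unspliced_sequence[locus.ir_B[0] : locus.ir_B[1]]
        row_a, row_b, _score = global_align(ir_a, ir_b, config.align_scoring)
        identities[locus.locus_id] = identity_after_n_removal(
            row_a, row_b, locus_id=locus.locus_id
        )
        classes[locus.locus_id] = classify_locus(locus, ann_a, ann_b)
        chromosomes[locus.locus_id] = ann_a.gene(a).chromosome

    screened_pass = [
        lid for lid, v in verdicts.items() if v.passed
    ]
    selectable = {}
    for lid in screened_pass:
        rec = identities[lid]
        if rec.identity is None:
            rejections.append((lid, "identity-undefined"))
            continue
        selectable[lid] = rec.identity
    selected = select_candidates(
        {lid: chromosomes[lid] for lid in selectable},
        selectable,
        {lid: classes[lid].region_class for lid in selectable},
        band=config.band,
        per_chromosome=config.per_chromosome,
    )
    lo, hi = config.band
    for lid in sorted(selectable):
        if lid in selected:
            continue
        if not (lo <= selectable[lid] <= hi):
            rejections.append((lid, "band-fail"))
        else:
            rejections.append((lid, "chromosome-quota"))

    stage_counts = {
        "ortholog_pairs": len(pairs),
        "pairs_with_crs": sum(1 for v in crs.values() if v),
        "candidate_loci": len(loci),
        "designed": sum(1 for p in designed.values() if p is not None),
        "specificity_pass": len(screened_pass),
        "band_qualified": sum(1 for v in selectable.values() if lo <= v <= hi),
        "selected": len(selected),
    }

    result = DesignResult(
        dataset_id=dataset_id_for(genome_a),
        ortholog_pairs=pairs,
        crs=crs,
        loci=loci,
        designed=designed,
        verdicts=verdicts,
        identities=identities,
        classes=classes,
        chromosomes=chromosomes,
        selected=selected,
        stage_counts=stage_counts,
        rejections=sorted(rejections),
    )
    _write_outputs(config, result, ann_a)
    return result


def _self_sites(
    locus: CandidateLocus,
    pair: PrimerPair,
    annotation: GenomeAnnotation,
    which: str,
) -> PrimerSelfSites:
    """Project the primer binding sites onto one genome via the gene model."""
    gene_id = locus.gene_pair[0] if which == "A" else locus.gene_pair[1]
    gene = annotation.gene(gene_id)
    cr_l = locus.cr_left.posA if which == "A" else locus.cr_left.posB
    cr_r = locus.cr_right.posA if which == "A" else locus.cr_right.posB
    f_off = pair.forward_span  # template coords; left CR starts at 0
    fwd_local = (cr_l[0] + f_off[0], cr_l[0] + f_off[1])
    left_len = locus.cr_left.length
    dummy = len(DUMMY_SEQUENCE)
    r_start_in_cr = pair.reverse_span[0] - (left_len + dummy)
    r_end_in_cr = pair.reverse_span[1] - (left_len + dummy)
    rev_local = (cr_r[0] + r_start_in_cr, cr_r[0] + r_end_in_cr)
    chrom_f, fs, fe = gene.project(fwd_local)
    chrom_r, rs, re_ = gene.project(rev_local)
    return PrimerSelfSites(forward=(chrom_f, fs, fe), reverse=(chrom_r, rs, re_))


def run_enrich(
    config: RunConfig, result: DesignResult, reps: int | None = None
) -> list[EnrichmentResult]:
    """GO enrichment of genes contributing at least one selected primer pair."""
    if config.gaf is None or config.slim is None:
        raise ValidationError("enrichment requires gaf and slim paths")
    domains = read_slim_terms(config.slim)
    annotation = read_gaf(config.gaf, set(domains))
    population = frozenset(g for g, terms in annotation.items() if terms)
    study_genes = frozenset(
        result.locus(lid).gene_pair[0] for lid in result.selected
    ) & population
    if not study_genes:
        raise ValidationError(
            "no selected locus maps to an annotated gene; run design first "
            "or supply annotations covering the selected genes"
        )
    inputs = EnrichmentInput(
        population=population,
        study=study_genes,
        annotation={
            g: frozenset(t) for g, t in annotation.items() if g in population
        },
        domains=domains,
    )
    results = enrich(
        inputs, reps=reps if reps is not None else config.go_reps,
        seed=config.seed,
    )
    _write_enrichment(Path(config.outdir) / "enrichment.tsv", results)
    return results


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def _write_outputs(
    config: RunConfig, result: DesignResult, ann_a: GenomeAnnotation
) -> None:
    outdir = Path(config.outdir)

    rows = []
    bed_rows = []
    for locus in result.loci:
        lid = locus.locus_id
        pair = result.designed[lid]
        if pair is None:
            continue
        a, b = locus.gene_pair
        gene = ann_a.gene(a)
        ident = result.identities[lid].identity
        rows.append(
            {
                "locus_id": lid,
                "gene_id_a": a,
                "gene_id_b": b,
                "chromosome": gene.chromosome,
                "forward": pair.forward,
                "reverse": pair.reverse,
                "tm_forward": round(pair.tm_f, 2),
                "tm_reverse": round(pair.tm_r, 2),
                "gc_forward": round(pair.gc_f, 1),
                "gc_reverse": round(pair.gc_r, 1),
                "product_min": pair.product_range[0],
                "product_max": pair.product_range[1],
                "ir_identity": "NA" if ident is None else round(ident, 4),
                "region_class": result.classes[lid].region_class,
                "specificity_pass": result.verdicts[lid].passed,
                "selected": lid in result.selected,
            }
        )
        chrom, s, e = gene.project(locus.ir_A)
        bed_rows.append((chrom, s, e, lid, 0.0, gene.strand))

    rows.sort(key=lambda r: str(r["locus_id"]))
    bed_rows.sort()
    write_primer_table(rows, outdir / "primer_table.tsv")
    write_bed(bed_rows, outdir / "irs.bed")

    with open(outdir / "crs.tsv", "w") as fh:
        fh.write("gene_id_a\tgene_id_b\tstartA\tendA\tstartB\tendB\tlength\n")
        for pair_key in sorted(result.crs):
            for cr in result.crs[pair_key]:
                fh.write(
                    f"{cr.gene_pair[0]}\t{cr.gene_pair[1]}\t{cr.posA[0]}\t"
                    f"{cr.posA[1]}\t{cr.posB[0]}\t{cr.posB[1]}\t{cr.length}\n"
                )

    with open(outdir / "identities.tsv", "w") as fh:
        fh.write(
            "locus_id\tcolumns_total\tcolumns_removed_N\tmatches\tidentity\n"
        )
        for lid in sorted(result.identities):
            rec = result.identities[lid]
            ident = "NA" if rec.identity is None else f"{rec.identity:.6f}"
            fh.write(
                f"{lid}\t{rec.columns_total}\t{rec.columns_removed_N}\t"
                f"{rec.matches}\t{ident}\n"
            )

    defined = [
        rec.identity for rec in result.identities.values()
        if rec.identity is not None
    ]
    if defined:
        edges, counts = identity_histogram(defined)
        with open(outdir / "identity_histogram.tsv", "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for i, c in enumerate(counts):
                fh.write(f"{edges[i]:.2f}\t{edges[i + 1]:.2f}\t{int(c)}\n")

    with open(outdir / "selection.tsv", "w") as fh:
        fh.write("locus_id\tselected\n")
        for lid in sorted(result.identities):
            fh.write(f"{lid}\t{'true' if lid in result.selected else 'false'}\n")

    with open(outdir / "rejections.tsv", "w") as fh:
        fh.write("locus_id\treason\n")
        for lid, reason in result.rejections:
            fh.write(f"{lid}\t{reason}\n")

    manifest = {
        "package_version": __version__,
        "dataset_id": result.dataset_id,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stage_counts": result.stage_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_enrichment(path: Path, results: list[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "domain\tgo_id\tterm\tobs\tmean\tsd\tz\tp\tp_adj\tdirection\t"
            "significant\n"
        )
        for r in results:
            z = "NA" if r.z is None else f"{r.z:.2f}"
            fh.write(
                f"{r.domain}\t{r.go_id}\t{r.term}\t{r.obs}\t{r.mean:.2f}\t"
                f"{r.sd:.2f}\t{z}\t{r.p:.6g}\t{r.p_adj:.6g}\t{r.direction}\t"
                f"{'true' if r.significant else 'false'}\n"
            )
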