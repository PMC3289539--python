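"""Reading and writing the external file formats.

All internal coordinates are 0-based half-open intervals ``(start, end)``.
GFF3 (1-based inclusive) and BED (0-based half-open) are converted at the
boundary.  Gene sequences are handled in transcript (strand) orientation;
genome-coordinate outputs are always plus-strand.

Sequences are restricted to the alphabet ``{A, C, G, T, N}``; ``U`` is
normalised to ``T`` on load and other ambiguity codes are rejected, because
downstream conserved-region detection requires exact-identity semantics in
which only ``N`` has a defined (never-matching) meaning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_GO_ID_RE = re.compile(r"^GO:\d{7}$")

Interval = tuple[int, int]


class FormatError(ValueError):
    """A malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a semantic contract."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene: genomic span plus exon structure and its unspliced sequence.

    ``span`` and ``exons`` are plus-strand genomic intervals (0-based
    half-open); ``unspliced_sequence`` is strand-oriented 5'->3', so for a
    minus-strand gene it is the reverse complement of the plus-strand slice.
    """

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    span: Interval
    exons: tuple[Interval, ...]  # genomic coords, sorted by start, non-overlapping
    unspliced_sequence: str

    def __post_init__(self) -> None:
        s, e = self.span
        if len(self.unspliced_sequence) != e - s:
            raise ValidationError(
                f"gene {self.gene_id}: unspliced sequence length "
                f"{len(self.unspliced_sequence)} != span length {e - s}"
            )
        for xs, xe in self.exons:
            if xs < s or xe > e:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{xs},{xe}) outside span [{s},{e})"
                )

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def local_exons(self) -> list[Interval]:
        """Exon intervals in unspliced-gene (transcript-oriented) coordinates."""
        s, e = self.span
        if self.strand == "+":
            out = [(xs - s, xe - s) for xs, xe in self.exons]
        else:
            out = [(e - xe, e - xs) for xs, xe in self.exons]
        return sorted(out)

    def local_introns(self) -> list[Interval]:
        """Non-exonic intervals of the gene in transcript coordinates."""
        introns: list[Interval] = []
        pos = 0
        for xs, xe in self.local_exons():
            if xs > pos:
                introns.append((pos, xs))
            pos = xe
        if pos < self.length:
            introns.append((pos, self.length))
        return introns

    def project(self, local: Interval) -> tuple[str, int, int]:
        """Map a transcript-coordinate interval onto the plus-strand genome.

        Returns ``(chromosome, start, end)`` with 0-based half-open coords.
        """
        s, e = self.span
        ls, le = local
        if not (0 <= ls <= le <= self.length):
            raise ValidationError(
                f"gene {self.gene_id}: local interval [{ls},{le}) outside gene"
            )
        if self.strand == "+":
            return self.chromosome, s + ls, s + le
        return self.chromosome, e - le, e - ls


@dataclass
class GenomeAnnotation:
    """A genome with its gene models; the unit a pipeline run works on."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.sequences:
                raise ValidationError(
                    f"gene {g.gene_id}: unknown chromosome {g.chromosome!r}"
                )
            if g.span[1] > len(self.sequences[g.chromosome]):
                raise ValidationError(
                    f"gene {g.gene_id}: span {g.span} exceeds chromosome length "
                    f"{len(self.sequences[g.chromosome])}"
                )
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id


@dataclass
class OrthologTable:
    """Rows of (gene_id_A, gene_id_B, homology_type)."""

    rows: list[tuple[str, str, str]]

    HOMOLOGY_TYPES = frozenset({"one2one", "one2many", "many2many"})


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``.

    Sequences are upper-cased and U is normalised to T.  Record ids are the
    first whitespace-delimited token of the header.  Characters outside
    ``{A,C,G,T,N,U}`` raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    # validation pass (line-numbered diagnostics); parsing delegated to Bio.SeqIO
    with open(path) as fh:
        seen_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            else:
                if not seen_header:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any header"
                    )
                bad = set(line.upper().replace("U", "T")) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC/unsupported characters "
                        f"{sorted(bad)}"
                    )
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path, genome: Mapping[str, str]) -> GenomeAnnotation:
    """Read gene and exon features from a GFF3 file against loaded sequences.

    Input coordinates are 1-based inclusive and converted to 0-based
    half-open.  Minus-strand genes get reverse-complemented unspliced
    sequences.  Exons are attached to their parent gene via the ``Parent``
    attribute; an exon outside its parent span raises
    :class:`ValidationError`.
    """
    path = Path(path)
    genes_raw: dict[str, dict] = {}
    exons_raw: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "exon"):
                continue
            try:
                iv = (int(start) - 1, int(end))  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr_map.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                genes_raw[gid] = {
                    "chromosome": seqid,
                    "strand": strand,
                    "span": iv,
                }
            else:
                parent = attr_map.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon feature without Parent")
                exons_raw.setdefault(parent, []).append(iv)

    genes: list[GeneModel] = []
    for gid, info in genes_raw.items():
        span = info["span"]
        chrom = info["chromosome"]
        if chrom not in genome:
            raise ValidationError(f"gene {gid}: chromosome {chrom!r} not in genome")
        exons = tuple(sorted(exons_raw.get(gid, [])))
        for xs, xe in exons:
            if xs < span[0] or xe > span[1]:
                raise ValidationError(
                    f"gene {gid}: exon [{xs},{xe}) outside gene span "
                    f"[{span[0]},{span[1]})"
                )
        plus_slice = genome[chrom][span[0] : span[1]]
        seq = plus_slice if info["strand"] == "+" else reverse_complement(plus_slice)
        genes.append(
            GeneModel(
                gene_id=gid,
                chromosome=chrom,
                strand=info["strand"],
                span=span,
                exons=exons,
                unspliced_sequence=seq,
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return GenomeAnnotation(sequences=dict(genome), genes=genes)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """TSV of ``gene_id_A<TAB>gene_id_B<TAB>homology_type`` (header optional)."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            a, b, ht = parts[0], parts[1], parts[2]
            if lineno == 1 and ht not in OrthologTable.HOMOLOGY_TYPES:
                continue  # header row
            if ht not in OrthologTable.HOMOLOGY_TYPES:
                raise FormatError(
                    f"{path}:{lineno}: unknown homology type {ht!r}"
                )
            rows.append((a, b, ht))
    return OrthologTable(rows=rows)


def read_slim_terms(path: str | Path) -> dict[str, str]:
    """Read a GO-slim term list: ``GO_id<TAB>domain`` per line.

    Domains partition the slim into biological_process / molecular_function /
    cellular_component.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected GO id and domain")
            go_id, domain = parts[0], parts[1]
            if not _GO_ID_RE.match(go_id):
                raise FormatError(f"{path}:{lineno}: bad GO id {go_id!r}")
            out[go_id] = domain
    return out


#: the root biological-process term carries no information and is dropped
EXCLUDED_GO_IDS = frozenset({"GO:0008150"})


def read_gaf(path: str | Path, slim_terms: Iterable[str]) -> dict[str, set[str]]:
    """Read GAF 2.x annotations restricted to a slim term set.

    Returns ``{gene_id: {GO ids}}``.  GO:0008150 (the uninformative
    biological-process root) is always removed.  Rows with malformed GO ids
    are skipped with a warning.
    """
    slim = set(slim_terms) - EXCLUDED_GO_IDS
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                logger.warning("%s:%d: short GAF row skipped", path, lineno)
                continue
            gene_id, go_id = parts[1], parts[4]
            if not _GO_ID_RE.match(go_id):
                logger.warning(
                    "%s:%d: unrecognised GO id %r, row skipped", path, lineno, go_id
                )
                continue
            out.setdefault(gene_id, set())
            if go_id in slim:
                out[gene_id].add(go_id)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

PRIMER_TABLE_COLUMNS = [
    "locus_id",
    "gene_id_a",
    "gene_id_b",
    "chromosome",
    "forward",
    "reverse",
    "tm_forward",
    "tm_reverse",
    "gc_forward",
    "gc_reverse",
    "product_min",
    "product_max",
    "ir_identity",
    "region_class",
    "specificity_pass",
    "selected",
]


def write_primer_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write the per-primer-pair TSV (one row per designed pair).

    ``rows`` are mappings keyed by :data:`PRIMER_TABLE_COLUMNS`; missing keys
    are written as empty fields.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_fmt(row.get(c, "")) for c in PRIMER_TABLE_COLUMNS) + "\n"
            )


def write_bed(rows: Sequence[tuple[str, int, int, str, float, str]],
              path: str | Path) -> None:
    """Write BED6 records ``(chrom, start, end, name, score, strand)``."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{_fmt(score)}\t{strand}\n")


def _fmt(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
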