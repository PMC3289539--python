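# crprimer

Comparative-genomics design of PCR primer pairs that amplify putatively
polymorphic loci in **non-sequenced** species, using two fully-sequenced
reference genomes.

## The problem

Population-genetic studies of species without a reference genome need many
independent nuclear sequence markers. `crprimer` finds them by comparison of
two sequenced relatives of the target species: wherever an orthologous gene
pair shares two **conserved regions** (CRs — perfectly identical blocks of
≥ 20 bp) flanking a 300–700 bp **interval region** (IR), primers placed
inside the CRs are likely to anneal in the target species too, while the
intervening IR — divergent between the references — is likely to be
polymorphic within the target. Moderately conserved IRs (75–90 % identity
between the references) are the sweet spot: conserved enough to amplify,
divergent enough to segregate.

## Method

Per one-to-one orthologous gene pair (one-to-many/many-to-many pairs are
discarded to avoid co-amplifying paralogs):

1. **CR detection** — all maximal exact matches ≥ 20 bp between the two
   unspliced gene sequences (k-mer seeding + bidirectional extension; `N`
   never matches).
2. **Locus enumeration** — all CR pairs with inner gap in [300, 700] bp on
   *both* genes.
3. **Primer picking** — the IR is replaced by a fixed 108-bp dummy,
   `NNNN(AATT)₂₅NNNN`, so primers can only be picked inside the CRs.
   Constraints follow primer3 practice: length 18–27 (opt 20), Tm 57–63 °C
   (opt 60, nearest-neighbor model with unified parameters and
   divalent-corrected salt), GC 20–80 %, ΔTm ≤ 3 °C, homopolymer ≤ 4,
   self/pair complementarity limits. Pairs are ranked by a weighted
   deviation penalty.
4. **Specificity screen** — each primer is searched against both whole
   genomes (ungapped seed-and-extend, word size 11, +1/−2) and every hit
   with Karlin–Altschul expectation `E = K·m·n·e^(−λS) < 0.1` must coincide
   with the design site; otherwise the next-ranked pair is tried, and the
   locus fails if none is specific.
5. **IR identity** — the two reference IRs are globally aligned
   (Needleman–Wunsch, +5/−4, gap −10/−0.5) and identity is computed after
   removing every column containing `N`; gap columns stay in the
   denominator.
6. **Classification & selection** — each amplified span is exonic, intronic
   or both, per the anchor annotation; final candidates have identity in
   [0.75, 0.90], at most 2 per chromosome, balanced across the three
   classes.
7. **GO enrichment** — genes contributing selected primer pairs are tested
   per GO-slim term with an exact hypergeometric tail (over- or
   under-representation), a resampled null mean/SD and Z score, and
   per-domain Bonferroni correction.

A seeded synthetic-data module generates complete reference pairs (FASTA,
GFF3, ortholog TSV, GAF, slim list) with known planted ground truth, so the
whole pipeline is testable offline.

## Worked example

```sh
crprimer simulate --out demo/sim --seed 11 --n-genes 8
crprimer design \
    --genome-a demo/sim/genomeA.fasta --genome-b demo/sim/genomeB.fasta \
    --gff-a demo/sim/genesA.gff3     --gff-b demo/sim/genesB.gff3 \
    --orthologs demo/sim/orthologs.tsv --outdir demo/run --seed 11
```

prints the per-stage funnel:

```
ortholog_pairs      8
pairs_with_crs      8
candidate_loci      597
designed            456
specificity_pass    418
band_qualified      326
selected            6
```

Eight orthologous gene pairs yield 597 CR-pair loci (most share anchors and
overlap); 456 admit a constraint-satisfying primer pair, 418 of those are
genome-wide specific, 326 fall in the 75–90 % identity band, and the
chromosome quota with class balancing keeps 6. The first rows of
`demo/run/primer_table.tsv`:

```
locus_id      forward               reverse               tm_f   tm_r   product  ir_identity  class  specific  selected
gene000_A:0   TTGTCAGCGTCTACTAGCGT  TGCGGGATAGAGCGTAGTGA  58.84  60.46  487-487  0.8665       both   true      true
gene000_A:1   TTGTCAGCGTCTACTAGCGT  ACAGGTATAGGATTGAGTCGGG 58.84 58.77  519-519  0.8742       both   false     false
```

Locus `gene000_A:0` is a selected marker: its primers melt within 1.6 °C of
each other, the predicted product is 487 bp in both references, and the IR
is 86.65 % identical between them — inside the band where cross-species
amplification and target-species polymorphism are both plausible. The run
directory also contains `irs.bed` (IR coordinates on genome A), `crs.tsv`,
`identities.tsv`, an identity histogram, per-locus rejection reasons, and a
reproducibility manifest; adding `--gaf/--slim` and using `crprimer enrich`
appends the GO enrichment table.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded synthetic reference
pair — 20 genes, 10 planted designable CR-pair loci with 300–700 bp
spacings, one decoy duplication — then runs design and GO enrichment and
reports the stage funnel, planted-locus recall, primer feasibility and
decoy rejection on stderr, writing the result JSON to `--out`.

See `docs/methods.md` for model assumptions, parameter rationale, and
limitations.
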