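# Methods

This note records the models behind `crprimer`, the defaults and why they
are what they are, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want spelled out.

## Conserved-region model

A conserved region (CR) is a *maximal* perfectly identical block of at
least `min_cr_len = 20` bases between the unspliced sequences of a
one-to-one orthologous gene pair. Identity is literal string equality over
`{A,C,G,T}`; `N` matches nothing, including another `N`, so CRs are N-free
by construction (a primer cannot contain `N`, and "perfect identity" has no
meaning for an unknown base). Detection seeds on exact k-mers with
k = `min_cr_len` and extends bidirectionally to maximality; because the
criterion is exact identity, this provably enumerates the same block set as
any word-based heuristic search, deterministically, which is why no
external search engine is needed at this stage. Repeated placements of the
same subsequence are all reported — uniqueness is the specificity screen's
job, not the detector's.

Candidate loci pair two CRs whose *inner* gap lies in [300, 700] bp,
inclusive, **on both genes**. The bounds are closed because the target
range is stated as a closed interval of expected PCR product sizes. The
both-genes rule reflects that the interval-region identity downstream is
only meaningful when the interval exists at comparable scale in both
references; enforcing it on one genome only would admit loci whose second
IR is wildly expanded or collapsed.

## Primer picking

The interval region is unknown in the target species, so it must never
contribute primer sequence. Before picking, the IR is replaced by the fixed
108-bp dummy `NNNN(AATT)₂₅NNNN`: the terminal Ns make any primer leaking
out of a CR detectable (primers with N are rejected), and the AT-only body
is unpickable under the Tm/GC constraints. A side effect, intended, is that
the apparent product size is decoupled from the real one; predicted product
sizes are reported separately as IR length plus the primer-to-inner-edge
offsets, per reference genome.

Melting temperatures use the unified nearest-neighbor parameter set
(Allawi & SantaLucia 1997 / SantaLucia 1998) with the entropic salt
correction ΔS += 0.368·(L−1)·ln[Na⁺]. Solution conditions default to
standard PCR practice as assumed by primer3's defaults: 50 mM monovalent
cation, 1.5 mM Mg²⁺, 0.6 mM dNTP (divalents enter via the von
Ahsen/Owczarzy conversion, effective monovalent = mono + 120·√(Mg−dNTP) ≈
164 mM) and 50 nM total oligo (C_T/4 in the Tm denominator). The divalent
term matters: under bare 50 mM Na⁺ the conventional 57–63 °C window sits
~4 °C above what typical 18–27-mers reach, and whole anchor blocks become
unpickable — the window and the solution conditions are a package deal.
The implementation is cross-checked in the tests against an independent
nearest-neighbor calculator (Biopython `Tm_NN`) under identical conditions,
to within 1 °C (observed agreement: ~1e-13 °C).

Hard constraints (all config-exposed, defaults in `PrimerConstraints`):
length 18–27 opt 20; Tm 57–63 opt 60; GC 20–80 %; pair ΔTm ≤ 3 °C;
mononucleotide run ≤ 4; self/pair complementarity limited by the longest
contiguous complementary stretch in any antiparallel register (≤ 8
anywhere, ≤ 3 touching a 3' end) — a deterministic simplification of
alignment-based complementarity scoring. The penalty is a weighted sum of
deviations from the optima (defaults: weight 1 per base of length and per
°C of Tm; GC and ΔTm weights 0, mirroring common primer3 weighting). Pair
search runs best-first over the two penalty-sorted candidate lists; since
the pair penalty is bounded below by the sum of single-primer penalties,
the search is exact for the returned ranking and stops early. Ties break
deterministically by (penalty, forward start, forward length, reverse
start, reverse length).

## Specificity screen

Each primer is searched against both whole genomes with an ungapped
seed-and-extend local search: word size 11, match +1 / mismatch −2, X-drop
20. Gaps are irrelevant at ≤ 27-mer query scale. Hits get expectation
values E = K·m·n·e^(−λS), with m the query length and n the length of both
strands of the searched genome. λ and K are computed numerically at first
use for whatever scoring scheme is configured: λ as the positive root of
Σ pₛe^(λs) = 1 and K by the lattice-case constant
K = δ·e^(−2σ) / (E[X e^(λX)]·(1−e^(−λδ))), σ the partial-sum series of the
score walk and its λ-tilted twin. For +1/−2 this reproduces the published
ungapped constants (λ = 1.33, K = 0.621), which the tests pin.

A pair passes only if, in *both* genomes, every hit with E < 0.1 overlaps
the genomic projection of the primer's own design site by ≥ 1 bp. Overlap
is tested regardless of hit strand, because a local hit and its
reverse-orientation twin describe the same physical duplex site. The
pipeline screens the ranked candidate pairs of a locus in order and reports
the first specific one; if all fail, the locus is rejected with the best
pair's offending hits. Note a scale effect: on desk-scale synthetic genomes
(~10⁵ bp) E < 0.1 is reached by chance exact repeats of only ~13 bp, so a
small fraction of loci can fail legitimately on random repeats — on
gigabase genomes the same threshold corresponds to much stronger homology.

## Interval identity and selection

Reference IRs are aligned with global Needleman–Wunsch (match +5, mismatch
−4, gap −10 for the first position, −0.5 per extension; end gaps penalized;
the two-sequence special case of progressive multiple alignment). Identity
removes every column containing `N` in either row, then counts identical
residue columns over the remaining columns; **gap columns stay in the
denominator** — the most conservative reading of "percent identity". If
every column is removed the identity is undefined and flagged, never
reported as 0 or 1.

Classification is computed on the anchor (genome A) gene model over the
amplified span (outer CR edge to outer CR edge): exon-only, intron-only, or
both; second-genome evidence is recorded but does not change the class,
matching the convention of reporting one class per pair. Selection keeps
loci with identity in [0.75, 0.90] (closed band), at most `per_chromosome
= 2` per anchor chromosome, chosen round-robin over the classes in the
fixed order exon → intron → both with ties broken by locus id — a
deterministic rendering of "spread over the genome, spread over identity,
mix exonic and intronic targets".

## GO enrichment

Population = genes with ≥ 1 slim GO id (the uninformative
biological-process root GO:0008150 is always excluded); study = genes
contributing ≥ 1 selected primer pair. Per term, the p-value is the exact
hypergeometric tail — upper when obs ≥ n·K/N (over-representation), lower
otherwise (under-representation) — summed in exact integer arithmetic.
Because classical reports also print a resampled expectation, each term
additionally gets the mean and SD (ddof = 1) of its count over seeded
draws of study-sized gene sets without replacement (default 10,000 reps)
and Z = (obs − mean)/SD, flagged undefined when SD = 0. Bonferroni
multiplicity is the number of tested terms in the same GO domain, since
results are reported per domain. Two one-sided tests rather than one
two-sided test: under-represented terms are reportable findings in their
own right.

## Synthetic data: what it emulates, what it does not

The generator builds an ancestral genome A (genes with exon/intron
structure on several chromosomes, intergenic spacers) and derives genome B
by seeded per-base substitution — uniform choice among the three
alternative bases — at compartment-specific rates (defaults: exons 5 %,
introns and intergenic 15 %; per-locus IR rates jittered ±50 % around the
intron rate so identity varies across loci), plus geometric-length indels
(rate 0.002/base, mean 2 bp) confined to introns, reflecting that
structural mutations are rare in exons. Planted CR pairs are copied
verbatim into both genomes with the flanking base forced to mismatch, so
the planted blocks are maximal at exactly their recorded coordinates (the
forcing is suppressed in the zero-mutation limit, where the genomes are
asserted identical). Planted loci cycle intron/both/exon host placements;
inner spacings are drawn from [200, 900] bp by default so that some planted
pairs deliberately miss the 300–700 window. Decoy duplications copy a
planted anchor verbatim into intergenic sequence of both genomes to
exercise the E < 0.1 uniqueness filter.

Planted anchor sequences are drawn with bounded composition — GC in
[0.4, 0.6] and no homopolymer longer than 4 — because real conserved
anchor blocks are not low-complexity DNA (search engines mask
low-complexity sequence, and a poly-A block could never host a primer);
uniform-random anchors of ≤ 45 bp otherwise have an appreciable chance of
admitting no primer under any Tm parameterisation, which would make
"planted designable locus" a misnomer. Default planted anchor lengths are
25–40 bp, which intentionally leaves some loci primer-less and exercises
the `no-primer` rejection path; recovery fixtures that presume all planted
loci are designable use 45–60 bp anchors.

What a green test does **not** establish: the generator has no coalescent
or codon structure, no rate heterogeneity beyond the exon/intron split, no
rearrangements, no paralogy beyond the explicit decoys, and genome sizes
are ~10⁵ bp rather than 10⁹ — so specificity behaviour at realistic
database sizes, and enrichment behaviour under realistic GO term
correlation, are modelled only in their mechanics, not their magnitudes.
Wet-lab outcomes (amplification success, sequence readability, observed
polymorphism) are outside the computational scope entirely.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; GFF3 and BED conversions
  happen at the I/O boundary; gene-local coordinates are transcript-
  oriented, genomic outputs always plus-strand.
- Ambiguity codes other than `N` are rejected on load; `U` → `T`.
- Alignment tie-breaking follows the DP traceback's canonical order and is
  deterministic for fixed inputs; only scores, never specific tracebacks,
  are contractual.
- Identity of an all-N alignment is `None` (flagged), never a number.
- `resample_null` requires ≥ 100 reps; SD uses ddof = 1; identical seeds
  give bit-identical results.
- Every pipeline run writes a manifest (config hash, seed, package
  version, genome-A content hash); identical inputs and config produce
  byte-identical outputs.

## Known limitations

- The self/pair complementarity check is a contiguous-run simplification;
  it is stricter in some registers and laxer in others than
  alignment-scored complementarity.
- The seed-and-extend search can miss hits whose best segment contains no
  exact 11-word; for E < 0.1 at primer scale such hits are impossible on
  realistic genomes but the guarantee degrades for very small word sizes
  or unusual scoring schemes.
- Exon coordinates of the derived (B) genome annotation are approximated
  by clipping when intron indels shift boundaries; B-side exon evidence is
  advisory only and never drives classification.
- Bonferroni across domains, resampling reps, and all thresholds are
  config-exposed; changing the search scoring recomputes λ and K but the
  word-size guarantee above should be rechecked.
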