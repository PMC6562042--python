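# Methods

`synmic` re-implements, as a tested pipeline over synthetic cohorts, the
analysis stack used to characterize and prioritize somatic synonymous
mutations in pan-cancer catalogs: curation of COSMIC-style mutation tables,
per-mutation annotation, a nine-parameter composite prioritization score,
positional-depletion statistics, expected-vs-observed amino-acid analysis,
exonic splicing-motif gain/loss scanning, and ranking analyses over ingested
RNA-structure aberration scores.

## Curation model

A raw catalog row is one (variant, sample, transcript) observation. Three
systematic defects are corrected:

* **Consequence re-derivation.** Every single-nucleotide variant's
  consequence is recomputed from the transcript sequence: the reference
  codon and the mutated codon are translated under the transcript's genetic
  code and compared. Synonymous = same amino acid; nonsense = sense→stop;
  stop-loss and all non-SNVs are labeled `other` and excluded from
  synonymous/missense analyses. Records whose stated reference allele does
  not match the transcript sequence are quarantined to a reject table with a
  reason, never silently dropped.
* **Genetic-code correction.** Mitochondrial transcripts are translated
  under the vertebrate mitochondrial code (NCBI table 2: TGA=Trp, ATA=Met,
  AGA/AGG=stop), which reclassifies variants mis-annotated under the
  standard code.
* **Deduplication.** The same variant in the same sample mapped to several
  transcripts of a gene is collapsed to one row. The retained mapping is the
  *canonical transcript*: longest CDS, ties broken lexicographically by
  transcript id. This retention rule is a design choice — any deterministic
  rule preserves the (variant, sample) identity set, which is what the
  downstream statistics use.

Coordinates: CDS positions are 1-based (HGVS `c.`), transcript offsets
0-based, genomic intervals 0-based half-open (BED). Alleles are stored on
the coding strand; genomic-strand alleles of minus-strand transcripts are
reverse-complemented on ingest. All converters live on `TranscriptModel`.

## Annotation

* **Recurrence.** `frequency` counts *distinct samples* carrying the
  identical genomic variant across all tumor entities (not rows, not
  per-transcript); `recurrent` ⇔ frequency > 1.
* **Signature normalization.** The six strand-symmetric substitution
  classes (C>A, C>G, C>T, T>A, T>C, T>G; a change and its reverse complement
  share a class) carry probabilities `p` from a `SignatureModel`. The
  signature-normalized frequency is `frequency × (1 − p)`, discounting
  changes that are common under the mutational process. A context-resolved
  96-channel signature is collapsed by summing channels within each class.
* **Mutation load.** Per-sample load is the sample's total curated mutation
  count over *all* consequence classes (the cohorts emulated are
  genome-wide, so totals are comparable); a variant's `avg_mutation_load`
  averages over its carriers.
* **Positional features.** CDS decile = ⌈10·pos/L⌉ clamped to [1, 10]
  (boundary positions fall in the lower bin, so pos = L is decile 10);
  codon index = ⌈pos/3⌉; a first-200-codon bin (20 codons per bin) is
  emitted only for CDS > 600 nt. Exon context is strand-aware in
  transcription order (on a minus-strand transcript the genomically leftmost
  exon is the *last* exon); internal-exon deciles run 5'→3' in transcript
  orientation; boundary distance is the distance to the nearer end of the
  containing exon.
* **External joins.** Variant-level tables (SNPs, FATHMM-MKL, CADD,
  ClinVar) join on (chrom, pos, ref, alt) — position *and* nucleotide change
  must match; conservation joins per locus; cancer genes per symbol.
  Missing joins produce nulls or false flags, never row loss; duplicate keys
  in a reference table are an error naming the key. ClinVar phenotypes
  containing "cancer" or "tumor" (case-insensitive substring) are flagged
  cancer-related.

## The composite score

    S = (log2 f + 1)(1 − p) − log10 L + g + c + s + m + qC + qR

f = frequency (≥1), p = signature class probability, L = average carrier
load (≥1), g ∈ {0, 2} cancer-gene term, c ∈ [0, 1] conservation,
s ∈ {0, 1} SNP term (1 when the variant is *not* a known SNP — novelty is
evidence of somatic specificity), m ∈ [0, 1] FATHMM-MKL, and qC, qR the
cohort-wide quantile ranks of the CADD and structure-impact scores.

Choices that were genuinely open:

* The published formula's parenthesization is ambiguous (unbalanced); the
  reading above — multiplicative bias-corrected frequency term, subtractive
  load term, additive bounded terms — matches the stated term order and the
  bracketed ranges of the additive parameters.
* The cancer-gene term is binary {0, 2} (the range notation would also
  admit a tiered mapping; the mapping value is a parameter of
  `score_table`).
* Quantile ranks use rank_i = #{values ≤ value_i}/n with ties averaged, so
  the maximum ranks 1.0; the identical convention serves CADD and the
  structure score.
* Missing c, m, qC, qR impute to 0 — no evidence contributes nothing — and
  imputations are flagged per row.

The leave-one-out analysis removes one of nine parameters at a time
(frequency removes the whole multiplicative term, signature replaces
(1 − p) by 1, load drops −log10 L, additive terms drop), and
`top_decile_retention` measures how much of the full-score top 10% each
reduced ranking retains. Empirical percentile thresholds (top 50/10/1/0.1/
0.01%) are cohort quantiles; absolute threshold values are cohort-specific
by construction and no attempt is made to reproduce any particular cohort's
thresholds.

## Splicing-motif scanning

Catalogs of ESE/ESS motifs (possibly degenerate IUPAC, U→T on ingest) are
merged on sequence with annotations concatenated; a sequence listed under
both roles is flagged `both`. For each mutation a ±100 nt transcript window
(truncated at transcript boundaries) is scanned against every motif in both
the wildtype and the mutated sequence. Occurrences are counted at *every*
offset (overlapping matches allowed) and only occurrences fully contained in
the window count — a motif straddling a truncated window edge is not
counted, a stated choice for short transcripts. The per-motif delta is
mutant − wildtype; scanning is antisymmetric by construction and any nonzero
delta must overlap the mutated base. Scanning is on the coding/pre-mRNA
sense strand only, where ESE/ESS function is defined.

## Structure-score ranking

RNA folding is out of process. The module exports per-mutation ±200 nt
windows (FASTA headers `>mutation_id|offset|ref>alt`), flags truncated
windows so length-sensitive analyses can drop them, and ingests remuRNA-like
(relative entropy, MFE, GC) and RNAsnp-like (d_max, GC/length-normalized
p-value, interval) tables under a strict column contract with key-integrity
checks. Analyses: Spearman correlations between metrics over
pairwise-complete rows; per-CDS-decile fractions of the global top 5th
percentile (top set = round(0.05·n) highest scores with deterministic
tie-break, so bin-weighted fractions conserve the percentile exactly up to
integer rounding); per-decile window GC/MFE means with SEM; and structure
score by mutation-load bins with Welch t-tests between adjacent bins.
Context length (100/200 nt) is carried in every row and never mixed.

## Cohort statistics

Positional distributions report per-bin counts and fractions, optionally
stratified (substitution class, study). Amino-acid analysis divides raw
per-amino-acid counts by codon multiplicity and renormalizes; the expected
distribution enumerates, for every sense codon, its nine single-base
substitutions, sums the signature probabilities of the synonymous ones,
weights by codon usage (computed from the supplied transcriptome's CDS set,
keeping the pipeline closed over its inputs), aggregates to amino acids and
normalizes. Trp and Met have no synonymous single-base route and get
expected share exactly 0. Stop codons are excluded throughout.

Group comparisons use a two-sided two-sample t-test; an F-test of variance
equality at α = 0.05 selects pooled vs Welch. Two zero-variance groups with
equal means return p = 1 by convention. No multiple-testing correction is
applied by default (raw p-values are reported); Benjamini–Hochberg is
available behind a flag. Per-study stratification selects the union of the
five studies with the most synonymous mutations and the five with the most
samples (all studies when fewer than ten exist).

## Synthetic cohorts: what they emulate, and what they do not

`synthetic_data` generates toy transcriptomes (multi-exon, both strands,
UTRs, ATG-initiated stop-terminated CDS without internal stops, one gene per
contig) and COSMIC-like mutation tables with these injectable properties:

* **Signature.** Default six-class probabilities: C>T 0.67 (the dominant
  C>T/G>A share observed pan-cancer), T>C 0.12, C>A 0.06, C>G 0.05,
  T>A 0.05, T>G 0.05. The mass outside C>T is spread with T>C second, as in
  the ubiquitous aging-associated process.
* **Load.** Per-sample totals are log-uniform over (20, 200) by default.
  These are *panel-restricted* burdens: the toy transcriptome stands in for
  a small fraction of the coding genome, so genome-wide burdens are scaled
  down proportionally, keeping the per-site hit rate — and with it the
  recurrence regime — in the range observed pan-cancer (with the default
  recurrence mixture, roughly a quarter of mutations are recurrent).
* **Depletion.** Multiplicative thinning weights for the first CDS decile
  and for the outer deciles of internal exons. Sampling sites proportional
  to weights is equivalent to rejection-thinning uniform positions, so
  closed-form bin expectations are available (weight w on the first decile
  gives expected bin-1 fraction w/(w + 9)).
* **Recurrence.** Site rates are multiplied by (1 + Pareto(α)) with tail
  index α = 1.5 by default — a power-law site-rate mixture giving a
  heavy-tailed recurrence distribution with roughly a quarter of mutations
  recurrent at default sizes. Each site carries one fixed alternate allele,
  so recurrent hits are the identical variant.
* **Sampling detail.** Events realize the joint law "uniform
  depletion-thinned position × signature class" by rejection: a site's
  selection weight includes the signature mass compatible with its reference
  base (C/G sites host the C>* classes). Class frequencies therefore
  converge to the configured signature; positions are uniform in expectation
  over sequence randomness, with a small (≈±0.5% relative) decile wobble
  conditional on the realized base composition. Statistical tests of
  uniformity are sized so sampling noise dominates this wobble.
* **Reference tables.** Conservation, FATHMM-like, CADD-like and structure
  scores are independent uniforms/normals unless the
  `structure_load_correlation` knob couples the structure score to (z-scored
  log) carrier load — score-component independence is itself a testable
  claim, so independence is the default, not an accident.

All randomness flows deterministically from `SyntheticConfig.seed` (each
stage derives its own stream from it), so fixed seeds give byte-identical
FASTA/BED/TSV outputs.

Not emulated: trinucleotide-context (96-channel) signature realism, germline
variation, study-specific calling artifacts, linkage between conservation
and true functional sites, real codon-usage bias, and real RNA-structure
scores (the built-in generator is a null model). Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
injected effects — not biological conclusions about real cohorts.

## Problem sizes and numerical choices

The statistical characterization runs use ~100,000 simulated mutations over
40 genes (closed-form depletion recovery, signature convergence to total
variation < 0.02, top-percentile conservation); unit-level checks use
cohorts of a few hundred to a few thousand rows. Decile boundary positions
go to the lower-indexed bin via the ceil rule. Quantile-rank ties share the
mean positional rank. Top-percentile and top-decile sets resolve score ties
by stable positional order, making retention and conservation quantities
deterministic. Empty strata are omitted with a log entry; bins with fewer
than two values report null SEM and skip tests with a flag.

## Known limitations

* The curation stage trusts the supplied transcript models; it cannot
  detect a wrong transcript sequence that is internally consistent.
* Frequency counts genomic variant identity; paralogous genes sharing
  coordinates would share counts.
* The motif catalogs bundled for the default pipeline are a small built-in
  set of SR-protein/hnRNP-class hexamers for exercising the machinery; real
  analyses should supply curated external catalogs as TSV.
* Structure ingestion trusts the tools' own GC/length normalization of
  p-values and does not re-derive it.
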