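# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices that were genuinely open.

## Input model and coordinates

The pipeline starts from base-modification calls as produced by SMRT
kinetic analysis: one record per called base with read coverage, the
interpulse-duration (IPD) ratio, and optionally `frac`, the estimated
fraction of sequenced molecules methylated at that site (only present when
fraction estimation was requested upstream). Raw kinetics, alignment and
base-calling are out of scope; calls are consumed as input.

External formats (the `modifications.gff` dialect, GFF3) are 1-based
inclusive and `ModificationRecord.position` keeps that convention. Every
computed structure — gene-model intervals, partition arrays, flank
windows, BED export — is 0-based half-open; the single conversion
(`position − 1`) happens where a record meets an array. Records whose
reference base is not adenine on the called strand (possible when calls
and genome come from different assembly versions) are excluded with a
logged count; a `strict` flag escalates to an error.

The coverage filter drops sites with coverage *strictly below* the cutoff
(default 25×; equality retains), matching the convention that sites with
less than N-fold coverage are excluded. The cutoff is global; a
per-chromosome reading of "per chromosome" in the source protocol would be
expressible by filtering per chromosome, but a single global cutoff is
what the filter implements.

## Genome partition

Each position receives exactly one label from {5′UTR, CDS, 3′UTR, intron,
ncRNA, intergenic}. Overlaps are resolved by fixed priority
CDS > 5′UTR > 3′UTR > ncRNA > intron > intergenic — coding function
dominates; the choice is an implementation decision because mutually
exclusive counts can be reported without stating one. Categories are
unstranded; a site's strand never changes its label but is kept for
per-strand densities. Multi-transcript genes collapse to one model: exon
union across transcripts, CDS from the transcript with the longest total
CDS, UTRs explicit when annotated or derived as exonic sequence outside
the CDS extent, introns as span minus exons. Genes without annotated UTRs
contribute only CDS/intron intervals; no UTR is imputed.

An adenine on the minus strand is a T on the forward sequence, so the
per-class adenine count on "−" is the class's forward-strand T count.
Partition exhaustiveness and adenine conservation are structural (a single
code array per chromosome) and asserted by tests.

## Densities and enrichment

Density is the exact ratio of two integers, `n_sites / n_adenines`,
undefined (reported `NA`, never 0/0) when the denominator is zero. Report
tables format the percent scale to three decimals with half-up rounding
(`decimal.Decimal`), which is what reproduces the published strawberry
table's printed column from its printed counts. The strand-specific
density columns of that published table are internally inconsistent with
its strand-labelled count columns (the labels appear swapped in several
rows), so only row totals and the grand total are used as reference
values; the bundled `fvesca_v1_site_counts.tsv` carries the counts.

Enrichment per class compares the observed site count with
`expected = n_A(class) × p̂`, `p̂ = total sites / total adenines`. The
default test is the exact binomial, two-sided by the minimum-likelihood
rule (sum of all outcome probabilities no larger than the observed one);
this is the test behind the headline class-enrichment figure in the kind
of study this package reimplements. A Wilcoxon signed-rank mode across
per-chromosome observed−expected differences is available behind a flag
because protocol texts sometimes name it for the same comparison; with few
chromosomes it has essentially no power, which is the main reason the
binomial is the default. Degenerate inputs (zero rate, zero adenines)
return p = 1 with an undefined ratio rather than erroring.

Methylation levels bin `frac × 100` into low [0, 35), moderate [35, 65),
high [65, 100]. The published bin labels overlap at 35 and 65; left-closed
right-open intervals (closed on the last) make the bins exhaustive,
disjoint and deterministic. Sites without `frac` are counted separately,
never silently dropped.

## Gene classes

Per gene, sites on either strand within the gene span are counted against
adenines on both strands of the span (a flag restricts to the gene's own
strand). `K = log₂(density / mean density)` with the mean taken over
methylated genes only; classes: high (K > 1), low (K < −1), moderate
(|K| ≤ 1), non (zero sites, K undefined). Strict inequalities mean a gene
at exactly 2× the mean (K = 1) is moderate and 4× (K = 2) is high.

## Flanks and the motif scanner

Every site contributes a 9-mer (±4 bp), read 5′→3′ on the methylated
strand: minus-strand windows are reverse-complemented so position 0 is
always the methylated A; chromosome ends pad with N, so the flank count
always equals the site count. Composition is computed over non-N
observations per position.

The motif scanner is a deliberately simple, fully enumerative stand-in for
EM-based motif discovery: it enumerates every exact k-mer (k = 5, 6, 7)
over every placement of a k-window that keeps the methylated A inside the
motif and inside the ±4 bp context (12 placements), counts occurrences in
the foreground and in a background of adenine flanks sampled uniformly
genome-wide excluding called sites (10× the foreground by default; the
sampling seed is recorded in output metadata), and scores each k-mer with
a one-sided Fisher exact test. Within a placement, k-mers identical at
≥ k − 2 positions merge greedily (best p first) into an IUPAC consensus;
a letter enters a consensus column when its count-weighted within-cluster
frequency is ≥ 0.25, and the seed k-mer's letters are always included so
the consensus matches at least one foreground k-mer. E = Fisher p of the
merged counts × the total number of candidates tested (Bonferroni);
candidates are ranked by ascending E. The 0.25 inclusion threshold and
the hamming-2 merge radius are tunable; the defaults let two-letter
degeneracies (R, W, Y…) survive the collapse, which is what published
6mA motifs like RAGGY require. E-values printed by EM-based tools on full
datasets are not comparable to this scanner's E-values and are not used
as reference values.

## TSS profiles

Occupancy windows are half-open [x, x + 50) in transcription-oriented
coordinates with the TSS at the left edge of the first downstream window
(edge conventions are unstated in the source material; this one is
deterministic and symmetric up to the half-open choice). A gene with k ≥ 1
sites in a window contributes exactly 1 to that window's numerator; the
denominator is the full class size, so genes with no sites — or whose
±1 kb window runs off a chromosome — still count. Sites on either strand
count toward a window by default (flag available). The central contrast
(±200 bp, 8 windows) between protein-coding and lncRNA classes is a Welch
t test on per-window occupancies. The relative-position profile uses 50
equal bins over the normalized gene body (`floor(B·offset/length)`,
clamped to the last bin), 5′ end first on either strand.

## Expression association

Genes with FPKM > 0 **and** density > 0 enter the analysis (filter first,
then the mean — matching the order the procedure is usually described in).
High/low groups are strictly above/below the arithmetic mean; exact ties
are excluded. The t test is Welch's by default because the two groups are
typically very unbalanced; a pooled-variance flag exists. A split leaving
a group with a single gene is still reported (the group sizes and means
are meaningful) but its t statistic and p are NaN; an empty group raises.
qPCR relative expression is `2^(−ΔCt)` with ΔCt the difference of
replicate means, and the group test runs on log₂ relative expression by
default for variance stabilization (raw-scale flag available). GO
over-representation is a one-sided Fisher test per (class, term) with
BH adjustment within class, significant at q < 0.01; the default universe
is every gene with at least one GO annotation (an all-genes universe is a
flag).

## The synthetic generator

The generator emulates the *downstream products* of a SMRT 6mA study, not
the platform: i.i.d. genome sequence at GC = 0.42 (the approximate
strawberry genome composition implied by an adenine fraction of ~0.29 per
strand), non-overlapping gene models (default 300 protein-coding + 60
lncRNA on 2 × 500 kb), per-class adenine methylation rates
(CDS 0.003, UTR 0.002, intron 0.0015, ncRNA 0.002, intergenic 0.001 —
intergenic matches the ~0.1% scale of real plant 6mA landscapes and the
CDS:intergenic ratio of 3 plants the coding-sequence enrichment), a
multiplicative TSS factor (default 0.5 within ±200 bp), and a relocation
step that moves a configurable fraction of sites (default 0.5) onto
same-class adenines with GG at +1..+2, preserving per-class counts while
planting the AGG core. `frac` is drawn from a 3-component Beta mixture
with weights (0.2, 0.3, 0.5) peaked low/mid/high, mirroring the
qualitative dominance of high methylated fractions in real data; coverage
is negative-binomial with mean 60 and shape 10 so both the 25× and 15×
cutoffs remove realistic small fractions; expression follows
`log FPKM = 1 + β·z(density) + N(0, 1)` with β = 0.5 and 10% structural
zeros; GO terms are assigned independently of methylation (so GO
enrichment is null by construction). All draws come from one seeded
generator; the same seed yields byte-identical files.

What the generator does **not** emulate: real genome composition beyond GC
(no repeats, no isochores), overlapping or nested genes, alternative
isoform structure, kinetic noise or mapping artefacts, and any dependence
of `frac` or coverage on genomic context. Passing recovery tests
therefore demonstrates that the pipeline's statistics detect the planted
effects at realistic magnitudes and calibrate correctly under the null —
not that they would be unbiased on every property of real data.

Problem sizes: the default bundle is 1 Mb with ~780 sites, which keeps a
full pipeline run under a second; the null-calibration suite runs 100
seeds at that scale, and the expression power checks use the direct
log-linear generator at n = 2,000 genes (building 10 multi-megabase
genomes would add nothing to that check, since the full generator uses the
identical expression model).

## Known limitations

* The Wilcoxon enrichment mode needs many chromosomes to have power; on
  the 2-chromosome default toy genome it is essentially uninformative.
* The motif scanner finds contiguous degenerate motifs only (no gaps, no
  EM refinement); its E-values are Bonferroni-conservative.
* Host-gene assignment for a site picks the highest-priority overlapping
  gene deterministically (span start, then id) when several genes'
  intervals of the same class contain the position.
* TSS distance is reported to the nearest TSS on the chromosome, which in
  dense annotations may not be the site's host gene's TSS.
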