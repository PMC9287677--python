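# Methods

This note documents the statistical procedures, the parameters that
matter, the synthetic-data model that the tests rest on, and the
numerical conventions and limitations of the implementation.

## Coordinates and sequence conventions

All intervals inside the package are 0-based half-open; GTF (1-based
inclusive) and BED (0-based half-open) are converted at the I/O
boundary and nowhere else, so any off-by-one can only live in
`miraxis/io.py`. Sequences are uppercased at load. miRNAs stay in the
RNA alphabet and UTRs in DNA throughout; the RNA→DNA reverse-complement
mapping (A↔T, C↔G, U→A) is applied explicitly in
`seed_enrichment.rna_site_word`, never silently. `N` in a UTR never
matches any word.

## Positional seed-word enrichment

For word length k = 7 and start positions 1–15 (requiring a miRNA of at
least 21 nt), each miRNA word is mapped to its DNA reverse complement
and searched in the 3' UTRs. The scan searches the *complement* because
a miRNA represses through base-pairing; a literal-occurrence mode
(`match_literal=True`) is provided for the alternative reading, but
only complement matching is expected to concentrate signal at the seed
(position 2).

The test statistic is gene-level presence/absence — a gene with three
site copies counts once — because the hypergeometric population/draw
framing is over genes, not occurrences. The p-value is the exact upper
tail `scipy.stats.hypergeom.sf`, not a normal approximation, verified
in the tests against an exact-rational enumeration over every
count-consistent instance with universe ≤ 12. BH adjustment is applied
across the 15 positions of one miRNA's scan (the natural test family);
both raw and adjusted p are reported because either may be the quantity
of interest, with `significant` flagging padj below the 0.01 reporting
threshold. The default query is padj < 0.05 AND log2fc < −0.5
(one-sided toward downregulation, where direct targets appear after
overexpression); the default universe is every DE-table gene with a
UTR. Tables lacking `padj` get BH recomputed from raw p with a logged
notice. Whether a real study's universe was "expressed genes" or "genes
with an annotated UTR" is a choice the caller makes by passing
`universe_genes`.

## CDF shift and target voting

`cdf_shift` is the two-sample two-sided Kolmogorov–Smirnov test,
with the exact small-sample null when min(n, m) ≤ 25 and the asymptotic
distribution otherwise; the D statistic is checked in tests against a
brute-force supremum over the pooled ECDF grid. The test is two-sided
because repression and de-repression are both of interest; direction is
read from `median_shift` = median(query) − median(background).
`vote_score` counts supporting databases per gene (score =
|supporting sources|), sorted score-descending then by gene id.

## Permutation GSEA

Genes are ranked by log2fc (or sign(log2fc)·(−log10 p) via
`metric="signed_logp"`), descending, with ties broken lexicographically
by gene id so the order is total and deterministic. The running sum
increments |score|^weight / Σ_hits |score|^weight at set members and
decrements 1/(N − n_hits) elsewhere; ES is the extremum of largest
magnitude. Weight defaults to 1 (the classic weighted statistic);
weight 0 gives the analytically tractable unweighted case used in
oracle tests. When |max| and |min| of the running sum tie exactly the
earliest extremum in rank order wins — a measure-zero event under
continuous scores whose resolution only matters to reproducibility.

The null is *gene-label* permutation: random same-size gene sets from
the ranking. Phenotype permutation is degenerate in designs with 2–3
samples per arm, which is exactly the regime this pipeline targets.
The p-value conditions on the sign of the observed ES,

    p = (1 + #{|ES'| ≥ |ES|, sign(ES') = sign(ES)}) / (1 + #{sign(ES') = sign(ES)}),

so it is valid (never zero) and one-sided in the direction actually
observed; NES = ES / mean |ES'| over same-sign permutations, reported
as missing when fewer than 10 same-sign permutations exist rather than
as an unstable ratio. With no same-sign permutation at all, p = 1 with
a warning. Permutation ES values are computed from sorted hit positions
only (the extrema can only occur immediately before or after a hit),
which makes 1,000 permutations on a 1,000-gene ranking take
milliseconds; the identity with the full running-sum scan is covered by
tests. Per-set seeds in `gsea_collection` are spawned from one
`SeedSequence` in sorted set-id order, so results are independent of
collection iteration order. BH is applied across the collection's sets.

## Cross-dataset consensus

`harmonize` outer-joins DE tables on miR id and keeps missingness
distinct from non-significance; `n_datasets_measured` is always
reported so the distinction stays auditable. Per dataset the
significance criterion is padj when the table carries one and raw p
otherwise (logged, and recorded in the CLI manifest) — public
case/control miRNA datasets span RNA-seq and microarray platforms with
heterogeneous reporting, and forcing BH onto a table that already has
it, or pretending one exists, would both be wrong. Thresholds default
to padj < 0.05 and |log2fc| > 0.5; retention requires significance in
≥ 3 datasets. "Commonly downregulated across all datasets" is
operationalized strictly: significant AND down in *every dataset in
which the miR was measured*; `require_measured_in_all=True` additionally
demands measurement in all K datasets. Retention is monotone in
`min_datasets` (tested). No effect pooling (Fisher/Stouffer) is done —
this stage is vote counting by design.

`de_contrast` is deliberately minimal plumbing for synthetic counts:
median-of-ratios size factors, log2 of normalized means with a 0.5
pseudocount, Welch t on log2(CPM + pseudocount), BH. Size factors are
computed in the count matrix's own column order so that swapping
condition labels negates every log2fc bit-exactly. Real datasets should
arrive as externally produced DE tables.

## Pri-miRNA inference from intronic reads

For an intronic miRNA the unspliced host-gene transcript is the
pri-miRNA, so intron-contained reads proxy its abundance. Introns are
the host span minus the merged exon union of *all* genes overlapping
that span — subtracting only the host's own exons would count a
neighbour's exonic signal as intronic. A read is counted only if fully
contained in one intronic interval; junction- or exon-overlapping reads
are ambiguous between spliced and unspliced molecules and contribute
nothing. Each read counts at most once per gene.

Fold changes use size factors from *total intronic counts per sample*
(scaled to mean 1), not whole-library totals, so a global change in
exonic amplitude cannot masquerade as a pri-miRNA change. The flip side
is that if every host gene in the set shifted the same way, the shared
component would be absorbed into normalization — the method measures
relative transcriptional change against the bulk of hosts, which is the
standard intronic-normalization trade-off. Genes with fewer than
`min_count=20` total intronic reads across the contrast are flagged
low-coverage and excluded from correlation; intron lengths are not used
for normalization (fold changes of a fixed gene are length-invariant).

Both Spearman's ρ and Pearson's r are reported for the mature-vs-pri
relationship, with n ≥ 3 pairs required. The per-miR classifier, with
lfc threshold t = 0.5 and concordance fraction c = 0.5: if the mature
change |m| ≥ t, the call is *transcriptional* when pri p has the same
sign and |p| ≥ c·|m|, *post_transcriptional* when |p| < c·|m|,
*discordant* when the signs oppose with |p| ≥ t; everything else is
*unchanged*. Every call is re-derivable from the row's two numbers.

## The synthetic-data model

The generators emulate the statistical structure the analyses assume,
not real biology:

- **UTRs**: i.i.d. per-base background at GC 0.45, lengths uniform in
  200–500 nt; target genes (default 30%) carry the exact DNA reverse
  complement of the miRNA seed (positions 2–8) planted at recorded
  non-overlapping offsets. There is no higher-order sequence
  composition, no conservation, no site-context effects — adequate for
  word-count nulls, silent about everything those ignore.
- **Counts**: negative binomial with var = μ + φμ², a single shared
  dispersion (default φ = 0.1; 0.05 for mature-miR counts), baseline
  means log-uniform in 20–2000. Condition-2 means are condition-1 means
  × 2^planted-log2fc. No per-feature dispersion variation.
- **Six-dataset DE**: planted miRs get |log2fc| ~ U(0.8, 2.0) with
  p = 10^−U(5, 9) in exactly their chosen datasets and null behaviour
  (log2fc ~ N(0, 0.1), p ~ U(0, 1)) elsewhere; the generator
  self-checks that the planted design survives BH. The same noise model
  is used for all six synthetic datasets — real microarray noise is not
  separately modelled.
- **De-repression DE**: target log2fcs shifted by a constant against a
  N(0, 0.5) background (0.5 log2 units being a typical fold-change
  spread), p-values from a two-sided z against the background sd.
- **Host-gene experiments**: one multi-exon gene per chromosome (4
  exons of 200–400 nt, introns 1.5–3 kb), intronic and exonic read
  counts Poisson at 500 and 300 reads/gene/sample, reads length 75
  placed uniformly and fully within their compartment, 3 samples per
  arm. The *transcriptional* scenario scales intronic totals and mature
  counts together by 2^pri-log2fc; *processing* scales mature counts
  only. Planting magnitudes −1.32 and −0.51 correspond to 60% and 30%
  reductions of the primary transcript, the regimes of interest. Reads
  are emitted as genomic intervals, not sequences: the counting stage
  needs positions only, so FASTQ/quality simulation is deliberately
  out of scope, as are splice-junction reads beyond exclusion geometry.

Every generator records its planted truth (`SimTruth`) and is
bit-reproducible given a seed; recovery tests consume the recorded
truth only. Passing tests therefore demonstrate correct recovery of
effects *under this model* — exact seed matches, uniform read
placement, independent genes — and not robustness to alignment
artefacts, 3'-UTR annotation error, or correlated expression.

## Problem sizes and tolerances in the test suite

The suite and the acceptance script scale the simulations to what the
statistics need rather than to study size: 200-gene UTR sets × 20
replicates for positional recovery and 200 null scans for family-wise
error (bound 0.07 ≈ 0.05 plus binomial slack); 200 permutation-test
trials for null calibration (acceptance band 0.02–0.09 around the
nominal 0.05); 100 random harmonizations against a set-algebra oracle;
24 host genes × 20 replicates per pri-miRNA regime with the ±0.2
recovery tolerance derived from the Poisson/normalization error budget
at depth 500; 208 miR/host pairs per correlation replicate. The
`de_contrast` power check (±0.3 on a planted −2 at n = 5/arm) runs at
dispersion 0.02 — the deeply sequenced, low-variability regime in which
a mean-based estimate can meet that envelope; at the default φ = 0.1
the fold-change standard error alone is ≈ 0.3. Exact-oracle agreements
(hypergeometric, BH, enrichment score) are asserted at 1e−12.

## Known limitations

- The minimal DE layer has no variance shrinkage and is not a
  replacement for a real DE tool on real data.
- Gene-label permutation treats genes as exchangeable; correlated gene
  sets on real data make these p-values optimistic, as with any
  gene-sampling GSEA null.
- The intronic counter assigns reads by containment only; it does not
  resolve transcript structure, nested genes sharing introns, or novel
  intronic transcription.
- The seed scan knows nothing of site accessibility, 8mer/7mer-A1 site
  taxonomy, or conservation — by design, it reproduces the plain
  positional word statistic.
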