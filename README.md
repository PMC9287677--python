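# miraxis

Analysis pipeline for dissecting a miRNA regulatory axis from
transcriptomic data, built around the kind of question raised by the
loss of an individual neuron-enriched miRNA (such as miR-139-5p in
degenerating motor neurons): is a miRNA reproducibly dysregulated
across independent patient datasets, which genes does it directly
repress, which pathways do those targets converge on, and is its loss
driven by reduced transcription of its primary transcript or by a
downstream processing defect?

The package is aimed at computational biologists working with bulk or
single-cell RNA-seq plus small-RNA-seq who need these five analyses as
tested, reusable components rather than one-off notebook code:

1. **Positional seed-word enrichment** (`miraxis.seed_enrichment`).
   For each 7mer window starting at positions 1–15 of a mature miRNA
   m (5'→3'), count the genes whose 3' UTR contains the DNA reverse
   complement of that word, and test over-representation in a query set
   q (e.g. genes downregulated after miRNA overexpression) drawn from a
   universe of N genes with the exact hypergeometric upper tail

   P(X ≥ k), X ~ Hypergeom(N, K, n) — K genes with the site in the
   universe, n = |q|, k of them in the query —

   with Benjamini–Hochberg adjustment across the 15 positions. Direct
   targeting shows up as a sharp minimum at position 2, the seed.
2. **Target de-repression CDF shift**: a two-sample two-sided
   Kolmogorov–Smirnov test comparing log2 fold changes of predicted
   targets against all genes (exact null distribution when
   min(n, m) ≤ 25), plus a median shift for direction; and
   **multi-database target voting** (score = number of databases
   supporting each interaction).
3. **Permutation GSEA** (`miraxis.gsea`): genes ranked from most up- to
   most downregulated; the classic weighted running-sum enrichment
   score ES (hits add |s|^w / Σ|s|^w, misses subtract 1/(N − n_hits));
   significance by gene-label permutation with
   p = (1 + #{|ES′| ≥ |ES|, same sign}) / (1 + #{same sign}) at 1,000
   permutations, BH across the collection.
4. **Cross-dataset consensus** (`miraxis.consensus`): outer-join
   harmonization of heterogeneous DE tables (missing ≠ not significant),
   retention of miRNAs significant (padj < 0.05, |log2fc| > 0.5) in at
   least 3 of 6 datasets, and an `all_down` flag for miRNAs
   significantly down in every dataset that measured them.
5. **Pri-miRNA transcription inference** (`miraxis.primirna`): introns
   of a host gene = gene span minus the exon union of all overlapping
   genes; reads count only if fully intron-contained; pri-miRNA log2
   fold changes are normalized by total intronic counts and correlated
   with mature-miR fold changes (Spearman and Pearson) to classify each
   intronic miRNA as transcriptional, post-transcriptional, discordant,
   or unchanged.

A first-class synthetic-data module (`miraxis.simulate`) generates every
input with planted ground truth — seed sites planted into background
UTRs, negative-binomial counts with planted log2 fold changes, six DE
datasets with controlled significance overlap, and host-gene read sets
whose intronic compartment is reduced by 60% (log2fc −1.32) or 30%
(−0.51) under a transcriptional regime, or left flat under a processing
regime — so every stage is validated by recovery of known truth.

## Worked example

The `analysis/` drivers run the whole study on simulated data:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_seed_enrichment.py
```

prints

```
Seed scan over 300 UTRs, query of 34 downregulated genes:
  strongest enrichment at miRNA position 2 (site ACTGTAG, padj 3.32e-19) — the seed window
Target CDF shift: D=0.557, p=1.18e-20, median shift -0.69 log2 units (targets repressed, as planted)
Vote scoring over 3 prediction sources: 30 genes supported by all three
```

The scan found the planted seed-complementary site (ACTGTAG, the
reverse complement of miR-139-5p positions 2–8) as the only
significantly enriched word, at the seed position; the planted targets'
fold-change distribution is shifted down by 0.69 log2 units relative to
all genes. Continuing,

```bash
python analysis/03_dataset_consensus.py   # miR-139 is the unique all-down miR
python analysis/04_gsea.py                # the planted target set has the top (negative) ES
python analysis/05_primirna.py
```

the last step prints

```
  planted 60%-reduction miR recovered at 59% intronic-read reduction, call: transcriptional
```

i.e. the host gene planted with a 60% loss of primary-transcript
reads is recovered from intron-contained read counting at 59%, and the
miR is classified as transcriptionally regulated. Summary tables land
in `results/`; simulated raw inputs live under `scratch/simulated/`.

The same functionality is scriptable via the `miraxis` CLI
(`simulate`, `seedscan`, `cdfshift`, `votescore`, `gsea`, `consensus`,
`primir`), each subcommand writing TSV results plus a JSON run
manifest.

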