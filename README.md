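# lncflow

Inference of antagonistic flowering-regulator lncRNAs from bulk RNA-seq under
a short-day / night-break design.

Night break (NB) — a brief light pulse interrupting the dark period —
represses flowering in short-day plants. Comparing transcriptomes sampled
early under short days (SD1), late under short days (SD2), and after a night
break (NB) lets one separate long noncoding RNAs that track the
flowering-promoting signal from those that oppose it: a lncRNA that is
**up-regulated from SD1 to SD2 but down-regulated from SD2 to NB** behaves
like a positive flowering regulator, and the mirrored pattern marks a
negative regulator. `lncflow` implements the full inference chain from
assembled transcripts and a gene-level count matrix to those calls and their
competing lncRNA–mRNA target networks. It is written for plant
transcriptomics groups who have run the standard upstream stack
(HISAT2/StringTie or equivalent) and want a tested, scriptable downstream.

## What it computes

1. **lncRNA identification** — assembled transcripts are filtered to
   candidates with spliced length > 200 bp and ≥ 2 exons whose coding
   potential is rejected both by an in-house rule (longest ATG-initiated ORF
   < 300 nt) and by any user-supplied external tool verdicts (intersection
   rule). Survivors are classified by position against the reference gene
   models into **lincRNA**, **intronic**, **sense** and **antisense** classes
   via a deterministic decision cascade.
2. **Expression profiles** — FPKM
   (`fpkm = count · 10⁹ / (length · library_size)`), per-condition expressed
   sets (mean replicate FPKM > 0.1 for lncRNAs, > 1 for mRNAs), the 3-way
   Venn partition, and Spearman sample QC.
3. **Differential expression** — a transparent negative-binomial Wald test
   (median-of-ratios size factors, moment dispersion estimates moderated
   toward the genome-wide trend, BH-FDR). Calls use FDR < 0.05 and
   |log₂FC| ≥ 1.
4. **Target prediction** — *cis*: protein-coding genes within 100 kb of a
   lncRNA span; *trans*: genes with |Pearson r| > 0.9 and two-sided
   P < 0.01 over the 9 samples (on log₁₀ FPKM).
5. **Flowering calls and networks** — the two-comparison direction logic
   above, bipartite lncRNA–target networks per label, their common-target
   intersection and degree/hub statistics, with Cytoscape-ready edge tables.
6. **Enrichment** — upper-tail hypergeometric over-representation of target
   sets against user gene-set tables (BH-corrected).
7. **Synthetic data** — a fully planted toy study (annotation, sequences,
   NB counts with condition effects and correlated trans targets) so the
   whole chain is testable without downloads.

## Worked example

Run the pipeline end-to-end on the built-in synthetic study:

```bash
lncflow all --seed 1 --outdir run
```

which prints (and writes to `run/summary.json`, alongside per-stage TSVs):

```json
{
  "de_lncrna_venn": {
    "n_both": 10, "n_nb_only": 0, "n_opposite": 10,
    "n_sd_only": 0, "n_union": 10
  },
  "lncrna_census": {
    "class_counts": {"antisense": 8, "intronic": 8, "lincRNA": 16, "sense": 8},
    "density_per_mb": {"chr1": 10.0, "chr2": 10.0},
    "total": 40
  },
  "network": {
    "n_common_targets": 129, "n_neg_targets": 151, "n_pos_targets": 140,
    "negative_edges": 648, "positive_edges": 360,
    "share_of_neg_pct": 85.43, "share_of_pos_pct": 92.14
  }
}
```

Reading this: all 40 planted lncRNAs were recovered with their planted
positional classes; 10 lncRNAs are differentially expressed in both
comparisons, all with opposite trends (the 5 planted positive and 5 planted
negative regulators); their target networks share 129 mRNAs. The full
summary also records precision/recall of every planted feature
(`"recovery"` block, 1.0 across the board at the default effect size).

The same stages run on real files:

```bash
lncflow all --no-simulate \
  --reference-gtf ref.gtf --assembled-gtf stringtie.gtf \
  --fasta transcripts.fa --counts counts.tsv --samples samples.tsv \
  --outdir run_real
```

Every stage is also a plain library call (`lncflow.nb_wald_test`,
`lncflow.trans_targets`, …) returning pandas DataFrames.

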