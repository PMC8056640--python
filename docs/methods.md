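# Methods

This note documents the models, conventions and design choices behind
`lncflow`, in the order the pipeline runs them.

## Coordinates and formats

GTF files carry 1-based inclusive coordinates on disk; internally every
interval is 0-based half-open, and the GTF reader/writer is the only place
the shift happens. Only `exon` rows are interpreted (StringTie-minimal
dialect); other feature rows are counted and skipped. Span distances are
measured between closest span boundaries in half-open coordinates, so the
distance equals the number of bases strictly between two features and
overlapping spans have distance 0.

## lncRNA identification

Candidates are transcripts absent from the reference annotation with spliced
length strictly greater than 200 bp and at least 2 exons. Coding potential
combines an in-house rule with optional external tool verdicts:

* the in-house call scans all three sense-strand frames for the longest
  ATG-initiated, stop-terminated ORF (stop codon included in the length);
  codons containing `N` match neither ATG nor a stop, a conservative choice.
  A transcript is called coding when that length is ≥ 300 nt (100 codons),
  motivated by the strong separation between the ~100 bp ORF mode of
  lncRNAs and the much longer mRNA ORFs;
* the consensus is noncoding only when the in-house call **and every**
  provided external verdict are noncoding (intersection rule). A
  majority-vote alternative would be less conservative; intersection is the
  stricter reading and is the default, with the external table optional.

Positional classification against the reference gene models is a
first-match-wins cascade: (1) same-strand exonic overlap → **sense**;
(2) span fully inside a single intron of a same-strand reference transcript
→ **intronic**; (3) span overlap with an opposite-strand reference
transcript → **antisense**; (4) otherwise **lincRNA**. The ordering makes
the four classes a deterministic partition; in particular a transcript
contained in an intron on the opposite strand is antisense, because
antisense-ness is strand-defined. The cascade is verified against a
brute-force all-pairs interval scan in the tests.

## Expression

FPKM uses the column sum of the provided count matrix as the
"million fragments mapped" denominator (self-contained; externally
determined totals can be passed instead). Expressed-set thresholds are
strict (`>`), applied to the mean FPKM of a condition's replicates: 0.1 for
lncRNAs and 1 for mRNAs. Sample QC is Spearman rank correlation with
average ranks on ties; a constant sample is reported as missing.

## Differential expression

The test is a deliberately transparent member of the DESeq2 model family,
not a reimplementation of it:

* **size factors**: median-of-ratios over features with all-positive
  counts, rescaled to geometric mean 1;
* **model**: counts `K ~ NB(mean μ = s·q, var μ + αμ²)` with per-sample
  size factor `s` and condition mean `q`;
* **dispersion**: per-feature method of moments on normalized counts within
  each condition (`Var(K/s) ≈ μ·E[1/s] + αμ²`, the `E[1/s]` term corrects
  the variance inflation introduced by dividing by size factors), pooled
  across conditions by residual degrees of freedom, then shrunk toward the
  genome-wide mean with 20 prior degrees of freedom and floored at 1e-8.
  With 3 replicates per condition the raw moment estimate is far too noisy
  to plug into a Wald statistic; the strong shrinkage is what makes the
  test calibrate (null type-I error ≈ 0.05, verified by simulation in the
  suite). Real data with heavy per-gene dispersion variation is better
  served by DESeq2/edgeR, whose result tables can be imported through the
  same TSV schema;
* **statistic**: `log2fc = log2((μ̂₂ + 0.5)/(μ̂₁ + 0.5))` (pseudo-count 0.5
  stabilizes zeros), delta-method standard error from the NB variance, two-
  sided p from the standard normal, BH-FDR over all tested features.
  Features with zero counts across the comparison are excluded from the
  test and from the BH family;
* **orientation**: the second-named condition over the first, so "up in
  SD1_vs_SD2" means higher late under short days;
* **calls**: up iff FDR < 0.05 and log2fc ≥ 1; down mirrored; otherwise ns.

Not implemented (out of scope by design): multi-factor designs, Cook's
outlier replacement, independent filtering, LFC shrinkage.

## Target prediction

*Cis*: a (lncRNA, gene) pair is emitted when the genomic spans lie within
100 kb on the same chromosome, strand-agnostic, inclusive at exactly
100 kb (the boundary must be pinned for exact oracle tests; it is
configurable). Host genes of sense/intronic lncRNAs pair at distance 0 —
nothing is excluded by strand.

*Trans*: Pearson correlation over the shared samples with the two-sided p
from `t = r√((n−2)/(1−r²))` on `n−2` df; both cutoffs strict
(|r| > 0.9, p < 0.01). Correlation is computed on `log10(FPKM + 0.01)` by
default, matching the log-scale on which expression heatmaps are read; a
raw-scale switch exists because the scale convention is genuinely open.
At n = 9 the |r| > 0.9 cutoff is the binding constraint (its null
probability ≈ 9·10⁻⁴ < 0.01), so the joint rule's false-positive rate is
well below 1%, verified by Monte Carlo.

## Flowering calls, networks, enrichment

A lncRNA present in both DE tables with directions (up, down) is a putative
positive flowering regulator; (down, up) negative; anything else — including
response in only one comparison — is labelled none. Networks are bipartite
multigraphs keyed by edge mode (cis/trans), so a pair can carry one edge of
each mode but no duplicates; the common-target intersection uses the union
of cis and trans targets per network by default (trans-only is a switch,
since the pooling convention is open). Hub rankings break ties
lexicographically. Enrichment is the upper-tail hypergeometric test with BH
correction; the default universe is all genes with a nonzero count in at
least one sample, a choice the user can override since no canonical
background exists.

## Synthetic study

The generator plants everything downstream stages are supposed to find.
Defaults (all configurable): 2 chromosomes of 2 Mb; 200 coding genes tiled
over the first 75% of each chromosome (3 × 500 bp exons, 1 kb introns,
alternating strands); 40 lncRNAs — 16 lincRNA (half in intergenic gaps,
half isolated > 100 kb from any gene), 8 intronic, 8 sense, 8 antisense,
each realized geometrically so positional classification is unambiguous;
5 positive and 5 negative planted regulators with condition multipliers
(1, 2³, 1) and (2³, 1, 2³) respectively; NB counts with genome-wide
dispersion α = 0.05, per-feature baseline means log-uniform over
10^[1.5, 2.5], and per-sample library factors log-uniform in [0.7, 1.4] so
size-factor estimation is non-trivial. The scale keeps the whole pipeline
under a second; the statistical calibration checks use larger feature
counts generated directly.

Coding sequences embed one long ORF (380 non-stop codons); lncRNA sequences
are rejection-sampled until their longest ORF is below 300 nt, which lands
them near the ~100 bp ORF regime.

Planted trans targets track their regulator's *realized* log expression: the
target's per-sample log-mean is `ρ·x̃ + √(1−ρ²)·sd(x̃)·ε` (with `x̃` the
centred log profile of the regulator, ρ = 0.99 by default), amplified by a
response gain of 2 before exponentiation. The gain exists because the
target's own counting noise attenuates the count-level correlation below
the latent ρ; amplifying the shared signal restores the empirical
|r| > 0.9 rate the planted-pair checks assume, and is biologically read as
targets responding more strongly than the regulator itself. The planted cis
pairs are the gene-proximal regulators paired with their designated
neighbour (distance ≤ 2 kb by construction).

What the generator does **not** emulate: isoform ambiguity, length-biased
counting, per-gene dispersion variation, batch effects, and the weak
expression typical of real lncRNAs. Passing the recovery tests therefore
demonstrates correctness of the inference chain under its own model
assumptions, not performance on real tissue data.

## Determinism

Every random draw flows through one `numpy` Generator seeded from the
config; identical config + seed reproduce byte-identical simulated files
and pipeline summaries (JSON written with sorted keys). The gene-set
emitter uses an offset of the same seed so it is independent of draw order.

## Known limitations

* The NB Wald test's strong dispersion shrinkage matches the generator's
  shared-dispersion assumption; on real data it under-models per-gene
  dispersion heterogeneity.
* FPKM depends on the filtering state of the count matrix through its
  column totals; supply explicit library totals to pin it.
* Enrichment operates on user-supplied gene-set tables only; no ontology
  parsing or topology-aware (elim/weight) algorithms.
* The pipeline starts at assembled transcripts and counts; read-level
  processing (mapping, assembly, quantification) is out of scope.
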