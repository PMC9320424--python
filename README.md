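# regvar

Regulatory-variation analysis of GWAS index variants when full summary
statistics are unavailable.

Most disease-associated genetic variants (GVs) fall in non-coding sequence,
so the question after a GWAS is not *which gene is mutated* but *whose
regulation is perturbed*. `regvar` implements a pipeline that starts from
index variants only and builds mechanistic hypotheses along two
complementary routes:

1. **cis-eQTL colocalization** — fine-map each association locus to
   per-variant causal probabilities, intersect with fine-mapped best-eQTL
   sets, and score shared causality by the product of probabilities.
2. **Transcription-factor binding-site (TFBS) alteration** — scan each
   variant's two alleles against position weight matrices under
   consequence-set-specific Markov backgrounds, keep allele-sensitive
   sites, and validate per motif against permuted-matrix and
   matched-random-variant null distributions.

Hits surviving both chromatin-state and TF-expression gates are joined
with tissue-matched TF→target evidence into GV → TF → eGene triples.

A first-class synthetic-data module generates every input with planted
ground truth, so the whole pipeline is testable end to end without any
downloads.

## The statistics at the core

**Fine-mapping (PICS).** With only the index variant's significance
S = −log₁₀ p and LD r² to each locus member, member *i* causal implies the
index association is approximately Gaussian with mean μᵢ = r²ᵢ·S and
spread σᵢ = k·√S·(1 − rᵢᶜ)^½, rᵢ = √r²ᵢ (defaults k = 0.5, c = 3.2). The
causal probability of member *i* is its density at S, normalized over the
locus. Variants with probability > 0.10 are retained.

**Colocalization (CLPP).** Assuming independent causal processes,
CLPP = P(causal | GWAS) × P(causal | eQTL); pairs with CLPP > 0.10 are
reported, and eQTL enrichment of causal variants is tested with a
one-sided Fisher (hypergeometric) test.

**Allele-specific scanning.** A site's weight is
w = log₂ P(site | PWM) − log₂ P(site | background), with an order-2 Markov
background (captures CpG depletion) estimated per consequence set
(intergenic/UTR, intronic, regulatory, non-coding) from ChIP-seq peak
sequences. The p-value of a weight is P(W ≥ w) under the background,
computed exactly by dynamic programming on a 0.01-log₂-unit score grid.
For each (variant, matrix) the best site per allele over both strands is
kept; retention requires best weight > 1, weight difference > 1, best
p < 10⁻³ and p-value ratio > 10.

**Null controls.** Each matrix is permuted five times (column order and
within-column values, preserving information content), and matched random
variants are sampled at 1:10 (strict windows: TSS distance ±5000 bp, gene
density ±5 per 100 kbp, LD partners ±50 at r² ≥ 0.1, coding class and
variant type equality) and 1:1000 (relaxed). A motif is confirmed when its
observed p-value-ratio distribution dominates both stage-one control
distributions (one-sided Wilcoxon rank-sum, α = 0.05; exact enumeration
for small tie-free samples) and is re-confirmed against the 1:1000 system.

## Worked example

```bash
regvar simulate --seed 11 --out demo
regvar run --data demo --seed 11 --out demo_out
```

The second command prints the funnel report:

```json
{
 "seed": 11,
 "associations": 23,
 "genome_wide_significant": 20,
 "gwas_pics_records": 300,
 "causal_variants": 10,
 "coloc_candidates": 6,
 "coloc_pairs": 6,
 "fisher_p": 2.1810865905369673e-10,
 "expressed_tfs": 9,
 "scanned_variants": 140,
 "scan_results": 1530,
 "filter_passing": 170,
 "confirmed_motifs": 4,
 "confirmed_pairs": 122,
 "active_variants": 93,
 "evidence_triples": 3
}
```

Reading the funnel: of 23 simulated association records, 20 pass
genome-wide significance (p ≤ 5·10⁻⁸); their LD-expanded loci carry 300
fine-mapped variants of which 10 exceed the 10% causal-probability
threshold. Six variants colocalize with an eQTL (CLPP > 0.10), and causal
variants are strongly enriched in eQTLs (Fisher p ≈ 2.2·10⁻¹⁰). On the
binding route, 140 peak-overlapping variants scanned against the 9
brain-expressed matrices give 1530 allele comparisons, 170 of which pass
the retention thresholds; 4 motifs survive both null-control stages, and
after the chromatin-state gate 3 variant→TF→eGene triples remain, e.g.

```
rs003_00  TF03 -> GENE048   (eQTL tissue Brain_Cortex, ChIP tissue brain, disrupt)
```

meaning: rs003_00 is a probable causal GWAS variant, its alternate allele
destroys a confirmed TF03 binding site in active brain chromatin, and
TF03 is known to target GENE048 — whose expression the variant alters as
an eQTL — in matched tissue. `demo_out/` holds the full tables
(`coloc.tsv`, `scan.tsv`, `confirmed.tsv`, `triples.tsv`).

Because the demo dataset is simulated, the planted truth is in
`demo/truth.json`; the report above recovers all four planted motifs and
three of the four planted triples.

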