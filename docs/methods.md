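# Methods

This note documents the models, conventions and design decisions behind
`regvar`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Fine-mapping

Only index variants are assumed available. After filtering associations at
genome-wide significance (p ≤ 5·10⁻⁸), each index is LD-expanded with all
partners at r² ≥ `r2_min` (default 0.5; the expansion radius is
configurable because no single standard exists). Causal probabilities
follow the PICS idea: conditional on member *i* being causal, the observed
index association S = −log₁₀ p is modelled as Gaussian with mean
μᵢ = r²ᵢ·S and spread σᵢ = k·√S·(1 − rᵢᶜ)^½ where rᵢ = √r²ᵢ. Member
probabilities are the normalized densities. Defaults k = 0.5, c = 3.2;
the qualitative properties that matter — per-locus normalization, index
dominance, monotonicity in r² — hold for any positive k, c. σ is floored
at 10⁻⁶ so members in perfect LD with the index share probability exactly
evenly. Precomputed probability tables (the snapshot route) are consumed
directly when present; the internal implementation serves self-contained
runs. The retention threshold is strictly greater than 0.10.

## Colocalization

CLPP multiplies the GWAS and eQTL causal probabilities of the same
variant, assuming independence; pairs with CLPP > 0.10 (strict) are
reported, deduplicated to the best tissue per (variant, eGene) for
headline counts with all tissues kept in the detailed output. Enrichment
of causal variants in eQTLs uses a one-sided hypergeometric tail with the
universe set to all LD-expanded GWAS variants — the only construction
expressible from the inputs the pipeline has; other universes change the
p-value and remain the caller's choice.

## Markov backgrounds

Backgrounds are order-2 by default (captures CpG structure without
overfitting small corpora) and estimated per consequence set from the
ChIP-seq peak sequences overlapping that set's variants; a set with fewer
than 10 kb of training sequence falls back to the model pooled over all
sets. Counting runs over each sequence and its reverse complement with
per-sequence circular wrap-around. The wrap-around is deliberate: it makes
the prefix and suffix context marginals identical, which in turn makes the
fitted model assign *exactly* equal probability to any sequence and its
reverse complement — an invariant the scanner relies on — at the cost of
two artificial junction (k+1)-mers per training sequence, negligible for
k ≤ 2. A pseudocount (default 1 per cell) avoids −∞ transitions. A
single-strand estimation mode exists for callers who need literal
per-strand frequencies. All logs are base 2.

## Allele-specific scanning

Only sites covering the variant base are scored — allele comparison is
undefined for sites the variant cannot touch. For a window of 2·30+1
bases per allele, every offset whose L-long site covers the variant is
scored on both strands: weight = log₂ P(site | PWM) − log₂ P(site |
background conditioned on the preceding bases in the window); minus-strand
sites are scored on the reverse complement with the strand-appropriate
context. PWM counts receive a pseudocount of 1 (¼ per cell) before
normalization. Best hits per allele break ties toward the plus strand,
then the lowest offset.

The p-value of a weight is P(W ≥ w) for a random site drawn from the
background with its initial context marginalized over the stationary
distribution, computed by dynamic programming over (context, score-bin)
states. The published score grid is 0.01 log₂ units; internally the DP
runs at a quarter of that bin so accumulated per-position rounding stays
well below one reported bin (verified against exhaustive 4^L enumeration
for L ≤ 6, order ≤ 1). Queries above the maximum achievable score return
the smallest positive survival value — a sentinel below grid resolution —
so allele p-value ratios stay finite; genuine scan hits always query
within the achievable range. Score distributions are computed once per
(matrix, background) and reused across windows.

Retention applies the four published thresholds, all strict:
max allele weight > 1, weight difference > 1, min allele p < 10⁻³,
p-value ratio > 10. The ratio is direction-free (larger ÷ smaller) with
the direction kept in the `effect` field (`disrupt` when the reference
allele scores higher). With ~2L−1 candidate offsets per allele the best
site is a maximum over correlated scores, so even pure background windows
pass all four filters at roughly 1–3% per (variant, matrix); this
irreducible floor is why the per-motif null-control stage exists.

## Null controls and confirmation

Permuted matrices (five per matrix; column order shuffled, then values
within each column) preserve per-column value multisets and hence total
information content exactly. Matched random variants are drawn without
replacement per target from a pool, strictly (all five attribute windows,
same chromosome) at 1:10 and relaxed (coding class and variant type only,
any chromosome) at 1:1000; shortfalls take every eligible control and are
logged. Control variants pass through the identical scan with the target's
consequence-set background and no retention filters, so ratio
distributions are comparable.

Per motif, the observed p-value-ratio sample is all scan results for that
motif (the same convention as the controls; using only filter-passing
pairs would make a single false-passing pair confirm its motif). The
one-sided Wilcoxon ("greater") is exact by enumeration for tie-free
samples with n+m ≤ 12 and otherwise uses the normal approximation with
tie and continuity corrections. A motif is confirmed when both the
permuted-matrix and 1:10 tests reject at α = 0.05 (raw; BH-adjusted
values are reported alongside) and the 1:1000 re-test also rejects;
confirmed pairs are the filter-passing pairs of confirmed motifs. A
Shapiro–Wilk p-value per motif documents why the nonparametric route is
taken. The per-pair quantile alternative was considered and not adopted:
motif-level testing is the convention the rest of the pipeline counts by.

## Chromatin context and evidence

A variant survives the chromatin gate when its single base overlaps a
segment in one of the 12 active states (TssA, TssFlnk, TssFlnkU,
TssFlnkD, Tx, TxWk, EnhG1, EnhG2, EnhA1, EnhA2, EnhWk, ZNF/Rpts) in at
least one selected brain biosample (any-one-of suffices). TFs must reach
2 TPM (inclusive) in at least one selected brain tissue; TFs missing from
the expression matrix are retained with a warning by default. Evidence
triples require a confirmed (variant, TF) pair, an eQTL record above the
causal threshold for the eGene, and a TF→eGene ChIP record whose tissue is
equivalent to the eQTL tissue under an editable mapping (shipped defaults
group the brain biosample, brain expression-tissue and "brain" ChIP
labels). Every triple carries the identifiers of its three supporting
records.

## Synthetic data

The generator emits a 2 Mb two-chromosome genome (GC 0.41; CpG
observed/expected ≈ 0.2, produced by thinning G after C at a rate chosen
so the realized ratio matches), 60 non-overlapping genes (the first twelve
double as the TF genes of the twelve motifs), 20 significant loci of 15
variants each plus 3 sub-threshold loci, per-locus probability tables (10
planted causal loci give the index 0.55–0.85; the rest stay uniformly
below 0.10, which requires locus size ≥ 12), 800 bp peaks (ChIP-seq
regions run 100–1000 bp), motifs of length 8–14 with heterogeneous column
sharpness — one column at the 0.97 cap, the rest Dirichlet-allocated and
capped at 80% of the per-column maximum, because fully saturated matrices
have staircase score distributions whose flat treads defeat the
p-value-ratio contrast — an 18-state segmentation with planted peaks
forced active in a brain biosample, a TPM matrix with planted TFs ≥ 2 TPM
in brain (and one motif's TF silenced to exercise the expression gate),
eQTL and TF-target tables with planted and distractor records, and a
ground-truth manifest.

Planted binding variants (30 per planted motif, 4 planted motifs) sit at
the sharpest column of a motif instance written into the genome; the
instance is sampled from an annealed PWM (frequencies squared,
renormalized) so instances of one motif are diverse near-consensus sites
rather than identical copies — identical copies both skew the small
background corpus and make cross-motif scan scores a single repeated
draw. Thirty per motif is a power choice: the per-motif Wilcoxon sees
roughly 170 observed against 1000 control ratios, putting the planted
shift near z ≈ 3. Control-pool variants are placed 0.3–4 kb from each
scanned variant (the 1-Lipschitz property of TSS distance keeps them
inside every strict matching window) plus a genome-wide scatter.

What the generator does not emulate: realistic LD from population
genetics (r² decays linearly with distance from the index, pairwise to
the index only), read-level ChIP-seq signal, multi-causal loci, indels,
trans effects, and between-tissue expression correlation. Passing tests
therefore demonstrate that the machinery recovers planted effects under
idealized regulatory architecture, not that the biological effect sizes
of any real study are reproduced.

## Problem sizes and determinism

Every stochastic step takes a seed; a dataset, a pipeline run and the
acceptance script are bit-reproducible given their seeds. The acceptance
script runs five replicate datasets at the default conditions for
recovery and twenty reduced zero-effect datasets (600 kb genome, 8 loci,
6 motifs) for the type-I rate — sizes chosen so the whole script
completes in a few minutes on one CPU while keeping every rate estimate
over at least 20 planted entities or 80 motif tests. Known limitation:
the permuted-matrix control is intrinsically weak when observed windows
contain strong sites (the best-site optimizer aligns permuted sharp
columns at those windows too), so occasional planted motifs fail stage
one at α = 0.05; measured triple recovery is ~80% against the 75%
design target.
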