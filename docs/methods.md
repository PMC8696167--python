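# Methods

## Paired association test

Genotypes are coded 0/1/2 copies of the alternate allele (AA/AB/BB). For
each SNP the subjects' calls in the two conditions form a 3×3 transition
table `n[i, j]`; subjects with a missing call in either condition are
dropped per SNP. The test statistic is Bowker's symmetry statistic

    T = Σ_{i<j, n_ij+n_ji>0} (n_ij − n_ji)² / (n_ij + n_ji),

zero iff the table is symmetric. Because the asymptotic chi-square
reference is unreliable at the discordance counts typical of matched
designs, significance comes from the exact conditional null: for every
unordered genotype pair the `n_ij + n_ji` discordant subjects are
redistributed as `Binomial(n_ij + n_ji, ½)` with diagonal counts fixed.
The p-value uses the add-one convention `(b + 1)/(m + 1)` (default
`m = 100 000` replicates), so it is never zero and is slightly
conservative. When all discordance is confined to one genotype pair this
null is exactly `Binomial(n, ½)`, which the tests exploit as a closed-form
oracle. No covariates are modelled; in a within-subject paired design,
subject-level covariates cancel.

Per-SNP random streams are keyed by (master seed, CRC32 of the rsID), so
results are independent of SNP ordering or any parallel split.

### Discreteness

The exact null is discrete: with few discordant subjects the attainable
p-values are a small set that includes 1 (a perfectly symmetric table).
Consequently `P(p < α) ≤ α`, sometimes well below it at small sample
sizes. Downstream consequences are noted where they matter below.

## QC and SNP-to-gene mapping

MAF and the 1-df chi-square HWE goodness-of-fit test are computed on the
normal-tissue condition by default (`hwe_condition="both"` pools all
calls): somatic events can break Hardy–Weinberg proportions in tumors for
reasons unrelated to genotyping quality. Removal is strict
(`MAF < maf_min`, `HWE p < hwe_alpha`, both defaulting to 0.05); boundary
values are kept, and a SNP failing both filters is logged under the MAF
rule. Mapping assigns a SNP to every gene whose ±`flank` window (default
5 kb, 1-based closed interval) contains it; a SNP may belong to several
overlapping genes and then contributes to each gene's SNP count `k`. The
window is symmetric, so strand is irrelevant to mapping.

## Integration and LD correction

The three combiners (minimum, Fisher, Stouffer) are described in the
README. Conventions worth stating:

- **Stouffer tail.** `Z_i = Φ⁻¹(p_i)` and `p_combined = Φ(Z_gene)` (lower
  tail). This is the only reading under which `k = 1` is an exact identity
  and small inputs map to small outputs.
- **Clamping.** p-values are clamped to `[1e-300, 1 − 1e-16]` before
  log/quantile transforms. This never changes a result at realistic
  precision, but note that a permutation p-value of exactly 1 maps to
  `Φ⁻¹(1 − 1e-16) ≈ 8.2`, a strong "no signal" vote in the Stouffer sum —
  intended behaviour, but it makes Stouffer markedly conservative when the
  association p-values are very discrete.
- **LD correction.** `p_corr = 1 − (1 − p_gene)^((k+1)/2)` is applied
  after combination with the same `k` the combiner used. The exponent
  `(k+1)/2` encodes the assumption that roughly half the SNPs in a gene
  are effectively independent; it is used literally for even `k` (no
  rounding). It is the identity at `k = 1` and never decreases a p-value,
  so corrected significant-gene counts can only shrink.

## Enrichment algorithms

All six test the competitive null. The ranked list sorts by
`r = −log10(p)` descending, ties broken lexically by identifier so
permutation runs are reproducible. The running-sum score uses

    P_hit(S, i) = Σ_{g_j ∈ S, j ≤ i} |r_j| / N_R,   N_R = Σ_{g_j ∈ S} |r_j|,
    P_miss(S, i) = Σ_{g_j ∉ S, j ≤ i} 1 / (N − N_H),

with ES the signed deviation at the position of maximum |P_hit − P_miss|
(first such position on ties, compared with a 1e-12 float tolerance). A
set whose members all carry zero rank weight has no defined hit profile;
the single-set API raises, the batch path scores it 0.

Signed permutation statistics (ES, SPES) use the two-null-distribution
convention: the observed score is compared only against permuted scores of
the same sign, `p = (#{|same-sign| ≥ |obs|} + 1)/(#same-sign + 1)`, and
GSEA's NES divides the observed ES by the mean magnitude of the same-sign
null. An empty same-sign null yields p = 1 and an undefined (NaN) NES,
with a warning.

- **GSEA** permutes gene labels (membership shuffled over rank positions).
- **GSEA-SNP** runs the same machinery over SNPs; a SNP belongs to a set
  iff it maps into any member gene; SNP labels are permuted.
- **i-GSEA4GWAS** declares a gene significant when at least one of its
  SNPs sits among the top 5% of all SNPs by p-value (ties at the threshold
  value are included); `SPES = ES · (k/K)` with `k` and `K` the
  significant-gene proportions inside the set and in the universe. Every
  permutation round permutes SNP p-values, re-integrates with the chosen
  combiner (vectorized grouped reduceat — one code path for all three
  methods), re-ranks and re-scores.
- **MAGENTA75**'s cutoff is the 75th percentile of all gene p-values; the
  statistic counts set members strictly below it. The mock-set null (equal
  size, uniform without replacement) is sampled as hypergeometric counts,
  which is mathematically identical to drawing mock sets and counting.
- **ORA** takes genes with (corrected) `p < deg_alpha` (default 0.05) as
  significant and computes the upper-tail hypergeometric probability of
  the set overlap; with zero significant genes all p-values are 1, with a
  warning.
- **CERNO** ranks genes 1..N ascending by p (average ranks on ties — they
  matter for an analytic test) and refers `F = −2 Σ_{g∈S} ln(rank_g/N)` to
  `χ²(2·N_H)`; no permutations.

Sets are intersected with the scored universe first; sets below
`min_set_size` (default 5 — guards degenerate hypergeometric and
chi-square behaviour) are dropped with a log entry. Benjamini–Hochberg
adjustment is applied across sets within each algorithm × integration ×
LD combination; raw p-values are always retained.

## Benchmark metrics

- **Sensitivity** = `1 − π̂₀` over all set p-values of a run. `π̂₀(λ)` is
  evaluated on the λ grid 0.05…0.95 (step 0.05), smoothed with a cubic
  polynomial, read off at λ = 0.95 and clipped to [0, 1]; under 20
  p-values a single-λ (0.5) estimate is used with a warning. Storey's
  estimator needs a few hundred p-values to be stable — at ~200 sets its
  sampling noise is roughly ±0.1.
- **Prioritization** = median rank of the target sets (rank 1 = smallest
  p, average ranks on ties); random expectation is `(N + 1)/2`.
- **Specificity** = |mean FPR − 0.05| over `n_label_perms` (default 50)
  phenotype permutations. A permutation swaps the two condition labels
  within each subject independently with probability ½ — the only
  relabelling consistent with the paired design — and reruns the *full*
  pipeline including association. A stage-only shortcut was deliberately
  not built: permuting phenotype without re-running the association test
  has no coherent interpretation.
- **Reproducibility** = trapezoidal AUC of
  `|∩ top-c lists across subsets| / c` over a cutoff grid, with subjects
  split into disjoint subsets (defaults: 5 subsets of 14 pairs). The
  overlap function and grid are under-determined in the literature this
  metric comes from; the default grid is 10 evenly spaced cutoffs from 2
  to N/2, isolated in one function so alternatives can be swapped.

`normalize_and_rank` orients every metric so lower is better (sensitivity
and reproducibility are inverted), min-max normalizes across the compared
combinations (best → 0, worst → 1; a constant metric normalizes to 0 with
a warning), sums the four normalized values, and ranks ascending with
average ties. The optional k-means labels (k by silhouette over 2..6) are
descriptive only.

## Synthetic data generator

The generator emulates a matched tumor/normal genotyping study at its
published scale — defaults: 83 subject pairs, 341 gene sets of which 54
are targets. Within-gene LD comes from a Gaussian copula (exchangeable
latent correlation `ld_rho`, default 0.5) thresholded at the
Hardy–Weinberg genotype boundaries of a per-SNP allele frequency drawn
from `maf_range` — normal-condition margins are therefore exactly HWE.
Tumor genotypes re-threshold `z_t = √(1−τ)·z_n + √τ·η` with `η` an
independent copy of the gene's latent structure (`τ` = `condition_noise`,
default 0.05): the latent pair is exchangeable, so without effects the
transition tables are symmetric in distribution and the association
test's null holds *exactly*. Effects shift the tumor genotype of each
associated SNP one step toward more alternate alleles with probability
`effect_size` (default 0.4) per subject — precisely the marginal asymmetry
the test targets. Target sets draw `target_effect_fraction` (default 0.8)
of their members from a pool of `n_effect_genes` effect genes.

What the generator does **not** emulate: realistic human LD maps and
block structure beyond genes, population stratification, somatic
copy-number artifacts, genotyping batch effects. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to those real-data complications.

## Problem sizes of the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale defaults chosen
to keep full runs in the minutes range: the global-null study uses 30
pairs, 600 genes (2–5 SNPs each), 200 sets, 999 association and 499
enrichment permutations; the LD-trend study 83 pairs, 300 genes with 5–20
SNPs per gene at `ld_rho = 0.8`; the spiked study 83 pairs, 400 genes,
341 sets. For the null study the free generator knobs are
`condition_noise = 0.9` and common alleles (MAF 0.2–0.5): at 30 pairs a
lower discordance level leaves the exact test's null so discrete (a large
fraction of p-values exactly 1) that threshold-based set statistics
(ORA, MAGENTA) cannot attain their nominal level at all. With `ld_rho = 0`
there is no dependency to correct, so that suite integrates with Stouffer
without LD correction.

## Known limitations

- The exact symmetry test is conservative at small pair counts; all
  p-value-threshold consumers inherit that conservativeness.
- GSEA-SNP and i-GSEA4GWAS permute SNP labels; under strong within-gene
  LD that null ignores the dependence structure, which is a property of
  the algorithms, not of this implementation.
- Storey sensitivity on ~200 set p-values is noisy; treat small values as
  "indistinguishable from zero" rather than as precise estimates.
- The Dunn–Šidák-style LD correction uses a fixed effective-test-count
  exponent; genes whose SNPs are nearly independent are over-corrected,
  fully redundant ones under-corrected.
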