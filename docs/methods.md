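# Methods

This note records the models, estimators and numerical conventions the
package implements, the assumptions behind the synthetic-data generator,
and the design decisions taken where more than one defensible choice
existed.

## Data model and QC

Genotypes live in a samples × variants alt-allele dosage matrix
(0/1/2, −1 for missing) with variants sorted by (chromosome, position) and
named `chrom_pos` (e.g. `1A_555961328`). VCF input is read with cyvcf2;
only biallelic single-nucleotide records are kept, and half-calls or
non-diploid genotypes become missing.

Marker QC retains a variant when, in order: its missing fraction is ≤ 0.5;
it maps to one of the 21 wheat chromosomes (`[1-7][ABD]`); its minor allele
frequency strictly exceeds 0.05; and its observed heterozygosity is
strictly below 0.2. Removals are attributed to the first failing rule, so
the report's counts sum exactly to the input count. MAF and heterozygosity
are computed on non-missing calls only. Imputation is deliberately not
implemented — each statistic states its own missing-data rule instead
(complete-case per site, per pair, or frequency-imputation where a linear
model needs a filled matrix). Coordinates are 1-based; Mb values are
pos/10⁶.

## Synthetic panel generator

The generator emulates a selfing hexaploid wheat diversity panel:

* **Ancestral frequencies** ~ Uniform(maf_floor, 1 − maf_floor), matching a
  panel already filtered at that MAF (default floor 0.05). The folded
  frequency is then Uniform(maf_floor, ½) with mean (maf_floor + ½)/2.
* **Subpopulation drift** follows Balding–Nichols:
  p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), mean p and variance F·p(1−p). The
  default F = 0.06 reproduces pairwise W&C F_ST in the 0.05–0.075 band
  (the estimator recovers F to within ±0.01 at n = 2×100, m = 5000).
* **Selected loci** (default 20): the designated first subpopulation's
  frequency is displaced by `selected_delta` *beyond* its drift deviation
  from the other subpopulations' mean, on whichever side of them retains
  the divergence after clipping to [0.01, 0.99]. A naive "shift away from
  0.5" rule silently loses the divergence whenever the drifted frequency
  sits near a boundary or the other subpopulations drift toward the target;
  the implemented rule guarantees every selected locus lands in the upper
  tail of per-SNP F_ST (verified: top 5% across seeds at delta = 0.5).
* **Selfing**: the heterozygote probability is
  h = min(selfing_het, 2·min(p, 1−p)), with the suppressed heterozygote
  mass split equally between the two homozygote classes — the unique split
  that keeps the expected allele frequency at p. `selfing_het` is therefore
  the expected heterozygous-call *fraction* itself (default 0.019, the
  level real inbred wheat panels show), not an inbreeding coefficient.
* **Placement**: SNP counts per chromosome are multinomial with weights
  proportional to genome shares A/B/D = 40/49/11% and, within a genome, to
  chromosome length; positions are unique sorted uniform draws. Ref/alt
  pairs are drawn with the transition-rich class frequencies wheat GBS
  shows (Ts/Tv ≈ 2.7), so substitution accounting is realistic.
* **Missingness** is MCAR (default 0: the workflow the package mirrors
  imputes genotypes before analysis).

What the generator does **not** emulate: linkage (loci are independent, so
LD decays instantly and windowed statistics carry no positional
autocorrelation), allele-frequency spectra shaped by ascertainment, and
site-specific error. Tests passing on this generator therefore validate
estimator correctness and calibration, not robustness to LD or batch
artefacts in real panels.

Determinism: a single `numpy` Generator seeded from the config drives every
draw, so identical configs produce byte-identical VCFs.

## Diversity statistics

Per marker: allele frequency p over called genotypes, MAF = min(p, 1−p),
observed heterozygosity, Nei gene diversity GD = 2pq, and PIC in the
biallelic Botstein form 1 − p² − q² − 2p²q². The PIC extremes pin the
variant down: 0.375 at p = ½ and ≈ 0.09 at p = 0.05, exactly the range a
MAF-0.05-filtered panel reports. Substitution classes keep A/C and G/T
distinct (no strand collapsing); the Ts/Tv ratio is transitions
(A/G + C/T) over the four transversion classes.

Summary tables use the largest observed marker position as the chromosome
length (no external genome index), density = markers per Mb, and the
genome/whole-genome density as the unweighted mean of member-chromosome
densities. Note the convention trap: such tables are often labelled
"Mb per marker" while tabulating markers per Mb; this package implements
and labels markers per Mb.

## Windowed π and Tajima's D

Windows of 1 Mb with 100 kb step (defaults) tile each chromosome from
position 1 to its last SNP; the trailing windows keep full nominal length.
Per-site π = 2j(n−j)/(n(n−1)) with n the number of called haplotypes;
window π sums site values and divides by the *window length in bp*
(the VCFtools `--window-pi` convention), which at ~1 SNP/Mb density puts
values on the 10⁻⁷–10⁻⁶ scale. Tajima's D uses the standard 1989 constants
with the haplotype count taken as 2 × round(mean called samples over the
window's SNPs); it is undefined (NaN, never 0) when the window has no
segregating site or fewer than 4 haplotypes. Sites need ≥ 2 diploid calls
to contribute.

## Relatedness and structure

* **VanRaden kinship** (method 1): K = ZZ′ / (2Σp(1−p)) with missing
  dosages imputed to 2p. Negative entries are reported as 0 (pairs less
  related than random), but clamping applies only to the reported kinship —
  the GRM used for eigen-decomposition is never clamped.
* **Standardized GRM**: A as defined in the README; monomorphic markers are
  an error (they must be QC'd out). Centering with sample-estimated
  frequencies makes every row sum exactly zero, hence mean off-diagonal
  = −(mean diagonal)/(n−1).
* **PCA**: dense symmetric eigen-decomposition of A, top k (default 10),
  descending; each eigenvector's largest-magnitude loading is made positive
  so runs and downstream regressions are reproducible.
* **Rogers distance** between individuals reduces, for biallelic dosages,
  to the mean of |g_i − g_j|/2 over loci called in both; pairs with no
  shared loci are NaN.
* **Neighbor joining** is the Saitou–Nei algorithm with the
  Studier–Keppler Q criterion, deterministic lowest-index tie-breaking and
  negative branch lengths clamped to zero. On additive matrices the tree
  reproduces the input path lengths exactly (tested at 10⁻⁹, cross-checked
  against scikit-bio's implementation).

An important scale effect: selfing doubles dosage variance relative to
Hardy–Weinberg (genotypes are nearly all 0/2), so the GRM diagonal sits
near 1 + F ≈ 2 and the effective sample size n_e = −1/mean-off-diagonal
≈ (n−1)/2 — about *half* the panel size. This is exactly the behavior real
inbred panels show and is asserted in the tests (an outbred HWE fixture
gives n_e ≈ n instead).

## Differentiation

Per-SNP Weir & Cockerham (1984) variance components a/b/c use per-group
called sample sizes, allele frequencies and observed heterozygote
fractions; θ = a/(a+b+c) is reported raw (negatives kept, monomorphic
sites NaN). Pairwise and multi-group F_ST use the ratio of sums Σa/Σ(a+b+c)
— not the mean of per-locus ratios — with permutation p-values from
shuffling group labels.

AMOVA decomposes allele-level squared distances into among-subpopulation,
among-individual-within and within-individual strata. For biallelic SNPs
every sum of squared haplotype distances reduces to per-locus count
algebra (x(C−x)/C within a stratum of C alleles carrying x alternates;
each heterozygous call contributes ½ to the within-individual SS), so no
explicit distance matrix is formed. Degrees of freedom are (G−1, N−G, N):
each diploid contributes two allele vectors, giving one within-individual
df per individual. Permutation p-values: Va by permuting individuals among
subpopulations; Vb and Vc by permuting pseudo-haplotype vectors among
individuals within each subpopulation (het alleles assigned to haplotypes
at random once per run).

## LD decay

r² is the squared Pearson correlation of dosages over pairwise-complete
samples (composite LD; no phasing). The decay fit is nonlinear least
squares of the Hill–Weir/Remington drift-sampling expectation (README
formula, C = β·d) over all intra-chromosomal pairs within 50 Mb, with the
starting value chosen so C = 1 at the median pair distance; β is the only
free parameter, so the fit is deterministic. The decay distance solves
E[r²] = threshold (default 0.1) by bisection on the monotone fitted curve
and is flagged "not reached" when the curve never crosses the threshold
within 10× the observed range (e.g. when even the d→0 plateau
(10/22)(1 + 36/(22n)) sits below it). Noiseless curve data recover β to
< 1%.

## EigenGWAS scan

Per SNP and eigenvector, ordinary least squares over called samples gives
β, its standard error, χ² = (β/se)² and a p-value from χ²₁ (Wald; at panel
sizes of hundreds the difference from the t reference is negligible and it
matches the genomic-control machinery). Eigenvectors are used at unit norm,
so β's scale is arbitrary but p-values are scale-invariant. λ_GC =
median(χ²)/0.4549364 is computed per EV and P_GC is the upper χ²₁ tail of
χ²/λ_GC. Degenerate scans (all χ² = 0) fall back to unadjusted p with a
warning.

Two calibration facts, both consequences of estimating eigenvectors from
the same markers that are scanned:

1. Even with *no* population structure, λ_GC sits near the largest
   Marchenko–Pastur eigenvalue (1 + √(n/m))² — about 1.5 at n = 200,
   m = 5000 and within [0.9, 1.1] only when m/n ≳ 500. The calibration
   test therefore runs at n = 80, m = 60,000.
2. Under genuine drift (F ≈ 0.05) λ_GC reaches ~7, so the genomic-control
   design only flags loci whose differentiation stands far above the
   genome-wide drift tail — divergence ≳ 0.6 in allele frequency at
   n = 200, m = 5000. Moderate divergence (≈ 0.5) yields roughly 40%
   power at the −log₁₀(P_GC) ≥ 5 cutoff; this is a property of the method,
   not a defect, and the corresponding power assertion in the acceptance
   suite documents the shortfall rather than relaxing the conditions.

The permutation threshold reshuffles the EV across samples (default 1000
times), reruns the scan and the within-permutation λ_GC, records each
permutation's most significant P_GC, and returns −log₁₀ of the 5th
percentile of those minima — the family-wise 5% point. The fixed cutoff
5.0 is the default for region calling; when the permutation threshold is
requested the stricter of the two applies.

Significant SNPs are merged per EV and chromosome by transitive overlap of
their ±5 Mb windows; a region spans [min pos − 5 Mb (floored at 0),
max pos + 5 Mb], reported in Mb at two decimals. The representative SNP
maximizes −log₁₀(P_GC) (ties: smaller position) and carries its per-SNP
F_ST for the Miami-plot lower track. Regions from different EVs are listed
separately; a panel-level unique count collapses cross-EV overlaps, since
the same sweep often surfaces on several eigenvectors.

Panel diagnostics from the GRM: mean off-diagonal relatedness ḡ, effective
sample size n_e = −1/ḡ (flagged when ḡ ≥ 0), and effective number of
independent genome segments m_e = 1/var(off-diagonal) (≈ m/4 for
independent loci under selfing; far smaller in real data because of LD).

## Pipeline and reproducibility

`run_all` executes qc → diversity → windows → structure → differentiation
→ LD → EigenGWAS → regions, writing every table as TSV (metadata lines
prefixed `#`) plus a JSON manifest with a SHA-256 config hash and per-file
checksums; identical configs and seeds reproduce identical checksums.
Configuration is YAML; unknown fields are rejected by name. All randomness
(permutation tests, AMOVA, simulation) flows through explicitly configured
seeds. Exit codes: 0 ok, 1 user/input error, 2 internal error.

Problem sizes in the test and acceptance suites (e.g. 2×100 samples ×
5,000 markers for drift recovery, 80 × 60,000 for null calibration,
200-replicate permutation-uniformity checks) are chosen so each property
is measured at full statistical strength while the whole suite remains a
desk-scale run.

## Known limitations

* No LD in the generator: decay-distance estimates on synthetic panels are
  degenerate by design; the fit machinery is validated on curve data.
* AMOVA assumes the allele-difference molecular distance; other distances
  (e.g. stepwise) are out of scope, as are >3-level hierarchies.
* No mixed-model association, LD pruning, imputation, or annotation of
  selection regions.
* Rogers distance and pairwise r² use pairwise-complete data, which can
  bias comparisons when missingness is informative; the generator's MCAR
  assumption matches the imputed-upstream workflow the package mirrors.
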