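# Methods

## Model and procedure

The unit of inference is a miRNA window: the hairpin transcript's 1-based
closed genomic interval extended symmetrically by `flank_bp` (default
20,000 bp) on each side, clamped at position 1. Coordinates are 1-based
fully closed throughout the package; BED input (0-based half-open) is
converted at the reader boundary, so no interior code ever mixes
conventions. Strand is ignored — the flank is symmetric. Only autosomal
(chr1–22) miRNAs are tested; records on X/Y/MT are counted and removed, and
any other chromosome label raises, since it usually means an assembly
mismatch. Overlapping windows are tested independently (no merging): the
output is per-miRNA, and a SNP may legitimately contribute to several
clustered miRNAs.

A SNP belongs to a window iff it is on the same chromosome and its position
lies in the closed interval `[win_start, win_end]`. Windows with no SNP in
the summary statistics are flagged not-covered and excluded; the
bookkeeping identity `n_input = n_non_autosomal + n_not_covered + n_tested`
is asserted on every run (windows whose SNPs are all dropped by the panel
are counted as not covered, with the sub-reason logged).

### The set statistic

Each window SNP's p-value is mapped to its χ²₁ quantile (the value with
upper-tail probability p). The statistic is the sum of the k largest
quantiles with k = max(1, ⌈f·m⌉), f = 0.1 by default. The ceiling-with-
floor-one rounding reads "the top 10 % most significant SNPs" as
at-least-10 %, so 1–10-SNP windows contribute their single best SNP;
`k_rounding="floor"` is available for sensitivity analysis. Summing
χ²-transformed quantiles (rather than p-values) is what makes stronger
association increase the statistic.

### The Monte-Carlo null and the selection correction

The null distribution is estimated by drawing z ~ MVN(0, R) — R being the
window's LD matrix — squaring componentwise, and re-selecting the top k
values inside each replicate before summing. Re-selection reproduces, under
the null, exactly the selection step applied to the observed data. The
biased alternative (fixing the observed top SNPs' indices across all
replicates) understates the null and inflates rejection severalfold under
strong LD — about 0.3 at nominal 0.05 for m = 20, ρ = 0.9 — while the
re-selecting version stays inside the exact binomial 99 % band around 0.05.
That contrast is kept as a permanent regression test; the fixed-index code
path exists only behind the `fixed_indices` argument for that purpose.

The empirical p is (1 + #{sim ≥ obs}) / (1 + n_sim). The add-one estimator
never returns 0 and ties count against the observed statistic
(conservative). Simulation is staged: cumulative totals (10³, 10⁴, 10⁵,
10⁶ by default), escalating while fewer than 10 simulated statistics have
reached the observed one; draws accumulate across stages rather than being
redrawn. The last stage bounds the attainable p at 10⁻⁶, comfortably below
window-level p-values of order 10⁻⁴ that such scans produce. MVN sampling
uses an eigendecomposition square root (valid for exactly singular R, which
perfect LD produces).

Each window draws from an RNG stream seeded by (master seed, CRC32 of the
window name), so per-window results are independent of processing order and
of the `n_workers` setting; the suite asserts byte-identical outputs between
serial and 2-worker runs.

### LD estimation

LD is the Pearson correlation of genotype dosages (0/1/2, missing
mean-imputed per SNP) in the reference panel — not haplotype r — because it
needs no phasing and matches the standard r measure on unphased VCFs. SNPs
with panel MAF below `maf_min` (default 0.01) or zero variance are dropped
and counted; the simulated null then covers exactly the SNPs that remain,
and the reported `n_SNPs` refers to those. Sample correlation matrices can
be slightly indefinite; repair clips eigenvalues at 10⁻⁸, reassembles, and
rescales to unit diagonal. A repair that moves any entry by more than 0.1
raises instead, since that signals an unusably small or inconsistent panel.
Eigenvalue clipping was chosen over nearest-correlation iteration because it
is deterministic, one-shot, and adequate at the panel sizes involved.

### Multiple testing and enrichment

Benjamini–Hochberg (step-up) is applied across the windows tested within
one phenotype's scan — each results table carries its own correction
context, mirroring how paired dichotomous/continuous scans are reported.
The two enrichment tests are one-sided (greater) Fisher exact tests on 2×2
tables of SNP category (inside a miRNA window / in the eQTL list) against
nominal significance (p < alpha, default 0.05). The SNP is the counting
unit: membership is the union over windows, so a SNP in two overlapping
windows counts once and the table total equals the number of summary-
statistic SNPs. Degenerate tables (an empty margin) return p = 1 with a
warning; an eQTL list with empty intersection raises, because that indicates
an id-space mismatch rather than absence of enrichment. Displayed odds
ratios are ad/bc with 0.5 continuity only when a cell is zero.

### Phenotypes

Alda total = max(0, A − ΣB), responder "good" iff total ≥ 7, continuous
trait = raw A score with ΣB > 4 excluded. The whole input space is 11·3⁵ =
2,673 combinations, so every rule — clamping, threshold, exclusion, and the
implication good ⇒ continuous-eligible (total ≥ 7 with A ≤ 10 forces
ΣB ≤ 3) — is verified by exhaustive enumeration, not sampling. Phenotype
derivation documents the traits behind the summary statistics; association
is consumed from the summary statistics, not recomputed from phenotypes.

## The synthetic cohort generator

The generator emulates the statistical structure the test assumes, not
human population history. Haplotypes within an LD block follow a stationary
binary Markov chain with one shared allele frequency per block (drawn from
`maf_range`, default 0.05–0.5): transitions P(1|1) = p + ρ(1−p),
P(1|0) = p(1−ρ) give adjacent-allele correlation exactly ρ and lag-d
correlation ρ^d, PSD by construction; diploid genotypes are sums of
haplotype pairs. The shared per-block frequency is a deliberate
simplification — a Gaussian-threshold copula with per-SNP frequencies
attenuates the binary correlation below its latent value, which would break
the exact ρ^|i−j| target that makes LD-recovery and calibration tests sharp;
sharing the frequency within a block is defensible (blocks share ancestry)
and is the price of exactness. Blocks whose empirical MAF escapes the range
are regenerated wholesale.

Summary-statistic z-scores are drawn directly from MVN(μ, R̂) per block,
with R̂ the panel's empirical dosage correlation and μ the injected
noncentrality at causal SNPs — not by regressing simulated phenotypes.
This matches exactly the null the set test assumes, which is what makes the
type-I calibration a sharp test of the test itself rather than of an
approximation chain. P-values are two-sided normal tails, clamped below at
1e-300 so the χ² transform stays finite. Consequently the generator does
*not* reproduce: meta-analytic heterogeneity across cohorts, imputation
uncertainty, genotype missingness, allele-frequency-dependent power, or
realistic minor-allele spectra. Passing calibration here shows the
statistic and its null simulation are correct under the model's own
assumptions; it does not validate robustness to those real-data features.

Default Alda marginals (A ~ Binomial(10, 0.6); each B criterion 0/1/2 with
probabilities 0.6/0.3/0.1) give a realistic minority of good responders and
~10 % continuous-trait exclusions. The eQTL-list generator samples ids
without replacement, optionally up-weighting in-window SNPs by (1 + bias);
the power scenario for enrichment uses few windows (so in-window SNPs are a
small minority), causal SNPs placed inside windows with noncentrality 5,
and strong bias (100), under which the one-sided Fisher test detects the
enrichment in ≥ 80 % of seeds.

## Numerical and design choices

* χ² quantile inversion, normal tails, BH (via the standard step-up
  implementation) and Fisher tails all go through SciPy/statsmodels; the
  test suite holds brute-force oracles (step-up from the formula,
  hypergeometric tail sums) against them.
* Top-SNP ties are broken by position, then id, so output is deterministic
  under permutation of input rows.
* Window testing sizes: the acceptance checks use nsim = 10³ for
  calibration sweeps (500 windows × 20 seeds over m ∈ {5…150},
  ρ ∈ {0, 0.5, 0.9}), 10⁴ for power, and 10⁵–10⁶ against closed forms and
  a 10⁷-draw independent MVN oracle; these sizes put Monte-Carlo error well
  below the tolerances asserted while keeping the default suite fast.
* Results tables render p-values in scientific notation with three
  significant digits (e.g. `1.71E-02`) and positions as
  `chrN:start-end`, 1-based inclusive.
* No plotting is bundled; results are plain TSV/JSON, and a QQ plot of
  per-window p-values is a two-liner on the output table with any plotting
  library.

## Known limitations

* The LD panel and the GWAS population must match; the package harmonizes
  chromosome labels but performs no liftover or ancestry checking.
* Windows with a single usable SNP reduce to the SNP test (by design), so
  their "set" p carries no aggregation benefit.
* The empirical p floor is 1/(1 + max sims); genuinely smaller p-values
  are reported at the floor.
* Dosage correlation treats imputed means as observations; with heavy
  missingness this shrinks off-diagonal LD slightly.
* The binary-Markov LD model cannot express negative or long-range LD;
  blocks are strictly independent.
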