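# Methods

`transloci` asks whether a quantitative-trait locus discovered by GWAS in
one population carries the same causal signal in a population of different
ancestry. Differences in allele frequency, linkage disequilibrium (LD) and
sample size mean that a simple look-up of the discovery SNP in the target
study conflates "not transferable" with "not detectable"; the package
therefore combines three complementary lines of evidence — credible-set
reproducibility, trans-ethnic colocalization, and genetic risk scores — and
ships a synthetic two-population generator so every stage can be exercised
and calibrated without access-controlled cohort data.

## Association model

All phenotypes are analysed on the standardized scale. Biomarkers are
prepared by covariate residualization followed by the rank-based inverse
normal transform (INT), `out_i = Φ⁻¹((rank_i − c)/(n − 2c + 1))` with
Blom's offset `c = 3/8`; ties receive average ranks so the transform is
deterministic. LDL can be derived from total cholesterol, HDL and
triglycerides by the Friedewald formula (`TC − HDL − TG/5` in mg/dL,
`TC − HDL − TG/2.2` in mmol/L), returned as missing above the formula's
validity limit (TG > 400 mg/dL / 4.52 mmol/L).

Per-variant association uses the correlation-form score test: for
standardized trait `y` and dosage `x`, `z = r_xy·√n`, with a two-sided
normal tail p-value and matching OLS `beta`/`se` (so `z = beta/se`
exactly). The scan is a single matrix product over the standardized dosage
matrix, and accepts a *matrix* of phenotype columns — this is what makes
the permutation test below cheap. Mixed-model association (appropriate for
related or structured cohorts) is deliberately out of scope: the synthetic
populations are unrelated, and every downstream stage consumes only the
score-test contract; a covariate hook covers principal components where
needed.

## Credible-set reproducibility

For each established locus (only the most strongly associated variant per
locus is kept; hits within 50 kb for the same trait are merged greedily in
ascending discovery p), the credible set is the lead variant plus all
variants correlated with it at r² > 0.6 in an ancestry-matched reference
panel — never target-panel LD. A locus is classified in the target study
as:

* `credible_set_hit` — some member reaches p < 10⁻³;
* `region_hit` — no member does, but some variant within ±25 kb of the
  lead does;
* `not_significant` — neither;
* `indeterminate` — the target has no variant in the region at all. This
  case is surfaced explicitly rather than folded into `not_significant`.

Loci with discovery p < 10⁻¹⁰⁰ are called *major*. All inequalities are
strict. The 10⁻³ threshold is justified per study by an empirical
calibration: the minimum p in 1000 random 50-kb windows should fall below
10⁻³ in fewer than 5% of windows (for 50 independent null variants per
window the expected proportion is 1 − 0.999⁵⁰ ≈ 0.0488, so the bar is only
passed when the study-wide signal density is low).

## Trans-ethnic colocalization

Under a single causal variant, the window's score statistics are jointly
normal, `z ~ N(λ·r·ᵢ, R)` when variant `i` is causal with non-centrality
`λ`. Profiling over `λ` collapses the likelihood of "`i` is causal" to
`L(i) ∝ exp(z_i²/2)`, normalized over the window (the full-MVN evaluation
is retained as a test oracle; LD matrices are ridge-regularized with
ε = 10⁻⁶ before any inversion). With reference likelihoods `L1`, target
likelihoods `L2`, and LD neighbourhoods `N_θ(i) = {j : r²(i,j) ≥ θ}` at
θ = 0.8, the colocalization statistic is

    Λ = Σ_{i ∈ N¹_θ(m*)} L1(i) · log[ L1(i)L2(i) / max_{j ∉ N²_θ(i)} L1(i)L2(j) ]

where `m*` is the reference lead. The statistic is implemented literally
as written; the `L1(i)` inside the ratio cancels, which is noted, not
"corrected". Positive Λ means the target's likelihood mass lies inside the
lead's LD neighbourhood. Windows are lead ± 25 kb (one causal variant per
window is the model's assumption; small windows minimise interference from
secondary signals), and loci overlapping the MHC
(chr6:28,477,797–33,448,354) are excluded outright because of its LD
complexity.

Significance comes from a permutation test: the target phenotype is
shuffled across samples, the target scan and Λ recomputed with `L1` and
both LD matrices fixed, and `p = (1 + #{Λ_b ≥ Λ_obs})/(B + 1)` (add-one
estimator; ties count toward the numerator, conservatively). Observed and
permuted statistics share one vectorized code path, so for an exchangeable
null phenotype the test is exact. Degenerate windows are reported as
explicit statuses (`failed_single_snp`, `failed_no_complement`,
`failed_too_few_variants` below 5 shared variants, `failed_lead_missing`,
`excluded_mhc`) rather than silent NaNs; members of the summation set whose
target complement is empty contribute no term.

## Synthetic two-population generator

The generator reproduces the two features the method is sensitive to — LD
decay within a locus and cross-population frequency/LD divergence — with a
founder-mosaic plus Balding–Nichols construction:

1. *Ancestral pool.* Per-variant ancestral frequencies are uniform on
   [`maf_floor`, 1 − `maf_floor`] (default floor 0.05). A small founder set
   (default 12) is drawn at those frequencies, and each of the (default
   500) pool haplotypes is a recombinant mosaic of founders, switching
   founder with probability `1 − exp(−recomb_rate·gap)` between adjacent
   variants (default rate 3×10⁻⁵/bp over 100 variants spaced 500 bp, i.e.
   a 50-kb window). Zero recombination degenerates to founder copies
   (perfect LD blocks); a large rate approaches linkage equilibrium.
2. *Study populations.* Each population draws per-variant frequencies from
   the Balding–Nichols distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)` around
   the pool frequency `p` (`F = 0` leaves frequencies untouched), then
   resamples pool haplotypes and flips individual entries with exactly the
   probability that moves each variant to its drifted frequency. The flips
   also perturb haplotype structure, so LD divergence grows with F
   alongside frequency divergence — but more gently than between real
   continental populations, whose LD differs structurally (block lengths,
   recombination hotspots). This is the main respect in which passing
   synthetic tests understates real-data difficulty; see *Limitations*.
3. *Phenotypes.* `y_i = β(x_i − 1) + η_i` with `η_i ~ N(0, σ²)` i.i.d. and
   `σ² = 1`, putting phenotypes on the standardized-trait scale. Effect
   sizes span {0.10, 0.15, 0.20, 0.25}, the magnitude range typical of
   major lipid loci. Causal variants are drawn uniformly among variants
   with MAF > 0.05 in both populations.

All outputs are bit-reproducible under fixed seeds; replicate streams are
derived from a master seed via counters so any cell of an experiment can be
regenerated in isolation.

## Simulation study design

Each replicate builds a fresh locus (pool → two populations → phenotypes),
scans the reference cohort (n = 5,000 by default) to obtain `z1` and the
lead, estimates reference LD from a 500-sample subsample (the size of an
ancestry-matched public reference panel), and runs the permutation
colocalization test on the target cohort (n = 2,000, B = 200).

*Power* replicates share one causal variant between cohorts. *False
positive* replicates give the cohorts discordant causal variants, and here
the design choice matters. Drawing discordant causal variants uniformly at
genome scale means the target's causal variant essentially never falls
inside the tested 50-kb window, so the target signal within the window is
null and the phenotype-permutation p-value is exact — the nominal 5% rate
is recovered by construction. The desk-scale analogue, and the default
(`distinct_mode="unlinked"`), simulates the target causal as an unlinked
Hardy–Weinberg variant. The alternative of forcing both causal variants
*into* the window at reference r² < 0.2 (`distinct_mode="in_window"`) is
provided for sensitivity analysis, but it answers a different question: a
strong foreign signal inside the window drives Λ far below its permutation
distribution, making the test strongly conservative (empirically, 0
rejections in 150 replicates at β = 0.25). Failed-status replicates are
excluded from rate denominators and reported; more than 20% failures
aborts the cell.

Rates carry Wilson 95% intervals. The divergence experiment compares mean
power (over ≥3 seeds) at a fixed effect size across F levels; β = 0.15 is
used because power there is far from both floor and ceiling, so a
divergence effect is visible. The effect of F on power in this generator
is real but modest (a few percentage points absolute between F = 0.02 and
F = 0.4), consistent with the gentler LD divergence noted above.

## Genetic risk scores

Score variants must survive in *every* study supplied: present, MAF ≥ 0.01,
imputation info ≥ 0.8 where an info metric exists, and allele-consistent
with the discovery table. Of each pair correlated at r² > 0.1 in the
pruning reference, the variant with the larger discovery p is removed; the
traversal is greedy best-p-first (position tie-break), and the r² cap is
re-asserted on the final set. Scores are `Σ_j β_j·dosage_ij` with
discovery betas as weights, effect-allele oriented, standardized to mean 0
and sd 1; with both score and biomarker standardized, the OLS slope *is*
the correlation, reported with its standard error `√((1−r²)/(n−2))` and a
score-test p-value. Significance for the 3 scores × 3 biomarkers grid uses
the Bonferroni threshold 0.05/9 = 0.0056. Model variants missing from a
scoring panel raise an error rather than being skipped, because silent
variant loss breaks cross-study comparability — the reason the
intersection filter exists.

## Transferability labels and BMI pleiotropy

A locus is *transferable* when it is a credible-set hit **and** its
colocalization p < 0.05; *non-transferable* when colocalization is
non-significant or failed **and** no region variant reaches p < 10⁻³
**and** the discovery lead is not rare in the target (MAF ≥ 0.01,
operationalizing "not rare" with the same bound as the GRS rarity filter);
anything else — conflicting or missing evidence — is *indeterminate*, so
the three labels partition any input. The packaged lookup
(`data/bmi_lipid_lookup.tsv`) lists the 21 established lipid loci with
clear evidence for or against transferability to the Ugandan cohort along
with their BMI associations from a large European-ancestry meta-analysis;
at the Bonferroni threshold 0.05/21 = 0.0024, 10 of 14 non-transferable
and 0 of 7 transferable loci are BMI-associated. Nearest-gene annotation
takes a caller-supplied BED table; no annotation database is bundled.

## Numerical choices

* Likelihoods are computed in log space with max-subtraction; normalizers
  cancel inside Λ's ratio, so permutation columns never exponentiate.
* p-values are clamped to the smallest positive float so the (0, 1]
  invariant holds at extreme z; stored z and p agree to 10⁻⁶ relative for
  internally produced tables (externally read tables are validated at a
  looser default, since printed p-values are rounded).
* LD ridge: `(R + εI)/(1 + ε)` with ε = 10⁻⁶ keeps the unit diagonal and
  bounds the smallest eigenvalue away from zero.
* Allele harmonization resolves the eight orientation cases by exact pair,
  swap, strand complement, and complemented swap; palindromic (A/T, C/G)
  variants are always excluded — frequency-based rescue is error-prone
  precisely when populations have diverged frequencies, which is this
  package's regime. Harmonization is idempotent.
* Missing genotypes are mean-imputed (and logged) to keep the matrix
  algebra dense; monomorphic variants are dropped at load time.
* Variant identity is (chrom, pos) first, rsid fallback; coordinates are
  1-based and windows are closed intervals.

## Problem sizes

Default experiment sizes — 100-SNP 50-kb windows, n_ref = 5,000,
n_target = 2,000, 400 replicates per cell, B = 200 permutations — were
chosen so a full calibration-plus-power grid runs in minutes on a single
core while keeping Monte-Carlo error small relative to the effects being
measured (Wilson CI half-width ≈ 0.02 at a rate of 0.05 with 400
replicates). Unit tests use smaller panels; the acceptance checks use the
defaults.

## Limitations

* Divergence is parameterized by a single F per population pair; real
  population pairs differ in demographic history, admixture and
  recombination landscape, so the generator's LD divergence is milder than
  e.g. European–African contrasts. Absolute power values on synthetic
  panels therefore do not transfer to real cohorts; only orderings
  (monotonicity in β and n, decline with divergence) are claimed.
* The colocalization model assumes a single causal variant per window;
  loci with multiple nearby independent signals can interfere, and
  multi-causal extensions are future work.
* The score test assumes unrelated samples. Cohorts with relatedness or
  strong structure need mixed models, which this package does not provide.
* Indels, multi-allelic sites, X-chromosome dosage compensation and
  build liftover are out of scope.
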