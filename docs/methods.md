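# Methods

## Cohort assembly and tagging

The clinical table carries one row per subject with a `domain` column
separating the phenotyped PAH case domain from the (much larger) non-PAH
control domain. Assembly removes PAH-domain subjects recorded as
unaffected relatives or with an unknown phenotype; non-PAH records pass
through untouched. Diagnosis verification can reveal conditions outside
the canonical categories (IPAH, HPAH, PVOD/PCH); such subjects are
relabelled `other` and remain eligible for phenotype-stratum tags (KCO and
age tertiles, KCO < 50%) but never match a diagnostic tag.

Eight tags ship by default. Diagnostic tags test diagnosis membership
(I/HPAH; FPAH additionally requires a recorded positive family history;
PVOD/PCH). Stratum tags cut a continuous variable at its tertiles,
computed by linear-interpolation quantiles at 1/3 and 2/3 over the
non-missing PAH-domain values, with inclusive membership at the boundary
(value ≤ q_low for the lower, ≥ q_high for the upper tertile); the
"young age"/"old age" tags are the age-at-diagnosis tertiles. A PAH
subject missing the tag's source variable is excluded *for that tag only*.
Every non-PAH subject is a control for every tag; no phenotype filtering
is applied on the control side. Two further restrictions apply per test:
subjects not flagged as unrelated are excluded (kinship inference is out
of scope — the flag is an input), and a case already explained by a
deleterious variant in an established gene is retained only for that
gene's own test.

Lung-function criteria for classifying pulmonary hypertension as
non-lung-disease (TLC ≥ 70%, FVC ≥ 70%, FEV1 ≥ 60% predicted) are
implemented as a three-valued check: a recorded failure returns false even
when other values are missing; otherwise missingness makes the record
not-evaluable (None).

## Variant filtering

A variant enters the association test when its population MAF is strictly
below 1×10⁻⁴ — missing MAF is treated as novel, hence ultrarare — and its
CADD phred score is at least 10 (inclusive; missing CADD fails,
conservatively). Surviving variants are partitioned into a high-impact
class (frameshift, stop-gained, splice acceptor/donor) and a moderate
class (missense with SIFT = deleterious AND PolyPhen-2 = damaging);
everything else is dropped. Annotations are joined from a sidecar TSV
keyed by (chrom, pos, ref, alt) rather than parsed from VCF INFO fields.
Genotypes are read with cyvcf2 and must be diploid; the per-gene matrix
holds alternate-allele counts in {0, 1, 2}.

## The Bayesian comparison

Let y be the case indicator over the N subjects of one (gene, tag) test
and G the N×k count matrix. The baseline model draws every yᵢ at a shared
rate τ₀ ~ Beta(a₀, b₀). An association model (MOI m, impact class c)
restricts G to class-c columns, draws z | ω iid Bernoulli(ω) with
ω ~ Beta(w_a, w_b), forms the pathogenic configuration x(z, m) (dominant:
any selected allele; recessive: selected allele count ≥ 2, phase-unaware),
and draws carrier labels at τ₁ ~ Beta(a₁, b₁). Conjugacy collapses the
evidence given z to

    P(y | z) = B(a₀+n₁⁰, b₀+n₀⁰)/B(a₀,b₀) · B(a₁+n₁¹, b₁+n₀¹)/B(a₁,b₁)

with stratum counts (cases/controls among x=0 and x=1), and the z-prior to
a beta-binomial function of s = Σz. All arithmetic is in log space with
log-sum-exp.

**Exact enumeration.** For k ≤ `k_max_exact` (default 16) the 2ᵏ sum is
computed exactly. Subjects with no alternate allele in the class can never
enter the carrier stratum, so the enumeration operates on carrier rows
only (rarely more than a few dozen at these frequencies) in blocks of 4096
z-vectors; per-variant posteriors P(zⱼ=1 | y) come from the same sweep.

**Stepping-stone sampler.** Above the cap, the evidence is estimated by
the stepping-stone identity along a power-posterior ladder
p_β(z) ∝ P(z)·P(y|z)^β with 11 rungs (β = 0, then geometric up to 1),
Gibbs/Metropolis single-site updates of z at each rung (burn-in one tenth
of the draw length, minimum 20 sweeps), and a delta-method standard error
with a lag-1 autocorrelation ESS correction, summed in quadrature across
rungs. The result is flagged when the two half-chain estimates at any rung
disagree by more than 1 log unit. The sampler is deterministic given its
seed.

**Summaries.** Per model, the natural-log Bayes factor against baseline;
overall B = Σ_m w_m B_m with uniform weights over the fitted
(MOI × class) grid unless configured otherwise, PP = πB/(πB+1−π), the
model/MOI posterior ∝ w_m B_m, and per-variant posteriors under the
highest-posterior model. The prior probability of association defaults to
π = 0.001, the value at which the mapping reproduces the printed
(log BF, PP) pairs that anchor this implementation — 11.362→0.989,
9.249→0.912, 10.023→0.958 are mutually consistent only near π = 0.001 and
only if "log BF" is the natural log, which is therefore used throughout.

**Default hyperparameters.** a₀=1, b₀=9 (tagged cases are a minority of
the tested cohort), a₁=3, b₁=1 (high-penetrance expectation for a truly
pathogenic configuration), w_a=w_b=1 (uniform ω). All are configurable;
they affect Bayes factors but none of the analytic PP-recovery results,
which take the Bayes factor as given.

## Pipeline

`run_associations` iterates the (gene × tag) grid: tag assignment,
unrelatedness restriction, the explained-case rule, genotype-matrix
construction, and the estimator fit. Case and control sets are asserted
disjoint. A pair with an empty stratum is emitted flagged, without
inference; a gene with no passing variants collapses to log BF = 0,
PP = π. Significance is PP strictly above the threshold (default 0.75);
no further multiple-testing adjustment is applied, matching the posterior-
probability design. Genotype-stratified phenotype comparisons (KCO, age at
diagnosis across e.g. high-impact / missense / established-gene / no-
mutation strata) use the two-sided Mann-Whitney rank-sum test by default
— the strata are unpaired, so the paired signed-rank test (also available
via `paired=True`) would be inappropriate as a default — with exact
p-values for tie-free strata up to n = 25, and report medians with IQRs.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any real genome. Subjects are a PAH case domain (default 1000) plus a
non-PAH control domain (default 10 000). Per gene, per-variant population
allele frequencies are drawn uniformly from a configurable range capped at
1×10⁻⁴ and genotypes are Binomial(2, AF). Background phenotypes are
Gaussian, truncated to plausible ranges (KCO in [10, 150]% predicted,
centred at 71 with SD 25, matching a median of 71 [52; 86]; age at
diagnosis in [1, 90] years, centred at 49 with SD 21, matching
49 [35; 63]). Sex is drawn at the observed 68% female predominance and the
diagnosis mix follows the reported cohort composition (86.6% IPAH, 6.5%
HPAH, 1.8% PVOD/PCH, 5.1% other). A configurable fraction of cases
(default 0.2, anchored to the ~24% of cases carrying variants in
established genes) is labelled as explained by a randomly chosen
established gene to exercise the explained-case rule.

A risk gene adds forced carriers among cases at a configurable pathogenic-
configuration frequency (default 1%); each carrier's variant is drawn
AF-weighted, so recurrent variants appear in several carriers, as observed
for real recurrent nonsense alleles. Dominant carriers receive one allele,
biallelic carriers either a homozygous or a phase-unaware compound-
heterozygous configuration. With probability equal to the penetrance
(default 0.9) a carrier draws its phenotype from the carrier distributions
(KCO centred at 40% predicted — the reported value for an affected LoF
carrier — SD 10; age 65, SD 12), otherwise from background. Phenotype
missingness is applied per field (default 5% KCO, 2% age). Outputs
(clinical CSV, plain-text VCF, annotation TSV, manifest JSON) are
byte-identical under a fixed seed.

Two allele-frequency regimes are distinguished in the validation
scenarios, on biological grounds: a dominant-acting LoF gene is
constrained, with population LoF carriers at roughly 4-7 per 100 000, so
its scenario draws per-variant AF ~ U(1e-6, 7e-6) over ten high-impact
variants; a recessive-acting gene tolerates heterozygous carriers, so its
variants sit near the ultrarare cap (U(1e-6, 1e-4)). The distinction
matters: heterozygous control carriers are exactly what separates the
dominant from the recessive model, and their absence makes the two models
nearly indistinguishable on biallelic data.

What the generator does **not** model: linkage and haplotype structure,
sequencing and genotyping error, pedigrees and cryptic relatedness,
covariate effects (age/sex/smoking on KCO), ancestry structure, and
selection-driven site-frequency spectra. Passing tests therefore
demonstrate the statistical machinery under idealised sampling, not
robustness to these real-data complications.

## Validation scale and numerical choices

The shipped checks run at desk scale: null calibration uses 200
phenotype-independent genes in one 11 000-subject cohort (median PP and
the fraction above 0.75 are compared with π); power and MOI recovery use
50 simulated cohorts each at 1000 cases / 10 000 controls. Exact-vs-brute-
force agreement is checked on random instances with k ≤ 10 at 1e-10
relative tolerance. Ties in tertile cuts are resolved by the inclusive
boundary convention; the degenerate all-identical case yields q_low =
q_high so lower and upper tertile tags both capture everything. Tertile
tags on fewer than three non-missing values tag nobody. The recessive rule
is phase-unaware (documented limitation: a true cis double-het is
miscounted as biallelic).

## Known limitations

- No covariate adjustment or relatedness modelling inside the Bayesian
  comparison; unrelatedness is an input flag.
- Impact classes are binary memberships; CADD enters only through the
  ≥ 10 gate, not as a quantitative weight.
- The exact set of consequence terms counted as high impact follows the
  variant types reported in this disease context (frameshift, nonsense,
  essential splice); start-lost/stop-lost are not included by default.
- Which (MOI × class) model grid the original analyses ran per gene is not
  fully specified anywhere public; the default grid tests both MOIs on
  each class plus the pooled class and reports every per-model Bayes
  factor so alternative weightings are recoverable.
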