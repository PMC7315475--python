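# Methods

## Scope and data model

The package compares unweighted polygenic risk scores (PRS) between two
populations and asks whether the difference exceeds what
frequency-structure alone would produce.  Genotypes are biallelic SNP hard
calls (VCF 4.x; alternate-allele dosages 0/1/2, `./.` as an explicit
missing sentinel distinct from 0); the ancestral allele comes from the
`AA` INFO tag where it matches REF or ALT, otherwise the SNP is treated as
unpolarized and excluded from derived-allele computations (with a count).
Indels and multi-allelic records are skipped.  Allele matching is
exact-string on A/C/G/T with no strand flipping — including palindromic
A/T and C/G SNPs — because silent flipping is a classic source of
sign errors in scoring; unmatched SNPs are excluded and reported instead.
Coordinates are 1-based everywhere.

## The score

`PRS = Σ Gᵢ / Σ Aᵢ`, with `Gᵢ` the effect-allele dosage and `Aᵢ ∈ {0, 2}`
the called-allele count.  Restricting `Aᵢ` to {0, 2} is a deliberate
narrowing of the general {0, 1, 2} form: half-calls do not arise from
diploid VCF hard calls, and supporting them would complicate the
missingness accounting for no input this pipeline sees.  Scores are
unweighted; a `weight` column in association tables is accepted and
ignored, since effect sizes curated from heterogeneous studies are not
combinable.

Between-population differences (ΔPRS) default to the **count scale** —
the difference in mean per-individual effect-allele counts — because the
resampling machinery decomposes exactly on that scale: the count-scale
ΔPRS of any SNP set equals the sum of per-SNP mean-dosage differences
(missing calls contributing 0).  The normalized [0, 1] scale is available;
every ΔPRS records its scale, and the corrected z-score refuses to mix
scales.  The z-score itself is invariant to the choice provided observed
and null share it (asserted numerically in the tests).  Individuals with
every trait SNP missing are flagged and excluded from population means.

## LD pruning

Pairwise r² is the squared Pearson correlation of dosage vectors
(composite-genotype LD) over individuals called at both SNPs — the
appropriate statistic for unphased hard calls; it differs from haplotype
r², which would require phase.  A monomorphic SNP yields r² = 0 (LD is
undefined; treating it as absent keeps such SNPs prunable only by other
pairs); fewer than two complete pairs makes the pair undefined and skipped
with a warning.

Pruning is greedy within a sliding window of 2000 SNPs stepping by half a
window (the step is a package choice; only the window size and threshold
r² > 0.1 are externally fixed).  Whenever an in-window retained pair
exceeds the threshold, the member with the lower minor-allele frequency is
removed, ties removing the later-position SNP; the scan restarts until no
in-window pair violates the threshold.  Lower-MAF removal mirrors common
pruning practice and makes the output deterministic; windows never span
chromosomes; the result is invariant to input order and to individual
ordering.  Pruning is performed on the pooled panel of all individuals
supplied, not per population.

## Ancestry regression

`PRSᵢ = α + βxᵢ + εᵢ` with `xᵢ` one continental ancestry fraction
(African, European, or Native American; the three are consumed as input,
e.g. from ADMIXTURE, and must sum to 1 within 1e-3 — violating rows are
dropped, never renormalized).  The fit is closed-form simple OLS
(β = cov(x, y)/var(x)); the slope SE, r², t statistic and a two-tailed P
from t with n − 2 df are reported.  Degenerate x is fatal; a constant
response returns β = 0, r² = 0, P = 1.

## Permutation null

Random SNP sets of the trait-set size are drawn uniformly **without
replacement within a set, independently across sets** from a genome-wide
catalog in which each SNP carries its own effect allele; each set's
count-scale ΔPRS forms the null distribution (default 500,000 draws; the
test suite uses 5,000 with Monte-Carlo tolerances stated per test).
Implementation note: sets are drawn in bulk by rejection sampling of
duplicate-free index rows, which is exactly uniform over subsets, and each
set's ΔPRS is the sum of precomputed per-SNP deltas — an identity, not an
approximation, verified against the scoring route in the tests.

The empirical tail probability is `P = (r + 1)/(n + 1)` with `r` the
number of null samples at least as extreme as the observation in the
tested direction.  The add-one keeps P away from 0.  The direction can be
fixed (`"greater"`/`"less"`) or chosen by the observation relative to the
null mean (`"observed"`).  The observed-direction variant is
anti-conservative under the null by about a factor of two (the tail is
picked after seeing the data); the replicated calibration studies
therefore use a fixed, pre-registered direction — the African-enriched
cohort hypothesized to score higher — which is also the directional form
of the scientific claim the pipeline is built to test.

## The DAF-matched correction

Five steps: (1) observed count-scale ΔPRS over the polarized trait SNPs;
(2) the trait set's derived-allele-frequency histogram in the GWAS source
population, bins of width 0.05 on [0, 1] (half-open, last bin closed);
(3) random catalog sets matching that histogram bin-for-bin — per trait
SNP, one catalog SNP from the same source-population DAF bin, without
replacement within a set, with replacement across sets; (4) the null ΔPRS
distribution of those sets, the between-population information entering
through each sampled SNP's own genotypes in the two populations compared;
(5) `corr.ΔPRS = (obsΔPRS − μ_null)/σ_null` with an empirical P.

Design choices made where the protocol was genuinely open:

* **Bin width 0.05** (20 bins) balances matching fidelity against bin
  occupancy; it is configurable, and an underfilled occupied bin is a
  fatal error naming the bin and suggesting a larger catalog or wider
  bins.
* **Matching is on source-population DAF only.**  The populations being
  compared influence the null through the sampled SNPs' genotypes, not
  through additional matching dimensions — the most literal reading of
  "sample sets parameterized by this DAF distribution".
* **Sampled effect alleles mirror the trait set's polarization mix**:
  each sampled SNP's effect allele is its derived allele with probability
  equal to the trait set's observed derived-effect fraction (0.56 for
  typical curated GWAS sets), else the ancestral allele.  Always taking
  the derived allele would build into the null exactly the polarization
  bias the correction exists to remove.
* The normal-theory tail of z is reported as `p_normal` but labeled
  secondary; the empirical P is primary.
* Observed ΔPRS and the null are computed over the same SNP universe:
  trait SNPs that are unpolarized or absent from the genotypes are
  excluded from both sides.

The correction is conservative: any component of the observed difference
that frequency-matched arbitrary SNPs reproduce is absorbed into the null.

## The synthetic-data generator

The generator emulates the structure of a two-cohort admixed study so the
pipeline's statistical behavior can be measured against known truth.

* **Frequencies.**  Global derived-allele frequency `p ~ Uniform(0.05,
  0.95)` per SNP; each ancestral population k ∈ {AFR, EUR, NAT} gets a
  Balding–Nichols frequency `q_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean p,
  variance F·p(1−p)).  Default `F = 0.15` for all three populations — a
  conventional continental-scale differentiation magnitude; configurable.
* **Cohorts.**  Ancestry vectors are Dirichlet draws; the two default
  cohorts have concentration `mean × 30` around 0.76/0.13/0.11
  (African-enriched) and 0.07/0.75/0.18 (European-enriched), mirroring the
  observed contrast between neighboring admixed American populations.  A
  genotype is Binomial(2, Σ_k f_k q_k) in derived-allele counts; REF/ALT
  and the ancestral state are assigned per SNP at random so allele
  orientation is exercised downstream, and the truth ancestral state is
  written to the AA tag.
* **Risk architecture.**  `n_risk_snps` SNPs (default 100) become the
  trait set; each effect allele is derived with probability 0.56.  A
  differential `δ` shifts the effect-allele frequency by +δ/2 in one
  target ancestral population and −δ/2 in the other (clipped to
  [0.01, 0.99], clips counted), so two unadmixed target populations differ
  in expected effect-allele count by 2·n·δ; admixed cohorts see that
  attenuated by their ancestry-fraction contrast.
* **Ascertainment-bias emulation.**  With exponent a > 0, risk SNPs are
  selected with probability ∝ `DAF_source^a` instead of uniformly.
  Conditioning on high source-population DAF makes the selected SNPs'
  source-population frequency systematically exceed their frequency
  elsewhere (regression toward the ancestral mean), which biases the
  observed ΔPRS with no true risk differential — precisely the distortion
  the matched null absorbs, since catalog SNPs in the same DAF bin carry
  the same conditional shift.  The replicated bias studies use a = 2,
  which produces a mean observed shift of about one allele count per 100
  trait SNPs, comfortably detectable against the unmatched null yet
  realistic in size.
* **Seeding.**  One seed drives a `SeedSequence` spawn tree (frequencies,
  risk embedding, catalog polarity, one child per cohort); the whole study
  is bit-reproducible and stages can be re-run independently.
* **Not emulated:** linkage disequilibrium (SNPs are independent; pruning
  tests construct correlated columns explicitly), phenotypes, genotype
  uncertainty from imputation, sex chromosomes, and real ascertainment
  pipelines.  Passing tests therefore demonstrate the statistical
  machinery under drift-generated frequency structure, not robustness to
  LD differences between populations — a known limitation of
  frequency-only matching.

## Replicated study conditions used in the tests

Calibration and power are measured on replicated synthetic studies at the
full default scale: 20,000 genome SNPs, 100 trait SNPs, 100 individuals
per cohort, 5,000 matched-null draws per replicate (the draw count trades
empirical-P resolution against runtime; at P-grid 1/5001 it resolves the
0.05 threshold exactly).  Batches: 200 replicates at δ = 0; 200 at δ = 0
with ascertainment exponent 2; 100 at δ = 0.1; 200 δ = 0 replicates with
identical cohort ancestry (5,000 SNPs) for the null-coverage property; 100
small scoring-only replicates for the binomial-error property.  Expected
behaviors: empirical P ≤ 0.05 in ~5% of null replicates (asserted within
the 99% binomial band 2–12%), |corr.ΔPRS| ≤ 2 in ≥ 95% under
ascertainment bias, detection in a majority and regression-slope sign
recovery in ≥ 95% at δ = 0.1.

The binomial-error property (|ΔPRS| ≤ 4 SE) is evaluated with identical
Dirichlet parameters for both cohorts: with differing ancestry mixes the
between-population drift in allele frequencies adds variance that
within-cohort binomial SEs cannot cover, so the property is only coherent
under exchangeable cohorts.

## Numerical and degenerate-input conventions

* Missing genotype sentinel −1, never conflated with 0.
* Monomorphic SNP in r²: 0 with a flag; < 2 complete pairs: undefined.
* Zero called alleles at a SNP in DAF computation: SNP excluded, warning.
* Empty trait/catalog intersections, degenerate regressors, zero-matched
  association sets, zero null SD: fatal errors with messages.
* Ancestry-fraction rows are validated (sum within 1e-3), excluded when
  violating, and never renormalized beyond float rounding.
* Set sampling equals `choice(..., replace=False)` in law; all randomness
  flows through `numpy.random.Generator` seeded per stage.
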