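# admixprs

Ancestry-aware comparison of polygenic risk scores (PRS) between admixed
populations, with a derived-allele-frequency-matched resampling correction
for GWAS ascertainment bias.

## The problem

Unweighted PRS sum trait-increasing (effect) alleles over a curated SNP
set:

```
PRS = Σᵢ Gᵢ / Σᵢ Aᵢ
```

with `Gᵢ ∈ {0, 1, 2}` the effect-allele count at SNP *i* and `Aᵢ` the
number of called alleles there (2 for a called diploid genotype, 0 for a
missing one).  When two populations with different continental ancestry
mixes — say an African-enriched and a European-enriched admixed American
population — are compared through the mean difference ΔPRS, part of that
difference can be an artifact: GWAS SNPs are ascertained and discovered
preferentially at high minor-allele frequency in European cohorts, derived
alleles are usually the minor alleles there, and derived-allele frequencies
(DAF) drift apart between populations.  A trait SNP set therefore carries
DAF structure that arbitrary genome-wide SNPs do not, and between-population
DAF differences masquerade as risk differences.

`admixprs` implements the whole comparison pipeline and the bias control:

1. **Scoring** — unweighted PRS from VCF genotypes, with exact-string
   effect-allele orientation (no strand flipping; unmatched SNPs are
   excluded and reported).
2. **LD pruning** — greedy windowed pairwise-r² pruning (default 2000-SNP
   windows, r² > 0.1) to an approximately independent SNP set.
3. **Ancestry regression** — OLS of PRS on a continental ancestry fraction
   (`PRSᵢ = α + βxᵢ + εᵢ`), with slope, SE, r², t and two-tailed P.
4. **Permutation null** — ΔPRS for random same-size SNP sets drawn
   uniformly from a genome-wide catalog (500,000 by default).
5. **DAF-matched correction** — random sets matched bin-for-bin to the
   trait set's DAF distribution in the GWAS source population, preserving
   its ancestral/derived effect-allele mix (56% derived by default),
   yielding the ancestry-corrected z-score

   ```
   corr.ΔPRS = (obsΔPRS − μ_null) / σ_null
   ```

   and a one-tailed empirical P.

A synthetic admixed-cohort generator (three-way Dirichlet admixture over
Balding–Nichols population frequencies, explicit ancestral states, an
embedded risk differential of known size, optional ascertainment-bias
emulation) makes every stage testable without external genotype downloads.

## Worked example

```python
from admixprs import DafCorrection, SimulationConfig, generate_study, fit_ols
from admixprs.io import ancestry_frame
from admixprs.prs import compute_prs, delta_prs, orient_dosages

config = SimulationConfig(n_snps=20_000, n_individuals=100, n_risk_snps=100,
                          risk_daf_shift=0.1, seed=7)
study = generate_study(config)
mask_a = study.cohort_masks["african_admixed"]
mask_b = study.cohort_masks["european_admixed"]

scores = compute_prs(orient_dosages(study.genotypes, study.associations))
obs = delta_prs(scores[mask_a], scores[mask_b], scale="count")

profiles = ancestry_frame(study.ancestry)
fit = fit_ols(scores["normalized_score"].to_numpy(),
              profiles.loc[scores["individual_id"], "f_African"].to_numpy())

model = DafCorrection(n_draws=100_000, random_state=1,
                      alternative="greater").fit(
    study.genotypes, associations=study.associations,
    catalog_ids=study.catalog["id"].tolist(),
    pop_a=mask_a, pop_b=mask_b, source_pop=mask_b)
```

Formatting the resulting objects prints:

```
observed ΔPRS (count scale): +9.92
PRS ~ f_African: beta=+0.072 (se 0.006), r2=0.41, P=3.84e-24
matched null: mean +0.07, sd 3.15 (100000 draws)
corr.ΔPRS = +3.13, empirical P = 0.0008
```

The simulation embedded a true effect-allele frequency shift of δ = 0.1
across 100 risk SNPs between the African and European ancestral
populations.  The African-enriched cohort carries ~9.9 more effect alleles
per individual; PRS rises with African ancestry fraction (β > 0); and the
DAF-matched null (centered near zero, SD ≈ 3.2 allele counts) shows the
excess is not explained by frequency-matched random SNPs: the corrected
score is +3.1 null SDs, empirical P ≈ 8 × 10⁻⁴.  With `risk_daf_shift=0`
the corrected score fluctuates around zero and the empirical P is uniform.

The same pipeline runs from the shell:

```
admixprs simulate --config config.yaml --out study/
admixprs score    --vcf study/genotypes.vcf --assoc study/associations.tsv --out scores.tsv
admixprs prune    --vcf study/genotypes.vcf --assoc study/associations.tsv --out pruned.tsv
admixprs regress  --scores scores.tsv --ancestry study/ancestry.tsv --component African --out fit.tsv
admixprs daf-correct --vcf study/genotypes.vcf --assoc study/associations.tsv \
    --catalog study/catalog.tsv --pop-a a.txt --pop-b b.txt --source-pop b.txt \
    --draws 500000 --seed 1 --out correction.tsv
```

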