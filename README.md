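# kinspan

Kin-cohort survival GWAS of parental lifespans.

Human lifespan is modestly heritable, yet a prospective GWAS of age at
death would take a lifetime to collect.  The kin-cohort design
sidesteps the wait: genotype living subjects and associate their
genotypes with their *parents'* survival (age and alive/dead status),
which is already largely observed.  `kinspan` implements that analysis
end to end for biostatisticians and genetic epidemiologists: the
residualised Cox association, combination of the two parents'
information, effect-size scale conversions between study designs,
collective replication against longevity case-control studies, Bayesian
risk-factor-informed association, age/sex-stratified effects,
disease-attribution statistics, and polygenic lifespan scores.  A
synthetic cohort generator with the design's statistical structure
(Gompertz mortality, ~60% of parents deceased, father-mother trait
correlation ~0.1, offspring-to-parent genotype r² = 0.25) makes every
stage testable without any genotype data.

## The model

Parent survival follows a proportional-hazards model

    h(x) = h0(x) · exp(β·X + γ1·Z1 + … + γk·Zk)

with x parent age, X offspring dosage, Z covariates.  Per-SNP fits are
replaced by one covariates-only Cox fit per parent sex: its Martingale
residuals divided by the proportion dead form a trait whose OLS slope on
dosage estimates the parent log hazard ratio.  Because a subject allele
comes from the indexed parent with probability ½, estimates are
**doubled** to the carrier scale and negated to the log protection ratio
(lnPR; positive = longer life; years of life ≈ 10 × lnPR).  Both-parent
evidence is combined two ways: a common-effect regression on the summed
parent residuals (CES), and a 2-df MANOVA-style test allowing
sex-specific effects (SSE), each accounting for the father-mother trait
correlation; genome-wide significance is 2.5 × 10⁻⁸ for the two tests.

See `docs/methods.md` for the full statistical account, including the
Bayesian prior construction, the replication alpha-ratio machinery, the
lifespan-variance-explained (2pqa²) attribution rules, and what the
synthetic cohorts do and do not emulate.

## Worked example

```python
import numpy as np
from kinspan import simcohort, kingwas, effectscale

snps = [
    simcohort.SnpSpec(id="rs_protective", maf=0.30, beta_carrier=0.10),
    simcohort.SnpSpec(id="rs_null", maf=0.20, beta_carrier=0.0),
]
cohort = simcohort.simulate_cohort(20_000, snps, seed=1)

print("proportion of parents deceased:",
      round(float(cohort.subjects[["father_dead", "mother_dead"]].mean().mean()), 3))

result = kingwas.run_cohort_gwas(cohort, mode="ces")
for _, row in result.iterrows():
    years = effectscale.years_from_lnpr(row["beta1"])
    print(f"{row['snpid']:>14}  lnPR = {row['beta1']:+.4f} (SE {row['se']:.4f})"
          f"  years/allele = {years:+.3f}  p = {row['p']:.2e}")
```

prints

```
proportion of parents deceased: 0.598
 rs_protective  lnPR = +0.0842 (SE 0.0211)  years/allele = +0.842  p = 6.81e-05
       rs_null  lnPR = +0.0050 (SE 0.0239)  years/allele = +0.050  p = 8.34e-01
```

The cohort lands at the design's 60% deceased; the protective allele is
recovered on the carrier lnPR scale (simulated 0.10, estimated
0.084 ± 0.021 — marginal hazard ratios are slightly attenuated by the
simulated family frailty, exactly as they would be in real data), while
the null SNP stays null.  The same pipeline is scriptable from the
shell:

```bash
kinspan simcohort --n 20000 --snps-file snps.tsv --seed 1 --out cohort.tsv
kinspan kingwas run --cohort cohort.tsv --mode ces --out ces.tsv
kinspan prs build --sumstats ces.tsv --threshold 1.0 --out model.tsv
```

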