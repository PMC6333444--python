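import numpy as np
import pytest

from kinspan import kingwas, simcohort


@pytest.fixture(scope="session")
def null_cohort():
    """Mid-size cohort with no genetic effects, at default study conditions."""
    snps = [simcohort.SnpSpec(id=f"null{i}", maf=0.1 + 0.02 * i)
            for i in range(10)]
    return simcohort.simulate_cohort(6000, snps, seed=11)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with one protective SNP (0.2 lnPR) and one null SNP.

    No frailty, so marginal hazard ratios are unattenuated and parameter
    recovery can be checked against the nominal simulated effect.
    """
    snps = [simcohort.SnpSpec(id="hit", maf=0.3, beta_carrier=0.2),
            simcohort.SnpSpec(id="neutral", maf=0.3)]
    return simcohort.simulate_cohort(20000, snps, seed=7, frailty_sd=0.0, rho=0.0)


@pytest.fixture(scope="session")
def effect_cohort_phenotypes(effect_cohort):
    cov = effect_cohort.covariates()
    fa = effect_cohort.parent("father")
    mo = effect_cohort.parent("mother")
    phen_f = kingwas.fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
    phen_m = kingwas.fit_residual_phenotype(mo["age"], mo["dead"], cov, "mother")
    return phen_f, phen_m


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
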