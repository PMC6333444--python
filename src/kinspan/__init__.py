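"""kinspan: kin-cohort survival GWAS of parental lifespans.

A toolkit for genome-wide association of survival using the kin-cohort
design (subject genotypes, parent lifespans): residualised Cox phenotype
construction, combined-parent association (common and sex-specific
effects), effect-size scale conversions, collective replication against
longevity studies, Bayesian risk-factor-informed association, age/sex
stratified effects, disease lifespan-variance attribution, and polygenic
lifespan scores — plus a synthetic cohort generator so the whole pipeline
is testable without any genotype data.
"""

from importlib import resources as _resources

import pandas as _pd

from . import (diseaselve, effectscale, igwas, kingwas, prs, replication,
               simcohort, strata, sumstats)

__all__ = [
    "simcohort", "kingwas", "effectscale", "replication", "igwas",
    "strata", "diseaselve", "prs", "sumstats", "load_lifespan_gws_loci",
]

__version__ = "0.1.0"


def load_lifespan_gws_loci() -> _pd.DataFrame:
    """Published genome-wide significant parental-lifespan loci.

    The 12 loci reaching genome-wide significance (p < 2.5e-8, two
    combined tests) in the 1,012,240-parent meta-analysis, with effect
    sizes in years of life per effect allele (Years1 = 10 x lnPR).
    """
    with _resources.files("kinspan.data").joinpath(
            "lifespan_gws_loci.tsv").open("r") as fh:
        return _pd.read_csv(fh, sep="\t")
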