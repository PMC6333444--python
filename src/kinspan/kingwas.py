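"""Kin-cohort GWAS of parental lifespan via residualised Cox models.

The design: subjects are genotyped, their parents are not, but parent
survival (age and alive/dead status) is known.  A Cox proportional-hazards
model of parent survival on covariates only is fitted once per parent sex;
its Martingale residuals, divided by the proportion dead, form a trait
whose linear regression slope on any offspring dosage estimates the
parent's log hazard ratio for that SNP — at half strength, because a
subject allele has a 50% chance of coming from the indexed parent.
Estimates are therefore doubled to the carrier scale and negated to log
protection ratios (lnPR; positive = longer life).

Two combined-parents analyses are provided:

* CES (common effect sizes): regression on the *summed* father + mother
  residual.  The summed trait's slope is already the carrier lnPR (the
  two halves add), and its sampling variance automatically absorbs the
  father-mother covariance — so CES results are never doubled again.
* SSE (sex-specific effect sizes): a bivariate Wald (MANOVA-style) test
  z' R^{-1} z on 2 df that either parent's effect is nonzero, with R the
  2x2 correlation matrix of the parent traits.

Cross-cohort/parent meta-analysis uses inverse-variance weighting with
standard errors inflated by sqrt(1 + r) for the inter-trait correlation r
(slightly conservative; the exact two-estimate variance
Var0 * (1 + 2 r s1 s2 / (s1² + s2²)) is also exposed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from scipy import stats

from . import sumstats

__all__ = [
    "GENOME_WIDE_SIG",
    "DEFAULT_MAF_FILTER",
    "ResidualPhenotype",
    "MetaConfig",
    "fit_residual_phenotype",
    "gwas_single_parent",
    "combine_ces",
    "combine_sse",
    "meta_ces_correlated",
    "run_cohort_gwas",
]

#: Genome-wide significance threshold accounting for the two combined
#: analyses (CES and SSE) run on every SNP: 5e-8 / 2.
GENOME_WIDE_SIG = 2.5e-8
DEFAULT_MAF_FILTER = 0.005


@dataclass
class ResidualPhenotype:
    """Hazard-ratio-scaled residual trait for one parent sex.

    ``residuals`` are Martingale residuals divided by the proportion of
    parents dead; raw Martingale residuals sum to zero, so the scaled
    trait does too.
    """

    residuals: np.ndarray
    parent_sex: str
    prop_dead: float
    n_lives: int
    n_deaths: int

    @property
    def variance(self) -> float:
        return float(np.var(self.residuals, ddof=1))


@dataclass(frozen=True)
class MetaConfig:
    """Inter-trait correlation and combination mode for meta-analysis."""

    r: float = 0.1
    mode: str = "ces"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must be in [-1, 1]")
        if self.mode not in ("ces", "sse"):
            raise ValueError("mode must be ces|sse")


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept + covariates design matrix; checks full rank."""
    if covariates is None or (hasattr(covariates, "shape") and covariates.size == 0):
        return np.ones((n, 1))
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return C


def fit_residual_phenotype(ages, dead, covariates=None,
                           parent_sex: str = "parent") -> ResidualPhenotype:
    """Fit the covariates-only Cox model and return the scaled residual trait.

    With covariates, a Cox partial-likelihood fit provides the cumulative
    hazard for each parent at exit; without covariates the Nelson-Aalen
    estimator is the same thing.  The Martingale residual (event indicator
    minus cumulative hazard at exit) divided by the proportion dead is the
    GWAS trait.

    Raises if there are fewer than two deaths (no survival information).
    """
    ages = np.asarray(ages, dtype=float)
    dead = np.asarray(dead, dtype=bool)
    n = ages.size
    n_deaths = int(dead.sum())
    if n_deaths < 2:
        raise ValueError("need at least two deaths to fit a survival model")
    prop_dead = n_deaths / n

    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        naf = NelsonAalenFitter()
        naf.fit(ages, event_observed=dead)
        cumhaz = naf.cumulative_hazard_at_times(ages).to_numpy()
        martingale = dead.astype(float) - cumhaz
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), C])) < C.shape[1] + 1:
            raise ValueError("covariate matrix is rank deficient")
        df = pd.DataFrame(C, columns=[f"z{i}" for i in range(C.shape[1])])
        df["age"] = ages
        df["dead"] = dead.astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="age", event_col="dead")
        except Exception as exc:  # pragma: no cover - lifelines raises rarely here
            raise ValueError(f"Cox fit did not converge: {exc}") from exc
        martingale = cph.compute_residuals(df, kind="martingale") \
            ["martingale"].reindex(df.index).to_numpy()

    return ResidualPhenotype(residuals=martingale / prop_dead,
                             parent_sex=parent_sex, prop_dead=prop_dead,
                             n_lives=n, n_deaths=n_deaths)


def _ols_scan(y: np.ndarray, dosages: np.ndarray, C: np.ndarray):
    """Per-column OLS slope of y on dosage, both residualised on C.

    Frisch-Waugh-Lovell: project y and every dosage column off the
    covariate span once, then each slope is a univariate regression.
    Missing dosages are mean-imputed per SNP.  Returns (slope, se, keep)
    where keep is False for (near-)monomorphic columns.
    """
    n = y.size
    D = np.array(dosages, dtype=float, copy=True)
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D[idx] = np.take(col_mean, idx[1])

    coefC, *_ = np.linalg.lstsq(C, np.column_stack([y[:, None], D]), rcond=None)
    R = np.column_stack([y[:, None], D]) - C @ coefC
    y_star, D_star = R[:, 0], R[:, 1:]

    dtd = np.einsum("ij,ij->j", D_star, D_star)
    keep = dtd > 1e-10 * n
    slope = np.full(D.shape[1], np.nan)
    se = np.full(D.shape[1], np.nan)
    yty = float(y_star @ y_star)
    dty = D_star.T @ y_star
    with np.errstate(invalid="ignore", divide="ignore"):
        slope[keep] = dty[keep] / dtd[keep]
        rss = yty - slope[keep] ** 2 * dtd[keep]
        dof = n - C.shape[1] - 1
        sigma2 = np.maximum(rss, 0.0) / dof
        se[keep] = np.sqrt(sigma2 / dtd[keep])
    return slope, se, keep


def _records(snp_ids, slope, se, keep, freq1, n_lives, n_deaths,
             scale: float) -> pd.DataFrame:
    """Assemble association records: beta = -scale * slope (lnPR)."""
    beta = -scale * slope
    se_out = scale * se
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se_out
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "snpid": snp_ids, "a1": "A", "a0": "G", "freq1": freq1,
        "beta1": beta, "se": se_out, "z": z, "p": p,
        "n_lives": n_lives, "n_deaths": n_deaths,
    })
    if not np.all(keep):
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        warnings.warn(f"monomorphic SNP(s) emitted with NA statistics: {dropped[:5]}"
                      + ("..." if len(dropped) > 5 else ""))
        out.loc[~np.asarray(keep), ["beta1", "se", "z", "p"]] = np.nan
    return out


def gwas_single_parent(phenotype: ResidualPhenotype, dosages: np.ndarray,
                       covariates=None, snp_ids=None) -> pd.DataFrame:
    """Single-parent GWAS of the residual trait.

    OLS of the scaled residual on each dosage (plus the Cox covariates,
    guarding against residual confounding); the slope and SE are doubled
    to the carrier scale and the sign flipped to lnPR.
    """
    y = phenotype.residuals
    n = y.size
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[0] != n:
        raise ValueError("dosages not aligned to subjects")
    if snp_ids is None:
        snp_ids = [f"snp_{j}" for j in range(dosages.shape[1])]
    C = _design(covariates, n)
    slope, se, keep = _ols_scan(y, dosages, C)
    freq1 = np.nanmean(dosages, axis=0) / 2.0
    return _records(snp_ids, slope, se, keep, freq1,
                    phenotype.n_lives, phenotype.n_deaths, scale=2.0)


def combine_ces(father: ResidualPhenotype, mother: ResidualPhenotype,
                dosages: np.ndarray, covariates=None, snp_ids=None) -> pd.DataFrame:
    """Common-effect-size analysis via the total (summed) parent residual.

    Under a common effect, the summed trait's slope is *twice* the
    single-parent (pre-doubling) slope, i.e. already the carrier-scale
    effect, so no further doubling is applied; the regression SE of the
    summed trait automatically reflects the parents' covariance.
    """
    if father.residuals.size != mother.residuals.size:
        raise ValueError("father and mother subject sets differ in size")
    y = father.residuals + mother.residuals
    n = y.size
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[0] != n:
        raise ValueError("dosages not aligned to subjects")
    if snp_ids is None:
        snp_ids = [f"snp_{j}" for j in range(dosages.shape[1])]
    C = _design(covariates, n)
    slope, se, keep = _ols_scan(y, dosages, C)
    freq1 = np.nanmean(dosages, axis=0) / 2.0
    return _records(snp_ids, slope, se, keep, freq1,
                    father.n_lives + mother.n_lives,
                    father.n_deaths + mother.n_deaths, scale=1.0)


def combine_sse(z_father, z_mother, r: float):
    """Sex-specific-effects MANOVA: bivariate Wald test on 2 df.

    chi² = z' R^{-1} z with R = [[1, r], [r, 1]] reduces to
    (z_f² + z_m² - 2 r z_f z_m) / (1 - r²).  Tests the null that both
    parents' effects are zero; produces no single combined beta.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    zf = np.asarray(z_father, dtype=float)
    zm = np.asarray(z_mother, dtype=float)
    chi2 = (zf ** 2 + zm ** 2 - 2.0 * r * zf * zm) / (1.0 - r ** 2)
    p = stats.chi2.sf(chi2, df=2)
    return chi2, p


def meta_ces_correlated(records: list[pd.DataFrame], r: float = 0.1) -> pd.DataFrame:
    """Correlation-adjusted inverse-variance meta-analysis.

    Pools >= 2 estimate tables of the same SNPs (allele-harmonised onto
    the first table's coding).  The pooled beta is the plain IVW estimate;
    the reported SE is SE0 * sqrt(1 + r), slightly conservative relative
    to the exact two-estimate variance
    Var0 * (1 + 2 r s1 s2 / (s1² + s2²)), which is also returned for
    two-table input as ``se_exact`` (equal to the sqrt(1+r) SE when
    s1 = s2).
    """
    if len(records) < 2:
        raise ValueError("need at least two estimate tables")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")

    base = records[0].copy()
    betas = [base.set_index("snpid")["beta1"]]
    ses = [base.set_index("snpid")["se"]]
    for other in records[1:]:
        m = sumstats.harmonise(base, other)
        betas.append(m.set_index("snpid")["beta1_y"])
        ses.append(m.set_index("snpid")["se_y"])

    B = pd.concat(betas, axis=1, join="inner")
    S = pd.concat(ses, axis=1, join="inner")
    w = 1.0 / S.to_numpy() ** 2
    beta = (w * B.to_numpy()).sum(axis=1) / w.sum(axis=1)
    var0 = 1.0 / w.sum(axis=1)
    se = np.sqrt(var0 * (1.0 + r))

    out = pd.DataFrame({"snpid": B.index, "beta1": beta, "se": se})
    if len(records) == 2:
        s1, s2 = S.to_numpy()[:, 0], S.to_numpy()[:, 1]
        factor = 1.0 + 2.0 * r * s1 * s2 / (s1 ** 2 + s2 ** 2)
        out["se_exact"] = np.sqrt(var0 * factor)
    out["z"] = out["beta1"] / out["se"]
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    a_cols = base.set_index("snpid").loc[out["snpid"], ["a1", "a0"]].reset_index(drop=True)
    out[["a1", "a0"]] = a_cols
    return out.reset_index(drop=True)


def run_cohort_gwas(cohort, mode: str = "ces", r: float = 0.1,
                    maf_filter: float = DEFAULT_MAF_FILTER) -> pd.DataFrame:
    """Convenience pipeline: residual phenotypes -> CES or SSE per SNP."""
    cov = cohort.covariates() if cohort.covariate_cols else None
    fa, mo = cohort.parent("father"), cohort.parent("mother")
    phen_f = fit_residual_phenotype(fa["age"], fa["dead"], cov, "father")
    phen_m = fit_residual_phenotype(mo["age"], mo["dead"], cov, "mother")

    freq = cohort.dosages.mean(axis=0) / 2.0
    keep = (np.minimum(freq, 1 - freq) >= maf_filter)
    dosages = cohort.dosages[:, keep]
    snp_ids = [s for s, k in zip(cohort.snp_ids, keep) if k]

    if mode == "ces":
        return combine_ces(phen_f, phen_m, dosages, cov, snp_ids)
    if mode == "sse":
        rec_f = gwas_single_parent(phen_f, dosages, cov, snp_ids)
        rec_m = gwas_single_parent(phen_m, dosages, cov, snp_ids)
        chi2, p = combine_sse(rec_f["z"], rec_m["z"], r)
        return pd.DataFrame({
            "snpid": snp_ids, "a1": rec_f["a1"], "a0": rec_f["a0"],
            "freq1": rec_f["freq1"], "chi2": chi2, "p": p,
            "z_father": rec_f["z"], "z_mother": rec_m["z"],
            "n_lives": rec_f["n_lives"] + rec_m["n_lives"],
            "n_deaths": rec_f["n_deaths"] + rec_m["n_deaths"],
        })
    raise ValueError("mode must be ces|sse")
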