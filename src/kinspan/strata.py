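"""Age-band and sex-stratified hazard ratios with moderator meta-regression.

The proportional-hazards assumption of the genome-wide scan is probed by
re-estimating each variant's effect within independent bands of age: a
parent who died younger than a band is excluded from it, a parent who
outlived the band is treated as alive at the band's end, and entry into
the band is handled by left truncation.  Band estimates (doubled to the
carrier lnPR scale) are then regressed on the band's mean age and on
parent sex by fixed-effects weighted least squares with known variances —
the classic meta-regression with moderators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_BANDS",
    "StratumEstimate",
    "ModeratorFit",
    "stratify_survival",
    "moderator_regression",
    "moderator_scan",
    "strata_table",
]

#: Age decades from 40 to 90 plus one wide terminal band.
DEFAULT_BANDS = [(40.0, 50.0), (50.0, 60.0), (60.0, 70.0),
                 (70.0, 80.0), (80.0, 90.0), (90.0, 120.0)]


@dataclass(frozen=True)
class StratumEstimate:
    """Carrier-scale lnPR for one SNP within one sex x age band."""

    snpid: str
    parent_sex: str
    age_lo: float
    age_hi: float
    beta: float
    se: float
    n_lives: int
    n_deaths: int

    def __post_init__(self) -> None:
        if self.age_lo >= self.age_hi:
            raise ValueError("age_lo must be < age_hi")
        if self.se <= 0:
            raise ValueError("se must be > 0")

    @property
    def mid_age(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


@dataclass(frozen=True)
class ModeratorFit:
    """Fixed-effects moderator model beta = b0 + b_age*age + b_sex*male."""

    intercept: float
    beta_age: float
    beta_sex: float
    se_intercept: float
    se_age: float
    se_sex: float
    p_age: float
    p_sex: float


def _check_bands(bands) -> list[tuple[float, float]]:
    bands = [(float(lo), float(hi)) for lo, hi in bands]
    for lo, hi in bands:
        if lo >= hi:
            raise ValueError("bands must have lo < hi")
    for (_, hi_prev), (lo, _) in zip(bands, bands[1:]):
        if lo < hi_prev:
            raise ValueError("bands must be non-overlapping and ordered")
    return bands


def stratify_survival(cohort, snp_ids=None, bands=DEFAULT_BANDS) -> list[StratumEstimate]:
    """Per-band, per-sex Cox estimates of each SNP's carrier lnPR.

    Within band (lo, hi]: parents with age_last <= lo are excluded (dead
    ones died before the band; alive ones were lost before entering it),
    exit is min(age_last, hi), the event fires only for deaths inside the
    band, and entry is left-truncated at lo.  The offspring-dosage Cox
    coefficient is doubled and negated to the carrier lnPR.  Bands with
    zero deaths are omitted with a warning.
    """
    bands = _check_bands(bands)
    if snp_ids is None:
        snp_ids = cohort.snp_ids
    cov = cohort.covariates() if cohort.covariate_cols else None
    out: list[StratumEstimate] = []
    for sex in ("father", "mother"):
        rec = cohort.parent(sex)
        age = rec["age"].to_numpy()
        dead = rec["dead"].to_numpy()
        for lo, hi in bands:
            in_band = age > lo
            if not in_band.any():
                warnings.warn(f"{sex} band {lo}-{hi}: no parents at risk; omitted")
                continue
            exit_age = np.minimum(age[in_band], hi)
            event = dead[in_band] & (age[in_band] <= hi)
            n_deaths = int(event.sum())
            if n_deaths == 0:
                warnings.warn(f"{sex} band {lo}-{hi}: zero deaths; omitted")
                continue
            base = {"start": np.full(in_band.sum(), lo), "stop": exit_age,
                    "event": event.astype(int)}
            for sid in snp_ids:
                j = cohort.snp_ids.index(sid)
                df = pd.DataFrame(base)
                df["dosage"] = cohort.dosages[in_band, j]
                if cov is not None:
                    for k in range(cov.shape[1]):
                        df[f"z{k}"] = cov[in_band, k]
                cph = CoxPHFitter()
                try:
                    cph.fit(df, entry_col="start", duration_col="stop",
                            event_col="event")
                except ConvergenceError:
                    warnings.warn(f"{sid} {sex} band {lo}-{hi}: Cox fit failed; omitted")
                    continue
                beta = -2.0 * float(cph.params_["dosage"])
                se = 2.0 * float(cph.standard_errors_["dosage"])
                out.append(StratumEstimate(snpid=sid, parent_sex=sex,
                                           age_lo=lo, age_hi=hi, beta=beta,
                                           se=se, n_lives=int(in_band.sum()),
                                           n_deaths=n_deaths))
    return out


def moderator_regression(estimates: list[StratumEstimate]) -> ModeratorFit:
    """Fixed-effects WLS of band betas on mean band age and sex.

    Weights are the known inverse variances 1/se²; coefficient covariance
    is (X'WX)^{-1} (known-variance meta-regression, not residual-scaled),
    with Wald normal p-values.  Age is the band midpoint in years; sex is
    0 = mother (reference), 1 = father.
    """
    if len(estimates) < 3:
        raise ValueError("need at least three stratum estimates")
    ages = np.array([e.mid_age for e in estimates])
    sexes = np.array([1.0 if e.parent_sex == "father" else 0.0 for e in estimates])
    if len(set(ages)) < 2 or len(set(sexes)) < 2:
        raise ValueError("strata must span at least two ages and both sexes")
    y = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se ** 2 for e in estimates])
    X = np.column_stack([np.ones(len(y)), ages, sexes])
    XtW = X.T * w
    A = XtW @ X
    if np.linalg.cond(A) > 1e12:
        raise ValueError("singular moderator design")
    cov = np.linalg.inv(A)
    b = cov @ (XtW @ y)
    se = np.sqrt(np.diag(cov))
    pz = 2.0 * stats.norm.sf(np.abs(b / se))
    return ModeratorFit(intercept=b[0], beta_age=b[1], beta_sex=b[2],
                        se_intercept=se[0], se_age=se[1], se_sex=se[2],
                        p_age=pz[1], p_sex=pz[2])


def moderator_scan(estimates: list[StratumEstimate]) -> pd.DataFrame:
    """Moderator fits for every SNP with BH q over the SNP x moderator family.

    Mirrors the reporting shape: one row per (variant, moderator) with
    effect, SE, p, and q computed across the whole panel.
    """
    rows = []
    for sid in sorted({e.snpid for e in estimates}):
        fit = moderator_regression([e for e in estimates if e.snpid == sid])
        rows.append({"snpid": sid, "moderator": "age", "beta": fit.beta_age,
                     "se": fit.se_age, "p": fit.p_age})
        rows.append({"snpid": sid, "moderator": "sex", "beta": fit.beta_sex,
                     "se": fit.se_sex, "p": fit.p_sex})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def strata_table(estimates: list[StratumEstimate]) -> pd.DataFrame:
    """Stratum estimates as a flat table (variant, parent, age range, ...)."""
    return pd.DataFrame([{
        "snpid": e.snpid, "parent": e.parent_sex,
        "age_lo": e.age_lo, "age_hi": e.age_hi,
        "n": e.n_lives, "deaths": e.n_deaths,
        "beta": e.beta, "se": e.se, "z": e.beta / e.se,
        "p": 2.0 * stats.norm.sf(abs(e.beta / e.se)),
    } for e in estimates])
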