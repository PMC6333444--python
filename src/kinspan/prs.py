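"""Polygenic lifespan scores: clump + threshold, survival and disease tests.

A lifespan polygenic score is the dosage-weighted sum of clumped
(distance/LD-pruned) training-GWAS effect sizes over SNPs passing a
p-value threshold, Z-standardised on the scored sample.  Association with
parent survival uses a Cox model whose coefficient is doubled (parent
genotypes are imputed at 50% from offspring) and negated to the lnPR
scale; top-vs-bottom decile Kaplan-Meier median contrasts express the
score's reach in years of life.  Disease associations use logistic
regression of *not* carrying the disease, so positive effects are always
protective, with first-degree-relative estimates doubled and kin
meta-analysis standard errors inflated for family-member trait
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .diseaselve import prune_loci
from .effectscale import years_from_lnpr

__all__ = [
    "PRSModel",
    "SurvivalAssoc",
    "DecileContrast",
    "build_prs",
    "score_cohort",
    "score_and_associate",
    "decile_contrast",
    "disease_associations",
]


@dataclass
class PRSModel:
    """Clumped, thresholded SNP weight list for a lifespan score.

    ``weights`` is indexed by snpid with columns ``a1, beta``;
    ``training_cohorts`` records which cohort labels contributed to the
    training summary statistics, enforcing the train/test split.
    """

    weights: pd.DataFrame
    p_threshold: float = 1.0
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    training_cohorts: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.weights.empty:
            raise ValueError("PRS model has no SNPs (threshold excluded all?)")


@dataclass(frozen=True)
class SurvivalAssoc:
    """Per-SD survival association of a polygenic score (lnPR scale)."""

    beta_per_sd: float
    se: float
    p: float
    kin: str  # "parent" | "subject"

    @property
    def years_per_sd(self) -> float:
        return float(years_from_lnpr(self.beta_per_sd))


@dataclass(frozen=True)
class DecileContrast:
    """Top-vs-bottom decile KM median survival contrast, in years."""

    median_top: float
    median_bottom: float
    contrast: float
    doubled: bool
    top_is_lower_bound: bool = False
    bottom_is_lower_bound: bool = False


def build_prs(training_stats: pd.DataFrame, p_threshold: float = 1.0,
              clump_kb: float = 250.0, clump_r2: float = 0.1,
              ld: pd.DataFrame | None = None,
              training_cohorts=frozenset()) -> PRSModel:
    """Clump-and-threshold weight construction from training summary stats.

    SNPs are LD/distance-clumped (greedy, best lifespan p kept) and then
    filtered to p <= p_threshold.  Scores built from all independent
    markers (p <= 1) are the default, reflecting that the densest score
    is the most informative for lifespan.
    """
    needed = {"snpid", "chrom", "pos", "a1", "beta1", "p"}
    missing = needed - set(training_stats.columns)
    if missing:
        raise ValueError(f"training stats missing columns: {missing}")
    clumped = prune_loci(training_stats, distance_kb=clump_kb,
                         r2_max=clump_r2, ld=ld)
    kept = clumped[clumped["p"] <= p_threshold]
    if kept.empty:
        raise ValueError("p-value threshold excluded every clumped SNP")
    weights = kept.set_index("snpid")[["a1", "beta1"]].rename(
        columns={"beta1": "beta"})
    return PRSModel(weights=weights, p_threshold=p_threshold,
                    clump_r2=clump_r2, clump_kb=clump_kb,
                    training_cohorts=frozenset(training_cohorts))


def _guard_leakage(model: PRSModel, cohort_id: str) -> None:
    if cohort_id in model.training_cohorts:
        raise ValueError(
            f"cohort {cohort_id!r} was part of PRS training; scoring it would leak")


def score_cohort(model: PRSModel, cohort, standardise: bool = True) -> np.ndarray:
    """Sum of dosage x weight over model SNPs, Z-standardised on the sample."""
    _guard_leakage(model, cohort.cohort_id)
    idx = {s: j for j, s in enumerate(cohort.snp_ids)}
    cols, betas = [], []
    for sid, row in model.weights.iterrows():
        if sid in idx:
            cols.append(idx[sid])
            betas.append(row["beta"])
    if not cols:
        raise ValueError("no model SNPs present in the cohort")
    raw = cohort.dosages[:, cols] @ np.asarray(betas, dtype=float)
    if not standardise:
        return raw
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("score has zero variance in the scoring sample")
    return (raw - raw.mean()) / sd


def _cox_score_assoc(score: np.ndarray, ages, dead, covariates=None,
                     kin: str = "parent") -> SurvivalAssoc:
    df = pd.DataFrame({"score": score,
                       "age": np.asarray(ages, dtype=float),
                       "dead": np.asarray(dead, dtype=bool).astype(int)})
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for k in range(C.shape[1]):
            df[f"z{k}"] = C[:, k]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="age", event_col="dead")
    mult = 2.0 if kin == "parent" else 1.0
    beta = -mult * float(cph.params_["score"])
    se = mult * float(cph.standard_errors_["score"])
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return SurvivalAssoc(beta_per_sd=beta, se=se, p=p, kin=kin)


def score_and_associate(model: PRSModel, cohort, kin: str = "parent",
                        parent_sex: str | None = None) -> SurvivalAssoc:
    """Score a test cohort and fit survival on the standardised score.

    ``kin="parent"`` fits the indicated parent's survival (both parents
    stacked when ``parent_sex`` is None) and doubles the coefficient;
    ``kin="subject"`` expects ``subject_age``/``subject_dead`` columns
    and applies no doubling.
    """
    score = score_cohort(model, cohort)
    cov = cohort.covariates() if cohort.covariate_cols else None
    if kin == "subject":
        sub = cohort.subjects
        if "subject_age" not in sub.columns:
            raise ValueError("cohort has no subject survival columns")
        return _cox_score_assoc(score, sub["subject_age"], sub["subject_dead"],
                                cov, kin="subject")
    if kin != "parent":
        raise ValueError("kin must be parent|subject")
    sexes = [parent_sex] if parent_sex else ["father", "mother"]
    ages, deads, scores, covs = [], [], [], []
    for s in sexes:
        rec = cohort.parent(s)
        ages.append(rec["age"].to_numpy())
        deads.append(rec["dead"].to_numpy())
        scores.append(score)
        if cov is not None:
            covs.append(cov)
    return _cox_score_assoc(np.concatenate(scores), np.concatenate(ages),
                            np.concatenate(deads),
                            np.vstack(covs) if covs else None, kin="parent")


def _km_median(ages, dead) -> tuple[float, bool]:
    km = KaplanMeierFitter()
    km.fit(ages, event_observed=dead)
    med = km.median_survival_time_
    if np.isinf(med):
        # survival plateaus above 0.5: report the censoring-time lower bound
        return float(np.max(ages)), True
    return float(med), False


def decile_contrast(score: np.ndarray, ages, dead,
                    doubled: bool = True) -> DecileContrast:
    """KM median survival difference between top and bottom score deciles.

    Deciles come from sample quantiles of the score with stable
    tie-breaking (ties resolved by original order rank).  The parent-based
    contrast is doubled to the carrier scale when ``doubled`` is set.
    """
    score = np.asarray(score, dtype=float)
    ages = np.asarray(ages, dtype=float)
    dead = np.asarray(dead, dtype=bool)
    n = score.size
    order = np.argsort(score, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    decile = np.minimum((ranks * 10) // n, 9)
    top, bottom = decile == 9, decile == 0
    med_top, top_lb = _km_median(ages[top], dead[top])
    med_bot, bot_lb = _km_median(ages[bottom], dead[bottom])
    contrast = (med_top - med_bot) * (2.0 if doubled else 1.0)
    return DecileContrast(median_top=med_top, median_bottom=med_bot,
                          contrast=contrast, doubled=doubled,
                          top_is_lower_bound=top_lb,
                          bottom_is_lower_bound=bot_lb)


def decile_contrast_by_sex(model_or_score, cohort, doubled: bool = True) -> dict:
    """Decile contrasts for fathers and mothers separately."""
    score = (model_or_score if isinstance(model_or_score, np.ndarray)
             else score_cohort(model_or_score, cohort))
    out = {}
    for sex in ("father", "mother"):
        rec = cohort.parent(sex)
        out[sex] = decile_contrast(score, rec["age"], rec["dead"], doubled=doubled)
    return out


def disease_associations(score: np.ndarray, disease_by_kin: dict[str, pd.DataFrame],
                         covariates=None,
                         kin_correlations: dict[str, float] | None = None,
                         first_degree: set[str] = frozenset({"father", "mother", "sibling"}),
                         se_adjustment: str = "sqrt") -> pd.DataFrame:
    """Protective logistic associations of the score with disease, by kin.

    For each kin and disease column, fits a logistic regression of *not*
    carrying the disease on the standardised score (positive beta =
    protective).  First-degree-relative estimates are doubled for
    genotype imputation.  Kin estimates per disease are IVW-meta-analysed
    with SEs inflated by sqrt(1 + r) per correlated kin (``"linear"``
    selects the more conservative (1 + r) multiplier), then BH-corrected
    across diseases.
    """
    if se_adjustment not in ("sqrt", "linear"):
        raise ValueError("se_adjustment must be sqrt|linear")
    kin_correlations = kin_correlations or {}
    Xbase = [np.ones_like(score), score]
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Xbase += [C[:, k] for k in range(C.shape[1])]
    X = np.column_stack(Xbase)

    per_kin_rows = []
    for kin, dis in disease_by_kin.items():
        dbl = 2.0 if kin in first_degree else 1.0
        r = float(kin_correlations.get(kin, 0.0))
        infl = np.sqrt(1.0 + r) if se_adjustment == "sqrt" else (1.0 + r)
        for col in dis.columns:
            y = 1.0 - dis[col].to_numpy(dtype=float)  # success = no disease
            fit = sm.Logit(y, X).fit(disp=0)
            per_kin_rows.append({
                "disease": col, "kin": kin,
                "beta": dbl * fit.params[1],
                "se": dbl * infl * fit.bse[1],
            })
    per_kin = pd.DataFrame(per_kin_rows)

    metas = []
    for disease, grp in per_kin.groupby("disease", sort=True):
        w = 1.0 / grp["se"] ** 2
        beta = float((w * grp["beta"]).sum() / w.sum())
        se = float(np.sqrt(1.0 / w.sum()))
        metas.append({"disease": disease, "beta": beta, "se": se,
                      "p": 2.0 * stats.norm.sf(abs(beta / se))})
    out = pd.DataFrame(metas)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
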