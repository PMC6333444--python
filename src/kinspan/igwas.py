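"""Bayesian risk-factor-informed GWAS (iGWAS).

Observed per-SNP lifespan Z statistics are combined with a prior built
from the SNP's effects on mortality risk factors, weighted by the
factors' multivariate Mendelian-randomisation causal effects on lifespan.
The prior for SNP j is normal with

    mu_j     = sum_k theta_k * b_jk
    sigma²_j = (first-order propagated variance of mu_j) + 1

where theta_k is factor k's causal effect on (standardised) lifespan and
b_jk the SNP's effect on factor k.  The extra ``+ 1`` accounts for prior
effects being estimated from *observed* Z statistics, which carry unit
sampling noise around the true Z.

Evidence per SNP is the normal-normal marginal likelihood ratio (Bayes
factor) of the informed model against the standard-normal null;
significance is assessed empirically by permuting the observed Z vector
against the fixed prior vector and pooling the null Bayes factors, with
Benjamini-Hochberg correction across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CausalEstimates",
    "PriorSpec",
    "BayesResult",
    "fit_multivariate_mr",
    "build_priors",
    "bayes_factor",
    "permutation_pvalues",
]


@dataclass
class CausalEstimates:
    """Per-factor causal effects on standardised lifespan.

    ``table`` is indexed by factor id with columns
    ``effect, se, p, selected``; only selected factors enter the prior.
    """

    table: pd.DataFrame

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]


@dataclass
class PriorSpec:
    """Per-SNP prior mean and variance on the Z scale.

    ``sigma2`` already includes the unit observation-noise term, so it is
    the marginal variance of an observed Z under the informed model.
    ``incomplete`` flags SNPs missing one or more factor effects (those
    contributions are treated as zero with their variance term dropped).
    """

    mu: pd.Series
    sigma2: pd.Series
    incomplete: pd.Series
    contributions: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.sigma2 < 0).any():
            raise ValueError("prior variance must be non-negative")
        if not np.isfinite(self.mu).all():
            raise ValueError("prior means must be finite")


@dataclass
class BayesResult:
    """Per-SNP iGWAS output: logBF, empirical p, BH q, floor flag."""

    table: pd.DataFrame
    min_p: float


def _check_collinearity(X: pd.DataFrame) -> None:
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # QR diagonal identifies which columns add no rank
        _, rmat = np.linalg.qr(Xv)
        diag = np.abs(np.diag(rmat))
        bad = [X.columns[i] for i in range(len(diag))
               if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient factor matrix; collinear factors: {bad or list(X.columns)}")


def _wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    model = sm.WLS(y, X, weights=w)
    return model.fit()


def fit_multivariate_mr(factor_betas: pd.DataFrame, lifespan_beta: pd.Series,
                        lifespan_se: pd.Series | None = None,
                        snp_chrom: pd.Series | None = None,
                        mask_chrom=None,
                        select: bool = True,
                        p_enter_aic: bool = True) -> CausalEstimates:
    """Multivariate MR of lifespan effects on the factor-effect matrix.

    Weighted least squares (weights 1/se² of the lifespan effects, or
    unweighted when SEs are absent) of per-SNP lifespan effects on the
    per-SNP factor effects, over instrument SNPs not on the masked
    chromosome.  No intercept: a SNP with no factor effects is assumed to
    have no lifespan effect through the factors.  Factor selection is
    bidirectional stepwise by AIC; unselected factors keep their
    full-model estimates but are flagged unselected.
    """
    X_all = factor_betas.copy()
    y = lifespan_beta.reindex(X_all.index)
    keep = y.notna()
    if snp_chrom is not None and mask_chrom is not None:
        keep &= snp_chrom.reindex(X_all.index) != mask_chrom
    X_all, y = X_all.loc[keep], y.loc[keep]
    if len(X_all) < X_all.shape[1] + 1:
        raise ValueError("need more instrument SNPs than factors")
    _check_collinearity(X_all)
    w = np.ones(len(y)) if lifespan_se is None else \
        1.0 / lifespan_se.reindex(y.index).to_numpy() ** 2

    factors = list(X_all.columns)

    def aic_of(cols: list[str]) -> float:
        # one consistent Gaussian AIC (n log(RSS_w/n) + 2k) across all
        # candidate sets, including the empty model
        n = len(y)
        yv = y.to_numpy()
        if not cols:
            rss = float(np.sum(w * yv ** 2))
            k = 0
        else:
            res = _wls_fit(X_all[cols].to_numpy(), yv, w)
            rss = float(np.sum(w * res.resid ** 2))
            k = len(cols)
        return n * np.log(max(rss, 1e-300) / n) + 2 * k

    if select:
        current: list[str] = []
        current_aic = aic_of(current)
        improved = True
        while improved:
            improved = False
            candidates = []
            for f in factors:
                trial = current + [f] if f not in current else \
                    [c for c in current if c != f]
                if not trial and f in current and len(current) == 1:
                    trial = []
                candidates.append((aic_of(trial), trial))
            best_aic, best_set = min(candidates, key=lambda t: t[0])
            if best_aic < current_aic - 1e-9:
                current, current_aic = best_set, best_aic
                improved = True
        chosen = current if current else factors  # degenerate: keep all
    else:
        chosen = factors

    full = _wls_fit(X_all[factors].to_numpy(), y.to_numpy(), w)
    if chosen != factors:
        sel_res = _wls_fit(X_all[chosen].to_numpy(), y.to_numpy(), w)
    else:
        sel_res = full

    table = pd.DataFrame(index=pd.Index(factors, name="factor"),
                         columns=["effect", "se", "p", "selected"], dtype=object)
    for i, f in enumerate(factors):
        table.loc[f, "selected"] = f in chosen
        if f in chosen:
            j = chosen.index(f)
            table.loc[f, ["effect", "se", "p"]] = (
                sel_res.params[j], sel_res.bse[j], sel_res.pvalues[j])
        else:
            j = factors.index(f)
            table.loc[f, ["effect", "se", "p"]] = (
                full.params[j], full.bse[j], full.pvalues[j])
    for c in ("effect", "se", "p"):
        table[c] = table[c].astype(float)
    table["selected"] = table["selected"].astype(bool)
    return CausalEstimates(table=table)


def build_priors(causal: CausalEstimates, factor_betas: pd.DataFrame,
                 factor_ses: pd.DataFrame | None = None) -> PriorSpec:
    """Assemble per-SNP normal priors from causal estimates and factor effects.

    mu = sum_k theta_k b_k over selected factors; the variance is the
    first-order (delta-method) propagation
    sum_k (theta_k² se_bk² + b_k² se_thetak²), plus one for the
    observation noise of the Z statistics the prior will be compared to.
    Missing factor effects contribute zero with their variance term
    dropped, and the SNP is flagged incomplete.
    """
    sel = causal.selected
    theta = sel["effect"]
    theta_se = sel["se"]
    cols = [f for f in theta.index if f in factor_betas.columns]
    if len(cols) < len(theta.index):
        missing = set(theta.index) - set(cols)
        raise ValueError(f"factor effect tables missing selected factors: {missing}")

    B = factor_betas[cols]
    if factor_ses is None:
        S = pd.DataFrame(0.0, index=B.index, columns=cols)
    else:
        S = factor_ses[cols].reindex(B.index)

    incomplete = B.isna().any(axis=1)
    Bf = B.fillna(0.0)
    Sf = S.where(B.notna(), 0.0).fillna(0.0)

    th = theta[cols].to_numpy()
    th_se = theta_se[cols].to_numpy()
    mu = Bf.to_numpy() @ th
    var = (th ** 2 * Sf.to_numpy() ** 2).sum(axis=1) \
        + (Bf.to_numpy() ** 2 * th_se ** 2).sum(axis=1)
    contributions = Bf * th

    return PriorSpec(mu=pd.Series(mu, index=B.index),
                     sigma2=pd.Series(var + 1.0, index=B.index),
                     incomplete=incomplete,
                     contributions=contributions)


def bayes_factor(z, prior_mu, prior_sigma2):
    """Normal-normal log Bayes factor of the informed model vs the null.

    logBF = log N(z; mu, sigma²) - log N(z; 0, 1), where sigma² is the
    *marginal* variance of an observed Z under the prior (i.e. it already
    includes the unit observation noise; a null prior mu = 0, sigma² = 1
    gives logBF = 0 for every z).
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(prior_mu, dtype=float)
    s2 = np.asarray(prior_sigma2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("marginal prior variance must be positive")
    return (stats.norm.logpdf(z, loc=mu, scale=np.sqrt(s2))
            - stats.norm.logpdf(z, loc=0.0, scale=1.0))


def permutation_pvalues(z_obs, prior: PriorSpec, n_permutations: int = 1000,
                        seed=None, rng: np.random.Generator | None = None) -> BayesResult:
    """Empirical Bayes-factor p-values by permuting Z against fixed priors.

    Each permutation randomly reassigns the observed Z vector across SNPs
    (breaking the Z-prior pairing while preserving both marginals); the
    null log Bayes factors from all permutations and SNPs are pooled, and
    each observed SNP gets p = (1 + #{null >= observed}) / (1 + N_null).
    The attainable floor 1/(1 + N_null) is reported and SNPs at the floor
    flagged.  BH q-values are computed across SNPs.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = rng if rng is not None else np.random.default_rng(seed)
    z = np.asarray(z_obs, dtype=float)
    mu = prior.mu.to_numpy()
    s2 = prior.sigma2.to_numpy()
    if z.size != mu.size:
        raise ValueError("z vector not aligned to priors")

    obs = bayes_factor(z, mu, s2)
    counts = np.zeros(z.size, dtype=np.int64)
    n_null = 0
    for _ in range(n_permutations):
        null = bayes_factor(rng.permutation(z), mu, s2)
        null.sort()
        counts += null.size - np.searchsorted(null, obs, side="left")
        n_null += null.size

    p = (1.0 + counts) / (1.0 + n_null)
    q = multipletests(p, method="fdr_bh")[1]
    min_p = 1.0 / (1.0 + n_null)
    table = pd.DataFrame({
        "snpid": prior.mu.index, "z": z, "prior_mean": mu,
        "prior_se": np.sqrt(s2), "logBF": obs,
        "p_bf": p, "q": q, "at_floor": counts == 0,
    })
    return BayesResult(table=table, min_p=min_p)
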