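"""Collective replication machinery for lifespan loci.

External longevity studies partially overlap in samples; their pooled
estimates need overlap-aware variances.  Given discovery and replication
effects on a common scale, per-SNP effect-size ratios ("alpha") and their
inverse-variance meta-analysis provide a collective replication test:
pooled alpha > 0 means discovery hits carry signal in replication, and
alpha < 1 means effects are attenuated relative to the calibration locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlphaEstimate",
    "OverlapSpec",
    "estimate_null_overlap",
    "meta_overlap_adjusted",
    "alpha_ratio",
    "meta_alpha",
]


@dataclass(frozen=True)
class AlphaEstimate:
    """Replication/discovery effect-size ratio for one SNP."""

    snpid: str
    alpha: float
    se_alpha: float
    one_sided_p: float

    def __post_init__(self) -> None:
        if self.se_alpha <= 0:
            raise ValueError("se_alpha must be > 0")


@dataclass
class OverlapSpec:
    """Pairwise null-SNP covariance of effect estimates across studies.

    ``cov`` is the (n_studies, n_studies) matrix of Cov(beta_n, beta_m)
    among null SNPs; the diagonal is ignored (per-study variances come
    from each SNP's own SE).
    """

    cov: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        off = c - np.diag(np.diag(c))
        if not np.allclose(off, off.T):
            raise ValueError("covariance matrix must be symmetric")
        self.cov = c


def estimate_null_overlap(study_a: pd.DataFrame, study_b: pd.DataFrame,
                          z_max: float = 1.0, min_null: int = 100) -> float:
    """Correlation of Z among SNPs null (|Z| < z_max) in both studies.

    Sample overlap between two GWAS induces correlation in their effect
    estimates; among SNPs with no true effect that correlation is visible
    directly, so the Pearson correlation of null-SNP Z statistics
    estimates it.
    """
    def z_of(df: pd.DataFrame) -> pd.Series:
        if "z" in df.columns:
            return df.set_index("snpid")["z"]
        return df.set_index("snpid").eval("beta1 / se")

    za, zb = z_of(study_a), z_of(study_b)
    m = pd.concat([za, zb], axis=1, join="inner", keys=["a", "b"]).dropna()
    null = m[(m["a"].abs() < z_max) & (m["b"].abs() < z_max)]
    if len(null) < min_null:
        raise ValueError(
            f"only {len(null)} shared null SNPs (< {min_null}); cannot estimate overlap")
    return float(np.corrcoef(null["a"], null["b"])[0, 1])


def meta_overlap_adjusted(betas, ses, overlap: OverlapSpec):
    """IVW meta-analysis with sample-overlap variance inflation.

    Var(pooled) = Var0 + 2 * sum_{n<m} w_n w_m Cov(beta_n, beta_m), where
    the w are the normalised inverse-variance weight fractions.  With all
    covariances zero this is plain IVW; with cov = var (a duplicated
    study) the pooled SE returns to the single-study SE.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be equal-length vectors")
    if overlap.cov.shape[0] != b.size:
        raise ValueError("overlap covariance does not match number of studies")
    prec = 1.0 / s ** 2
    w = prec / prec.sum()
    pooled = float(np.sum(w * b))
    var0 = 1.0 / prec.sum()
    cov_term = 0.0
    for i in range(b.size):
        for j in range(i + 1, b.size):
            cov_term += w[i] * w[j] * overlap.cov[i, j]
    var = var0 + 2.0 * cov_term
    return pooled, float(np.sqrt(var))


def alpha_ratio(beta_disc: float, se_disc: float, beta_rep: float,
                se_rep: float, snpid: str = "") -> AlphaEstimate:
    """Replication-to-discovery effect ratio with delta-method SE.

    alpha = beta_rep / beta_disc;
    SE_alpha = sqrt(SE_rep²/beta_disc² + beta_rep² SE_disc²/beta_disc⁴)
    (first-order Taylor expansion of the denominator; biased when
    |beta_disc|/SE_disc is small).  The one-sided p tests H0: alpha = 0
    against the alternative that the replication effect shares the
    discovery sign, symmetrically for protective or deleterious discovery
    alleles: p = Phi(-alpha_hat / SE_alpha).
    """
    if beta_disc == 0:
        raise ValueError("beta_disc must be nonzero")
    if se_disc < 0 or se_rep <= 0:
        raise ValueError("standard errors must be positive")
    alpha = beta_rep / beta_disc
    se_alpha = float(np.sqrt(se_rep ** 2 / beta_disc ** 2
                             + beta_rep ** 2 * se_disc ** 2 / beta_disc ** 4))
    one_sided_p = float(stats.norm.sf(alpha / se_alpha))
    return AlphaEstimate(snpid=snpid, alpha=alpha, se_alpha=se_alpha,
                         one_sided_p=one_sided_p)


def meta_alpha(estimates: list[AlphaEstimate], exclude: set[str] = frozenset()):
    """IVW pooled alpha across SNPs, Wald 95% CI, two-sided p (H0: alpha=0)."""
    kept = [e for e in estimates if e.snpid not in exclude]
    if not kept:
        raise ValueError("no alpha estimates left after exclusion")
    a = np.array([e.alpha for e in kept])
    w = np.array([1.0 / e.se_alpha ** 2 for e in kept])
    pooled = float(np.sum(w * a) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    ci = (pooled - 1.959963984540054 * se, pooled + 1.959963984540054 * se)
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    return pooled, se, ci, p
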