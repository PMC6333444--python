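"""Shared simulation scenarios used by both module and acceptance tests."""

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kinspan import igwas


def simulate_informed_scan(seed, n=1000, n_causal=100, scale=4.0,
                           n_perm=100, factor_noise=0.1):
    """One paired informed-vs-plain GWAS replicate.

    Sparse architecture: ``n_causal`` of ``n`` SNPs carry effects acting
    purely through three modelled risk factors (causal vector
    0.4/-0.3/0.2, true-Z scale ``scale``); factor GWAS tables observed
    with noise SE ``factor_noise``.  Returns (informed detections, plain
    detections) at Benjamini-Hochberg FDR 5%.
    """
    rng = np.random.default_rng(seed)
    theta = np.array([0.4, -0.3, 0.2])
    B = np.zeros((n, 3))
    B[:n_causal] = rng.normal(size=(n_causal, 3))
    z_true = scale * (B @ theta)
    z_obs = z_true + rng.normal(size=n)
    ids = [f"s{i}" for i in range(n)]
    cols = ["factor_1", "factor_2", "factor_3"]
    X = pd.DataFrame(B + rng.normal(0, factor_noise, B.shape),
                     index=ids, columns=cols)
    S = pd.DataFrame(factor_noise, index=ids, columns=cols)
    y = pd.Series(z_true + rng.normal(0, 1.0, n), index=ids)
    est = igwas.fit_multivariate_mr(X, y, select=False)
    prior = igwas.build_priors(est, X, S)
    res = igwas.permutation_pvalues(z_obs, prior, n_permutations=n_perm, rng=rng)
    p_plain = 2 * stats.norm.sf(np.abs(z_obs))
    plain = int(multipletests(p_plain, alpha=0.05, method="fdr_bh")[0].sum())
    informed = int((res.table["q"] <= 0.05).sum())
    return informed, plain
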