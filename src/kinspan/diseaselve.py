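"""Disease attribution for lifespan variants.

Given a panel of disease-associated SNPs with lifespan effects, this
module prunes them to independent loci, computes the lifespan variance
each explains (LVE = 2pqa², in years² for a per-allele effect of a
years), applies the one-false-positive FDR rule, classifies pleiotropy
(secondary when another disease's |Z| is at least double the nominal
disease's; antagonistic when a variant raises both disease risk and
lifespan), and totals LVE per disease category.  A Fisher exact-test
harness serves enrichment questions such as whether lifespan SNPs are
over-represented among age-related eQTLs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DISEASE_CATEGORIES",
    "DiseaseSnp",
    "EnrichmentTable",
    "prune_loci",
    "lifespan_variance_explained",
    "fdr_one_false_positive",
    "classify_pleiotropy",
    "sum_lve_by_category",
    "cumulative_lve",
    "fisher_enrichment",
]

DISEASE_CATEGORIES = ("CVD", "neurological", "diabetes",
                      "smoking/lung cancer", "other cancers")


@dataclass
class DiseaseSnp:
    """A disease-catalog SNP scored against lifespan.

    ``a1`` is the disease-protective allele; ``beta_years`` its lifespan
    effect in years (positive = longer life); ``z_by_category`` maps each
    disease category to the signed association Z of the a1 allele with
    that category (positive = protective against the disease).
    """

    snpid: str
    chrom: int
    pos: int
    disease_category: str
    a1: str
    beta_years: float
    freq1: float
    z_by_category: dict[str, float] = field(default_factory=dict)
    p_lifespan: float = 1.0
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.freq1 < 1:
            raise ValueError("freq1 must be in (0, 1)")
        if self.disease_category not in DISEASE_CATEGORIES:
            raise ValueError(f"unknown disease category {self.disease_category!r}")

    @property
    def lve(self) -> float:
        """Signed LVE: magnitude 2pqa², sign of the lifespan effect."""
        mag = lifespan_variance_explained(self.freq1, self.beta_years)
        return float(np.copysign(mag, self.beta_years)) if self.beta_years else 0.0


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 enrichment result: counts, conditional odds ratio, exact p."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float


def prune_loci(table: pd.DataFrame, distance_kb: float = 500.0,
               r2_max: float = 0.1, ld: pd.DataFrame | None = None) -> pd.DataFrame:
    """Greedy pruning to independent loci by ascending p-value.

    Candidates are visited from the smallest lifespan p upward (ties
    broken by chromosome then position); one is rejected if it lies
    within ``distance_kb`` of an already-kept SNP on the same chromosome,
    or if its LD r² with any kept SNP reaches ``r2_max`` (when an LD
    matrix, indexed by snpid both ways, is supplied).  Without an LD
    matrix the pruning is distance-only.

    ``table`` needs columns snpid, chrom, pos, p.
    """
    for c in ("snpid", "chrom", "pos", "p"):
        if c not in table.columns:
            raise ValueError(f"prune_loci table missing column {c!r}")
    if table["pos"].isna().any():
        raise ValueError("missing positions")
    order = table.sort_values(["p", "chrom", "pos"], kind="mergesort")
    kept_idx: list[int] = []
    kept_chrom: list = []
    kept_pos: list[float] = []
    kept_ids: list[str] = []
    dist = distance_kb * 1000.0
    for idx, row in order.iterrows():
        ok = True
        for c, x in zip(kept_chrom, kept_pos):
            if c == row["chrom"] and abs(row["pos"] - x) < dist:
                ok = False
                break
        if ok and ld is not None:
            for kid in kept_ids:
                if kid in ld.index and row["snpid"] in ld.columns:
                    if ld.loc[kid, row["snpid"]] ** 2 >= r2_max:
                        ok = False
                        break
        if ok:
            kept_idx.append(idx)
            kept_chrom.append(row["chrom"])
            kept_pos.append(row["pos"])
            kept_ids.append(row["snpid"])
    return table.loc[kept_idx].sort_values(["chrom", "pos"])


def lifespan_variance_explained(freq1: float, beta_years: float) -> float:
    """LVE = 2 p q a² in years² for a biallelic additive variant."""
    if not 0 < freq1 < 1:
        raise ValueError("freq1 must be in (0, 1)")
    return 2.0 * freq1 * (1.0 - freq1) * beta_years ** 2


def fdr_one_false_positive(pvalues) -> tuple[np.ndarray, float, np.ndarray]:
    """BH q-values with the one-false-positive threshold q <= 1/n.

    At q <= 1/n the expected number of false discoveries among n tests is
    at most one.  Returns (q_values, display_threshold, significant_mask);
    selection uses the exact 1/n, the display threshold is 1/n truncated
    to three decimals (the printed convention).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    q = multipletests(p, method="fdr_bh")[1]
    thr = 1.0 / p.size
    display = np.floor(thr * 1000.0) / 1000.0
    return q, float(display), q <= thr


def classify_pleiotropy(snp: DiseaseSnp, z_significant: float = 1.959963984540054,
                        double_factor: float = 2.0) -> dict[str, bool]:
    """Apply the double-Z secondary rule and the antagonistic rule.

    * ``secondary_pleiotropic``: some other disease category's |Z| is at
      least ``double_factor`` times the nominal category's |Z|, with the
      same (protective) direction — the variant's disease attribution
      belongs elsewhere.
    * ``antagonistic``: an allele increasing disease also increases
      lifespan.  In the protective-allele coding this surfaces as the
      nominally disease-protective allele *shortening* life
      (sign(beta_years) opposite to sign(z_primary)) while a significant
      opposite-direction association with another disease accounts for
      the lifespan cost.
    """
    zs = snp.z_by_category
    if snp.disease_category not in zs or len(zs) < 2:
        raise ValueError("z_by_category must cover the nominal and >= 1 other category")
    z_primary = zs[snp.disease_category]
    secondary = False
    opposite_significant = False
    for cat, z in zs.items():
        if cat == snp.disease_category:
            continue
        if abs(z) >= double_factor * abs(z_primary) and np.sign(z) == np.sign(z_primary):
            secondary = True
        if abs(z) >= z_significant and np.sign(z) == -np.sign(z_primary):
            opposite_significant = True
    antagonistic = bool(
        opposite_significant
        and snp.beta_years != 0
        and np.sign(snp.beta_years) == -np.sign(z_primary))
    flags = {"secondary_pleiotropic": secondary, "antagonistic": antagonistic}
    snp.flags.update(flags)
    return flags


def sum_lve_by_category(snps: list[DiseaseSnp]) -> pd.Series:
    """Total LVE per disease category over significant, non-secondary SNPs.

    Requires ``flags['significant']`` and ``flags['secondary_pleiotropic']``
    to have been set.
    """
    totals = {c: 0.0 for c in DISEASE_CATEGORIES}
    for s in snps:
        if s.flags.get("significant") and not s.flags.get("secondary_pleiotropic"):
            totals[s.disease_category] += abs(s.lve)
    return pd.Series(totals)


def cumulative_lve(snps: list[DiseaseSnp]) -> pd.DataFrame:
    """Cumulative LVE of significant, non-secondary loci ordered by LVE."""
    kept = [s for s in snps
            if s.flags.get("significant") and not s.flags.get("secondary_pleiotropic")]
    kept.sort(key=lambda s: abs(s.lve), reverse=True)
    rows = []
    running = 0.0
    for rank, s in enumerate(kept, start=1):
        running += abs(s.lve)
        rows.append({"rank": rank, "snpid": s.snpid,
                     "category": s.disease_category,
                     "lve": abs(s.lve), "cumulative_lve": running})
    return pd.DataFrame(rows)


def fisher_enrichment(in_a, in_b) -> EnrichmentTable:
    """Fisher's exact test of membership association between two sets.

    ``in_a``/``in_b`` are boolean vectors over the same universe (e.g.
    lifespan-associated x age-related among eQTLs).  Returns the
    conditional-MLE odds ratio and the two-sided exact p.
    """
    a = np.asarray(in_a, dtype=bool)
    b = np.asarray(in_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("membership vectors must be aligned")
    counts = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                       [int((~a & b).sum()), int((~a & ~b).sum())]])
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("degenerate 2x2 table (empty margin)")
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    or_cond = _conditional_or(counts, kind="conditional").statistic
    return EnrichmentTable(counts=tuple(map(tuple, counts.tolist())),
                           odds_ratio=float(or_cond), p=float(p))
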