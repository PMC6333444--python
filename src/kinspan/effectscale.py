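"""Effect-size scale conversions for kin-cohort lifespan GWAS.

All estimates in this package live on the *carrier lnPR* scale: the negated
log hazard ratio per effect allele in the person carrying the allele
(positive = protective).  External studies report effects on a zoo of other
scales — rank-normalised Martingale residuals, longevity case-control log
odds ratios, recessive homozygote contrasts — and this module holds the
pure conversion functions between them.

Conventions
-----------
* ``c`` is the proportion of lives in a sample that are deceased.
* Kin-cohort estimates observed on offspring dosage are *half* the effect
  in the parent carrying the allele; conversions expose this doubling
  explicitly via ``to_self`` flags rather than baking it in.
* Every empirical anchor (e.g. a calibration variant's log OR and lnHR)
  must be passed in by the caller; nothing is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ScaleFactor",
    "EquivalenceInputs",
    "martingale_rescale",
    "recessive_to_additive",
    "longevity_calibration",
    "years_from_lnpr",
    "lnpr_from_years",
    "equivalent_sample_size",
    "reference_equivalent_n",
    "mean_successive_increase",
    "percent_increase",
]


@dataclass(frozen=True)
class ScaleFactor:
    """A multiplicative constant mapping one effect-size scale to another."""

    source_scale: str
    target_scale: str
    factor: float
    provenance: str = "formula"  # "formula" | "empirical"

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor == 0:
            raise ValueError("scale factor must be finite and nonzero")

    def apply(self, beta: float) -> float:
        return self.factor * beta

    @property
    def inverse(self) -> "ScaleFactor":
        return ScaleFactor(self.target_scale, self.source_scale,
                           1.0 / self.factor, self.provenance)


@dataclass(frozen=True)
class EquivalenceInputs:
    """Inputs for the equivalent-sample-size dilution calculation.

    A kin-cohort GWAS of ``n_lives`` parent lifespans has the statistical
    power of a much smaller GWAS of a fully heritable directly measured
    trait: the sample is diluted by the trait heritability, by the r² of
    offspring dosage on parent genotype, and by the proportion of parents
    already deceased.
    """

    n_lives: float
    heritability: float
    r2_kin: float
    prop_dead: float
    h2_reference_trait: float = 1.0

    def __post_init__(self) -> None:
        for name in ("heritability", "r2_kin", "prop_dead", "h2_reference_trait"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_lives <= 0:
            raise ValueError("n_lives must be positive")


def martingale_rescale(beta_reported: float, c: float, to_self: bool = False) -> float:
    """Convert a rank-normalised Martingale-residual effect size to lnHR.

    Effects estimated on rank-normalised Martingale residuals (standard
    deviation ~ sqrt(c)) are returned to the raw residual scale by
    multiplying by sqrt(c), then placed on the log-hazard-ratio scale by
    dividing by c — a net factor of 1/sqrt(c).  With ``to_self`` the
    offspring-dosage estimate is additionally doubled to the effect in the
    parent carrying the allele.

    Parameters
    ----------
    beta_reported : effect on the rank-normalised residual scale.
    c : proportion of the original sample deceased, in (0, 1].
    to_self : double the estimate from offspring-observed to carrier scale.
    """
    if not 0 < c <= 1:
        raise ValueError(f"proportion dead c must be in (0, 1], got {c}")
    factor = (2.0 if to_self else 1.0) / np.sqrt(c)
    return beta_reported * factor


def recessive_to_additive(beta_homozygote: float, q: float) -> tuple[float, float]:
    """Expected additive (carrier-scale) effect implied by a recessive one.

    A variant acting recessively with homozygote effect ``beta_homozygote``
    still produces a nonzero slope when an additive model is misspecified
    onto kin-cohort data: a subject allele is transmitted by a parent who
    is homozygous with probability q²/(q² + 2pq), so the expected
    per-subject-allele effect on the parent is half the homozygote effect
    times that probability, and doubling back to the carrier scale leaves
    ``beta_homozygote * q²/(q² + 2pq)``.

    Returns
    -------
    (expected_carrier_beta, frequency_factor) where
    frequency_factor = q²/(q² + 2pq).
    """
    if not 0 < q < 1:
        raise ValueError(f"effect-allele frequency q must be in (0, 1), got {q}")
    p = 1.0 - q
    freq_factor = q * q / (q * q + 2 * p * q)
    return beta_homozygote * freq_factor, freq_factor


def longevity_calibration(logor_anchor: float, lnhr_anchor: float) -> ScaleFactor:
    """Empirical conversion between longevity log OR and lifespan lnHR.

    Case-control longevity studies and lifetime-hazard studies measure the
    same underlying protective effects on different scales.  The ratio of
    the two observed effects at a shared, well-powered anchor variant
    calibrates the conversion empirically; magnitudes are used so that the
    two studies' opposite sign conventions cannot silently flip results.

    The returned factor maps lnHR-scale magnitudes to log-OR-scale
    magnitudes; use ``.inverse`` for the OR -> HR direction.
    """
    if logor_anchor == 0 or lnhr_anchor == 0:
        raise ValueError("calibration anchors must be nonzero")
    factor = abs(logor_anchor) / abs(lnhr_anchor)
    return ScaleFactor("lnHR", "logOR", factor, provenance="empirical")


def years_from_lnpr(beta_lnpr: float | np.ndarray) -> float | np.ndarray:
    """Years of life gained per allele: 10 x log protection ratio.

    The long-standing actuarial rule of thumb that a 10% reduction in
    lifetime hazard corresponds to about one year of life.
    """
    return 10.0 * np.asarray(beta_lnpr, dtype=float)[()] if np.isscalar(beta_lnpr) \
        else 10.0 * np.asarray(beta_lnpr, dtype=float)


def lnpr_from_years(years: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`years_from_lnpr`."""
    return np.asarray(years, dtype=float)[()] / 10.0 if np.isscalar(years) \
        else np.asarray(years, dtype=float) / 10.0


def equivalent_sample_size(inputs: EquivalenceInputs) -> tuple[float, float]:
    """Equivalent directly-measured-trait sample size of a kin-cohort GWAS.

    n_eff = n x h² x r²_kin x c, and the sample size of a reference trait
    (e.g. height, h² = 0.8) with the same power is n_eff / h²_reference.
    """
    n_eff = (inputs.n_lives * inputs.heritability * inputs.r2_kin
             * inputs.prop_dead)
    return n_eff, n_eff / inputs.h2_reference_trait


def reference_equivalent_n(n_eff: float, h2_reference_trait: float) -> float:
    """Reference-trait sample size with equivalent power: n_eff / h²_ref."""
    if not 0 < h2_reference_trait <= 1:
        raise ValueError("reference heritability must be in (0, 1]")
    return n_eff / h2_reference_trait


def mean_successive_increase(values: Sequence[float]) -> float:
    """Arithmetic mean percentage step increase along an ordered series.

    mean over i of 100 * (v[i+1]/v[i] - 1); used e.g. for the sensitivity
    of annuity prices to purchase age.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    return float(np.mean(100.0 * (v[1:] / v[:-1] - 1.0)))


def percent_increase(before: float, after: float) -> float:
    """Percentage increase from ``before`` to ``after``."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (after - before) / before
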