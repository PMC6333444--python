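"""Synthetic kin-cohort generator.

Generates cohorts with the statistical structure the kin-cohort lifespan
analysis assumes, so every downstream stage is testable without external
data:

* biallelic genotype dosages under Hardy-Weinberg, with offspring dosage
  built from one transmitted allele per parent (so r² between offspring
  dosage and either parent's genotype is 0.25 in expectation);
* parent death ages drawn by inverse transform from a Gompertz hazard,
  left-truncated at the entry age, with per-allele proportional hazard
  effects and a correlated Gaussian log-frailty shared between the two
  parents of a subject;
* censoring-at-interview ages tuned so that ~60% of parents are deceased
  and the father-mother residual-trait correlation is ~0.1;
* risk-factor GWAS summary-statistic tables in which SNP effects on
  lifespan act through a known causal-effect vector, for testing the
  prior-informed association stage.

All randomness flows through one :class:`numpy.random.Generator` created
from an explicit seed; the same seed yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GompertzParams",
    "SnpSpec",
    "ParentRecord",
    "CohortTable",
    "RiskFactorStats",
    "DEFAULT_GOMPERTZ",
    "DEFAULT_RHO",
    "DEFAULT_FRAILTY_SD",
    "DEFAULT_CENSOR_AGES",
    "gompertz_cumhaz",
    "conditional_gompertz_median",
    "conditional_gompertz_survival",
    "simulate_genotypes",
    "simulate_lifespans",
    "simulate_risk_factor_stats",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "write_snp_manifest",
    "read_snp_manifest",
]

MIN_MAF = 0.005
MAX_DEATH_AGE = 120.0


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz baseline mortality h0(x) = a * exp(b * x).

    Defaults (a = 2e-5/yr, b = 0.1/yr) put the modal age at death in the
    mid-80s; lives are left-truncated at ``entry_age`` because parental
    deaths before 40 are excluded from the analysis design.
    """

    a: float = 2e-5
    b: float = 0.1
    entry_age: float = 40.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.entry_age >= 0):
            raise ValueError("require a > 0, b > 0, entry_age >= 0")
        if self.a * np.exp(self.b * self.entry_age) >= 1.0:
            raise ValueError(
                "degenerate hazard: baseline exceeds 1/yr at entry age")


DEFAULT_GOMPERTZ = GompertzParams()

#: Inter-parent log-frailty correlation calibrated so that the
#: father-mother Martingale-residual-trait correlation is ~0.1 at the
#: default frailty scale (see docs/methods.md).
DEFAULT_RHO = 0.35
DEFAULT_FRAILTY_SD = 1.0
#: Age-at-last-observation (censoring) distribution: uniform bounds chosen
#: so that ~60% of parents are deceased under the default hazard.
DEFAULT_CENSOR_AGES = (70.0, 100.0)


@dataclass(frozen=True)
class SnpSpec:
    """A simulated biallelic variant.

    ``beta_carrier`` is the log protection ratio per effect allele in the
    carrier (positive = protective).  Under ``mode="recessive"`` the
    effect applies only to parents homozygous for the effect allele, and
    ``beta_carrier`` is the homozygote lnPR.
    """

    id: str
    maf: float
    beta_carrier: float = 0.0
    mode: str = "additive"
    chrom: int = 1
    pos: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.maf) or not MIN_MAF < self.maf <= 0.5:
            raise ValueError(
                f"{self.id}: maf must be finite and in ({MIN_MAF}, 0.5], got {self.maf}")
        if not np.isfinite(self.beta_carrier):
            raise ValueError(f"{self.id}: beta_carrier must be finite")
        if self.mode not in ("additive", "recessive"):
            raise ValueError(f"{self.id}: mode must be additive|recessive")


@dataclass(frozen=True)
class ParentRecord:
    """One parent's survival record: age at death or last observation."""

    sex: str  # "father" | "mother"
    age_last: float
    dead: bool

    def __post_init__(self) -> None:
        if self.sex not in ("father", "mother"):
            raise ValueError("sex must be father|mother")
        if self.dead and self.age_last <= 40:
            raise ValueError("deaths at or before age 40 are excluded upstream")
        if self.age_last > MAX_DEATH_AGE:
            raise ValueError(f"age_last must be <= {MAX_DEATH_AGE}")


@dataclass
class CohortTable:
    """A cohort: subjects with dosages, covariates and two parent records.

    ``subjects`` carries one row per subject with columns
    ``subject_id``, the covariate columns, and
    ``father_age, father_dead, mother_age, mother_dead``.
    ``dosages`` is the (n_subjects, n_snps) dosage matrix aligned to
    ``snps``.  Latent parent genotypes are retained (when simulated) so
    tests can use them as oracles; real data would not have them.
    """

    subjects: pd.DataFrame
    dosages: np.ndarray
    snps: list[SnpSpec]
    cohort_id: str = "sim"
    covariate_cols: list[str] = field(default_factory=list)
    father_genotypes: np.ndarray | None = None
    mother_genotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if self.dosages.shape != (n, len(self.snps)):
            raise ValueError("dosage matrix not aligned to subjects x snps")
        if np.any((self.dosages < 0) | (self.dosages > 2)):
            raise ValueError("dosages must lie in [0, 2]")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        if self.covariate_cols:
            X = self.subjects[self.covariate_cols].to_numpy(dtype=float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
                raise ValueError("covariate matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def covariates(self) -> np.ndarray:
        return self.subjects[self.covariate_cols].to_numpy(dtype=float)

    def parent(self, sex: str) -> pd.DataFrame:
        """Survival columns for one parent as (age, dead)."""
        if sex not in ("father", "mother"):
            raise ValueError("sex must be father|mother")
        return pd.DataFrame({
            "age": self.subjects[f"{sex}_age"].to_numpy(dtype=float),
            "dead": self.subjects[f"{sex}_dead"].to_numpy(dtype=bool),
        })


# ---------------------------------------------------------------------------
# Gompertz closed forms (used both for simulation and as test oracles)

def gompertz_cumhaz(age, gp: GompertzParams = DEFAULT_GOMPERTZ):
    """Integrated baseline hazard H(x) = (a/b) (exp(bx) - 1)."""
    age = np.asarray(age, dtype=float)
    return gp.a / gp.b * (np.exp(gp.b * age) - 1.0)


def conditional_gompertz_survival(age, gp: GompertzParams = DEFAULT_GOMPERTZ,
                                  loghr: float = 0.0):
    """S(x | survival to entry_age) for a subject with log hazard shift."""
    dh = gompertz_cumhaz(age, gp) - gompertz_cumhaz(gp.entry_age, gp)
    return np.exp(-dh * np.exp(loghr))


def conditional_gompertz_median(gp: GompertzParams = DEFAULT_GOMPERTZ,
                                loghr: float = 0.0) -> float:
    """Median death age conditional on surviving to entry_age."""
    target = gompertz_cumhaz(gp.entry_age, gp) + np.log(2.0) / np.exp(loghr)
    return float(np.log(1.0 + gp.b / gp.a * target) / gp.b)


def _invert_gompertz(u: np.ndarray, gp: GompertzParams, eta: np.ndarray) -> np.ndarray:
    """Death ages from uniforms by inverse transform, conditional on entry."""
    # H(T) = H(entry) + E / exp(eta),  E ~ Exp(1) = -log(u)
    target = gompertz_cumhaz(gp.entry_age, gp) - np.log(u) / np.exp(eta)
    return np.log(1.0 + gp.b / gp.a * target) / gp.b


# ---------------------------------------------------------------------------
# Generators

def _validate_snps(snps: Sequence[SnpSpec]) -> None:
    ids = [s.id for s in snps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate SNP ids")


def simulate_genotypes(n_subjects: int, snps: Sequence[SnpSpec], seed=None,
                       rng: np.random.Generator | None = None):
    """Draw parent genotypes (Hardy-Weinberg) and transmitted offspring dosages.

    Each parent genotype is Binomial(2, maf); the offspring receives one
    allele from each parent, drawn Bernoulli(g/2).  This transmission
    model makes the squared correlation between offspring dosage and
    either parent's genotype 0.25 in expectation, the dilution factor of
    the kin-cohort design.

    Returns
    -------
    dosages : (n_subjects, n_snps) float array in {0, 1, 2}
    father_genotypes, mother_genotypes : int arrays of the same shape
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    _validate_snps(snps)
    rng = rng if rng is not None else np.random.default_rng(seed)
    mafs = np.array([s.maf for s in snps])
    shape = (n_subjects, len(snps))
    gf = rng.binomial(2, mafs, size=shape)
    gm = rng.binomial(2, mafs, size=shape)
    transmitted_f = rng.random(shape) < gf / 2.0
    transmitted_m = rng.random(shape) < gm / 2.0
    dosages = (transmitted_f.astype(float) + transmitted_m.astype(float))
    return dosages, gf, gm


def _genetic_loghr(genotypes: np.ndarray, snps: Sequence[SnpSpec]) -> np.ndarray:
    """Per-parent log hazard shift from their own genotypes.

    A protective allele (beta_carrier > 0, lnPR) lowers the carrier's
    hazard, so it contributes -beta_carrier per allele (or per homozygote
    under the recessive mode).  Contributions are centred at the
    population-mean exposure (2*maf additive, maf² recessive) so the
    aggregate polygenic load is absorbed into the baseline hazard and the
    population-level survival stays at its calibrated shape regardless of
    how many effect SNPs are simulated.
    """
    eta = np.zeros(genotypes.shape[0])
    for j, s in enumerate(snps):
        if s.beta_carrier == 0.0:
            continue
        g = genotypes[:, j]
        if s.mode == "recessive":
            exposure = (g == 2).astype(float) - s.maf ** 2
        else:
            exposure = g.astype(float) - 2.0 * s.maf
        eta -= s.beta_carrier * exposure
    return eta


def simulate_lifespans(father_genotypes: np.ndarray, mother_genotypes: np.ndarray,
                       snps: Sequence[SnpSpec],
                       gp: GompertzParams = DEFAULT_GOMPERTZ,
                       rho: float = DEFAULT_RHO,
                       frailty_sd: float = DEFAULT_FRAILTY_SD,
                       censor_age_dist: tuple[float, float] | Callable = DEFAULT_CENSOR_AGES,
                       seed=None, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw father and mother survival records for each subject.

    Death ages come from inverse-transform sampling of the Gompertz
    survival function conditional on survival to ``gp.entry_age``.  Each
    parent's log hazard is shifted by their own genotype effects and by a
    Gaussian log-frailty; the father and mother frailties of one subject
    are correlated (``rho``), which induces the father-mother residual
    trait correlation the analysis must handle.  A parent still alive at
    their drawn censoring age is recorded alive at that age.

    ``censor_age_dist`` is either a ``(lo, hi)`` uniform bound pair or a
    callable ``f(n, rng) -> ages``.
    """
    if not 0.0 <= rho <= 0.5:
        raise ValueError(f"rho must be in [0, 0.5], got {rho}")
    if frailty_sd < 0:
        raise ValueError("frailty_sd must be >= 0")
    _validate_snps(snps)
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = father_genotypes.shape[0]

    # shared + individual decomposition gives Corr(g_f, g_m) = rho with
    # total variance frailty_sd^2
    shared = rng.normal(0.0, 1.0, n)
    eps_f = rng.normal(0.0, 1.0, n)
    eps_m = rng.normal(0.0, 1.0, n)
    g_f = frailty_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps_f)
    g_m = frailty_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps_m)

    eta_f = _genetic_loghr(father_genotypes, snps) + g_f
    eta_m = _genetic_loghr(mother_genotypes, snps) + g_m

    t_f = _invert_gompertz(rng.random(n), gp, eta_f)
    t_m = _invert_gompertz(rng.random(n), gp, eta_m)

    if callable(censor_age_dist):
        c_f = np.asarray(censor_age_dist(n, rng), dtype=float)
        c_m = np.asarray(censor_age_dist(n, rng), dtype=float)
    else:
        lo, hi = censor_age_dist
        c_f = rng.uniform(lo, hi, n)
        c_m = rng.uniform(lo, hi, n)

    dead_f = t_f <= c_f
    dead_m = t_m <= c_m
    age_f = np.minimum(np.where(dead_f, t_f, c_f), MAX_DEATH_AGE)
    age_m = np.minimum(np.where(dead_m, t_m, c_m), MAX_DEATH_AGE)
    dead_f &= t_f <= MAX_DEATH_AGE
    dead_m &= t_m <= MAX_DEATH_AGE

    return pd.DataFrame({
        "father_age": age_f, "father_dead": dead_f,
        "mother_age": age_m, "mother_dead": dead_m,
    })


@dataclass
class RiskFactorStats:
    """Simulated risk-factor GWAS summary statistics.

    ``factor_betas``/``factor_ses`` are (n_snps, n_factors) frames of
    observed per-SNP effects on each standardised risk factor;
    ``true_factor_betas`` the noiseless versions; ``causal_effects`` the
    per-factor causal effect on lifespan; and ``true_lifespan_beta`` the
    implied per-SNP lifespan effect sum_k causal_k * b_k.
    """

    factor_betas: pd.DataFrame
    factor_ses: pd.DataFrame
    true_factor_betas: pd.DataFrame
    causal_effects: np.ndarray
    true_lifespan_beta: pd.Series


def simulate_risk_factor_stats(snps: Sequence[SnpSpec], n_factors: int,
                               causal_effects: Sequence[float],
                               noise_se: Sequence[float],
                               factor_effect_sd: float = 1.0,
                               seed=None,
                               rng: np.random.Generator | None = None) -> RiskFactorStats:
    """Generate risk-factor summary-stat tables with a known causal chain.

    Each SNP's true effect on factor k is N(0, factor_effect_sd²); the
    implied lifespan effect is the causal-weighted sum of the true factor
    effects, and the observed tables add independent noise with the given
    per-factor standard errors.
    """
    causal = np.asarray(causal_effects, dtype=float)
    ses = np.asarray(noise_se, dtype=float)
    if not (len(causal) == len(ses) == n_factors):
        raise ValueError("causal_effects and noise_se must have length n_factors")
    if np.any(ses < 0):
        raise ValueError("noise_se must be non-negative")
    _validate_snps(snps)
    rng = rng if rng is not None else np.random.default_rng(seed)

    ids = [s.id for s in snps]
    factors = [f"factor_{k+1}" for k in range(n_factors)]
    b_true = rng.normal(0.0, factor_effect_sd, size=(len(snps), n_factors))
    b_obs = b_true + rng.normal(0.0, 1.0, b_true.shape) * ses

    return RiskFactorStats(
        factor_betas=pd.DataFrame(b_obs, index=ids, columns=factors),
        factor_ses=pd.DataFrame(np.broadcast_to(ses, b_true.shape).copy(),
                                index=ids, columns=factors),
        true_factor_betas=pd.DataFrame(b_true, index=ids, columns=factors),
        causal_effects=causal,
        true_lifespan_beta=pd.Series(b_true @ causal, index=ids),
    )


def simulate_cohort(n_subjects: int, snps: Sequence[SnpSpec],
                    gp: GompertzParams = DEFAULT_GOMPERTZ,
                    rho: float = DEFAULT_RHO,
                    frailty_sd: float = DEFAULT_FRAILTY_SD,
                    censor_age_dist=DEFAULT_CENSOR_AGES,
                    n_covariates: int = 2,
                    cohort_id: str = "sim",
                    seed=None) -> CohortTable:
    """End-to-end cohort draw: genotypes, lifespans, and null covariates.

    Covariates are independent standard normals (stand-ins for principal
    components and technical covariates); they carry no lifespan effect by
    default, so residualisation on them must be harmless.
    """
    rng = np.random.default_rng(seed)
    dosages, gf, gm = simulate_genotypes(n_subjects, snps, rng=rng)
    surv = simulate_lifespans(gf, gm, snps, gp=gp, rho=rho,
                              frailty_sd=frailty_sd,
                              censor_age_dist=censor_age_dist, rng=rng)
    cov_cols = [f"pc{i+1}" for i in range(n_covariates)]
    subjects = pd.DataFrame({
        "subject_id": [f"{cohort_id}_{i:07d}" for i in range(n_subjects)]})
    for c in cov_cols:
        subjects[c] = rng.normal(0.0, 1.0, n_subjects)
    subjects = pd.concat([subjects, surv], axis=1)
    return CohortTable(subjects=subjects, dosages=dosages, snps=list(snps),
                       cohort_id=cohort_id, covariate_cols=cov_cols,
                       father_genotypes=gf, mother_genotypes=gm)


# ---------------------------------------------------------------------------
# Plain-text interchange

def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as a tab-delimited table (one row per subject)."""
    df = cohort.subjects.copy()
    for j, sid in enumerate(cohort.snp_ids):
        df[f"dosage_{sid}"] = cohort.dosages[:, j]
    front = ["subject_id"] + [f"dosage_{s}" for s in cohort.snp_ids] \
        + cohort.covariate_cols \
        + ["father_age", "father_dead", "mother_age", "mother_dead"]
    df.loc[:, front].to_csv(path, sep="\t", index=False)


def read_cohort(path, snps: Sequence[SnpSpec] | None = None,
                cohort_id: str = "cohort") -> CohortTable:
    """Read a cohort table written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t")
    dosage_cols = [c for c in df.columns if c.startswith("dosage_")]
    snp_ids = [c[len("dosage_"):] for c in dosage_cols]
    if snps is None:
        snps = [SnpSpec(id=s, maf=float(np.clip(df[f"dosage_{s}"].mean() / 2.0,
                                                0.00501, 0.5)))
                for s in snp_ids]
    cov_cols = [c for c in df.columns
                if c not in dosage_cols
                and c not in ("subject_id", "father_age", "father_dead",
                              "mother_age", "mother_dead")]
    return CohortTable(
        subjects=df.drop(columns=dosage_cols),
        dosages=df[dosage_cols].to_numpy(dtype=float),
        snps=list(snps), cohort_id=cohort_id, covariate_cols=cov_cols)


def write_snp_manifest(snps: Sequence[SnpSpec], path) -> None:
    """Write a SNP manifest TSV (1-based positions)."""
    pd.DataFrame({
        "id": [s.id for s in snps],
        "chrom": [s.chrom for s in snps],
        "pos": [s.pos for s in snps],
        "a1": "A", "a0": "G",
        "maf": [s.maf for s in snps],
        "beta": [s.beta_carrier for s in snps],
        "mode": [s.mode for s in snps],
    }).to_csv(path, sep="\t", index=False)


def read_snp_manifest(path) -> list[SnpSpec]:
    df = pd.read_csv(path, sep="\t")
    return [SnpSpec(id=str(r.id), maf=float(r.maf),
                    beta_carrier=float(r.beta), mode=str(r.mode),
                    chrom=int(r.chrom), pos=int(r.pos))
            for r in df.itertuples()]
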