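"""Summary-statistics tables: reading, writing, allele harmonisation.

The lingua franca between pipeline stages is a whitespace/tab-delimited
table with columns ``snpid chr pos a1 a0 freq1 beta1 se p n`` (effect
sizes on the carrier lnPR scale, a1 = effect allele).  Readers tolerate
column reordering and extra columns; writers emit tab-separated text that
is bit-stable for a fixed input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CORE_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonise",
    "is_strand_ambiguous",
]

CORE_COLUMNS = ["snpid", "chr", "pos", "a1", "a0", "freq1", "beta1", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_sumstats(path, require: tuple[str, ...] = ("snpid", "a1", "a0", "beta1", "se")) -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistics table.

    Column order is free; names are lower-cased.  Raises if any column in
    ``require`` is missing.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"snpid": str})
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stats table {path} missing columns: {missing}")
    for c in ("a1", "a0"):
        if c in df.columns:
            df[c] = df[c].str.upper()
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table as TSV (deterministic output)."""
    cols = [c for c in CORE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def is_strand_ambiguous(a1: str, a0: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved."""
    return _COMPLEMENT.get(a1.upper()) == a0.upper()


def harmonise(left: pd.DataFrame, right: pd.DataFrame,
              drop_ambiguous_freq: tuple[float, float] = (0.4, 0.6)) -> pd.DataFrame:
    """Align two summary-stat tables on shared SNPs and effect alleles.

    Matches on ``snpid``.  Where the right table reports the alleles
    swapped (a1/a0 reversed, directly or as strand complements), its beta
    is sign-flipped and its frequency reflected.  Strand-ambiguous (A/T,
    C/G) SNPs are dropped when either table's effect-allele frequency lies
    inside ``drop_ambiguous_freq``, since allele identity cannot then be
    resolved from frequency.  Unresolvable allele pairs raise.

    Returns a merged frame with ``_x``/``_y`` suffixed statistics, the
    right-hand beta already on the left-hand allele coding.
    """
    m = left.merge(right, on="snpid", suffixes=("_x", "_y"))
    if m.empty:
        return m

    a1x, a0x = m["a1_x"], m["a0_x"]
    a1y, a0y = m["a1_y"], m["a0_y"]
    comp = lambda s: s.map(_COMPLEMENT)  # noqa: E731

    same = (a1y == a1x) & (a0y == a0x)
    same |= (comp(a1y) == a1x) & (comp(a0y) == a0x)
    swapped = (a1y == a0x) & (a0y == a1x)
    swapped |= (comp(a1y) == a0x) & (comp(a0y) == a1x)

    unresolved = ~(same | swapped)
    if unresolved.any():
        bad = m.loc[unresolved, "snpid"].tolist()
        raise ValueError(f"allele mismatch without resolvable flip: {bad[:5]}")

    m.loc[swapped, "beta1_y"] = -m.loc[swapped, "beta1_y"]
    if "freq1_y" in m.columns:
        m.loc[swapped, "freq1_y"] = 1.0 - m.loc[swapped, "freq1_y"]
    m.loc[swapped, ["a1_y", "a0_y"]] = m.loc[swapped, ["a0_y", "a1_y"]].to_numpy()

    ambiguous = np.array([is_strand_ambiguous(a, b) for a, b in zip(m["a1_x"], m["a0_x"])])
    lo, hi = drop_ambiguous_freq
    freq_cols = [c for c in ("freq1_x", "freq1_y") if c in m.columns]
    if freq_cols and ambiguous.any():
        in_band = np.zeros(len(m), dtype=bool)
        for c in freq_cols:
            f = m[c].to_numpy(dtype=float)
            in_band |= (f >= lo) & (f <= hi)
        m = m.loc[~(ambiguous & in_band)].reset_index(drop=True)
    return m
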