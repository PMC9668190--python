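"""Bench-validation statistics.

Exact calculators for the small assays used to validate pooled-fitness
calls at the bench: viable spore yield (VSY) normalization with a
Mann-Whitney comparison against wild type, spore/vegetative competition
log-ratios, and Fisher exact tests on category tallies (tetrad morphology,
chromosome-III disomy). All consume plain tables of counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from sexfit.fitness_stats import mann_whitney

#: Sentinel for a competition endpoint where the focal strain was not
#: recovered at all; it ranks below every finite score.
NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# viable spore yield


def vsy(records: pd.DataFrame, wild_type: str = "WT") -> pd.DataFrame:
    """Viable spore yield per replicate, normalized to same-batch wild type.

    ``records`` needs columns ``replicate, genotype, spores, cells`` and
    optionally ``batch`` (defaults to one batch). VSY = viable spores
    recovered / cells plated; normalized VSY divides by the mean VSY of
    wild-type replicates from the same batch, so the wild-type batch mean
    is exactly 1.
    """
    df = records.copy()
    if "batch" not in df.columns:
        df["batch"] = 0
    if (df["cells"] <= 0).any():
        raise ValueError("cells plated must be positive")
    df["vsy"] = df["spores"] / df["cells"]
    wt_mean = (
        df.loc[df["genotype"] == wild_type].groupby("batch")["vsy"].mean()
    )
    if wt_mean.empty or wt_mean.isna().any() or (wt_mean <= 0).any():
        raise ValueError(f"every batch needs wild-type ({wild_type!r}) replicates")
    missing = set(df["batch"]) - set(wt_mean.index)
    if missing:
        raise ValueError(f"batches without wild-type replicates: {sorted(missing)}")
    df["vsy_normalized"] = df["vsy"] / df["batch"].map(wt_mean)
    return df


def vsy_test(
    records: pd.DataFrame, genotype: str, wild_type: str = "WT"
) -> tuple[float, float]:
    """Mann-Whitney of a genotype's normalized VSY against wild type."""
    df = vsy(records, wild_type=wild_type)
    a = df.loc[df["genotype"] == genotype, "vsy_normalized"].to_numpy()
    b = df.loc[df["genotype"] == wild_type, "vsy_normalized"].to_numpy()
    return mann_whitney(a, b)


# ---------------------------------------------------------------------------
# competition


def competition_score(p0: float, p1: float) -> tuple[float, bool]:
    """Log10 ratio of final over initial focal-strain frequency.

    Frequencies are the focal (marker-resistant) fraction among all scored
    colonies. A zero final frequency yields a flagged ``-inf`` sentinel
    (ranked below all finite scores in cohort tests) rather than a
    pseudo-count. Returns ``(score, degenerate_flag)``.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("initial frequency must be strictly between 0 and 1")
    if not (0.0 <= p1 < 1.0):
        raise ValueError("final frequency must be in [0, 1)")
    if p1 == 0.0:
        return NEG_INF, True
    return math.log10(p1 / p0), False


def competition_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Score a table with columns ``replicate, group, p0, p1``."""
    out = records.copy()
    scored = [competition_score(a, b) for a, b in zip(out["p0"], out["p1"])]
    out["score"] = [s for s, _ in scored]
    out["degenerate"] = [f for _, f in scored]
    return out


def competition_test(
    records: pd.DataFrame, test_group: str, control_group: str
) -> tuple[float, float]:
    """Mann-Whitney of competition scores, test cohort versus the neutral
    marker control cohort. ``-inf`` sentinels participate by rank."""
    df = competition_scores(records)
    a = df.loc[df["group"] == test_group, "score"].to_numpy()
    b = df.loc[df["group"] == control_group, "score"].to_numpy()
    return mann_whitney(a, b)


# ---------------------------------------------------------------------------
# Fisher exact tests


def fisher_exact(table) -> float:
    """Two-sided Fisher exact test on a 2x2 or 2xk category table.

    2x2 uses the standard hypergeometric test; 2xk (k > 2) uses the
    Freeman-Halton extension — the exact two-sided p is the total
    probability, under fixed margins, of all tables no more probable than
    the observed one. Raises on degenerate tables (an all-zero row or
    column margin).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2xk with k >= 2")
    if (t < 0).any():
        raise ValueError("tallies must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: empty row or column margin")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    return _freeman_halton(t)


def _freeman_halton(t: np.ndarray) -> float:
    """Exact conditional test on a 2xk table by enumeration of the first
    row under fixed margins; feasible for the bench-scale tallies used
    here (complexity is the product of column totals)."""
    col = t.sum(axis=0)
    r1 = int(t.sum(axis=1)[0])
    n = int(t.sum())
    log_denom = _log_comb(n, r1)

    def log_prob(first_row: tuple[int, ...]) -> float:
        return sum(_log_comb(int(c), int(a)) for c, a in zip(col, first_row)) - log_denom

    obs = log_prob(tuple(t[0]))
    total = 0.0
    k = len(col)

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                lp = acc + _log_comb(int(col[j]), remaining) - log_denom
                if lp <= obs + 1e-9:
                    total += math.exp(lp)
            return
        # bound a_j so later columns can still absorb the remainder
        later = int(col[j + 1 :].sum())
        lo = max(0, remaining - later)
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, acc + _log_comb(int(col[j]), a))

    recurse(0, r1, 0.0)
    return min(1.0, total)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def collapse_tetrad_table(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Collapse a 2xk tetrad-morphology table (four spores / no visible
    spores / other, ...) to 2x2: four-spore asci versus everything else."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape[1] < 2:
        raise ValueError("need at least two categories")
    return np.column_stack([t[:, 0], t[:, 1:].sum(axis=1)])
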