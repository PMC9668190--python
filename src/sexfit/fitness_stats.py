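"""Gene-level fitness statistics for pooled insertion libraries.

The unit of fitness evidence is the per-site log10 fold change

    r = log10( f_post / f_pre ),   f = max(count, 1) / sample total,

where the one-read floor keeps r finite for sites that drop out. Each
gene's distribution of r across its insertion sites is compared with the
pooled intergenic distribution — a built-in neutral control — by a
two-sided Mann-Whitney U test; family-wise error over the genes tested in
a comparison is controlled by Bonferroni. A gene is called required for
sexual reproduction when it is significant in at least one of the two
post-sex comparisons (T3/T2 short, T4/T2 long) with mean r below the null
mean; significant genes with mean r above the null mean are repressor
candidates. The same machinery applied to the two purely vegetative
comparisons (T2/T1 and T4/T3) flags growth-rate confounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Gene filter: genes with fewer distinct insertion sites than this are
#: reported but not tested.
MIN_SITES = 5

ALPHA = 0.05

#: The two post-sex fold-change comparisons used for hit calling and the
#: two vegetative comparisons used for growth-confound flags.
SEX_COMPARISONS = (("T2", "T3"), ("T2", "T4"))
GROWTH_COMPARISONS = (("T1", "T2"), ("T3", "T4"))


def mann_whitney(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of ``x`` versus ``y``.

    ``method="auto"`` uses the exact null distribution when both samples
    have at most 8 observations and there are no ties, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction. Returns ``(U, p)`` with U the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# fold changes


def fold_changes(
    table: pd.DataFrame, pre: str, post: str, floor: int = 1
) -> pd.DataFrame:
    """Per-site log10 fold change of post over pre insert frequency.

    Counts are floored at ``floor`` (default 1 read) before conversion to
    frequency, so sites undetected post-selection contribute a finite,
    magnitude-understating r rather than -inf. Sample totals are the sums
    of the (already site-filtered) raw counts; they are not re-inflated by
    the flooring. Expects a table that has passed :func:`sexfit.quant.filter_sites`.
    """
    for col in (pre, post):
        if col not in table.columns:
            raise ValueError(f"sample {col!r} absent from table")
    tot_pre = float(table[pre].sum())
    tot_post = float(table[post].sum())
    if tot_pre <= 0 or tot_post <= 0:
        raise ValueError("zero sample total")
    f_pre = table[pre].clip(lower=floor) / tot_pre
    f_post = table[post].clip(lower=floor) / tot_post
    out = pd.DataFrame({"r": np.log10(f_post / f_pre)}, index=table.index)
    if "feature" in table.columns:
        out["feature"] = table["feature"]
    return out


def intergenic_null(fc: pd.DataFrame) -> np.ndarray:
    """The pooled fold-change values of intergenic sites (the neutral
    reference distribution)."""
    null = fc.loc[fc["feature"] == "intergenic", "r"].to_numpy()
    if null.size == 0:
        raise ValueError("no intergenic sites")
    return null


def gene_values(fc: pd.DataFrame) -> dict[str, np.ndarray]:
    """Fold-change values grouped by gene.

    Sites inside overlapping genes (feature ``"a;b"``) contribute to each
    owner; intergenic sites are excluded.
    """
    genic = fc.loc[fc["feature"] != "intergenic", ["r", "feature"]].copy()
    genic["feature"] = genic["feature"].str.split(";")
    exploded = genic.explode("feature")
    return {g: grp["r"].to_numpy() for g, grp in exploded.groupby("feature")}


# ---------------------------------------------------------------------------
# gene tests


@dataclass
class ComparisonResult:
    """Per-gene Mann-Whitney outcomes for one pre/post comparison."""

    comparison: str
    results: pd.DataFrame  # gene, n_sites, U, p, p_bonf, mean_r, median_r, significant, direction
    null_mean: float
    null_median: float
    n_null: int
    n_tested: int


def gene_test(
    values: dict[str, np.ndarray],
    null: np.ndarray,
    comparison: str,
    alpha: float = ALPHA,
    min_sites: int = MIN_SITES,
    method: str = "auto",
    correction: str = "bonferroni",
) -> ComparisonResult:
    """Test every gene's fold-change distribution against the intergenic null.

    Genes with fewer than ``min_sites`` sites are listed with status
    ``too_few_sites`` and no p-value. Bonferroni multiplies each raw p by
    the number of genes actually tested in this comparison (``m``), capped
    at 1; ``correction="bh"`` switches to Benjamini-Hochberg FDR (a
    documented deviation from the family-wise default).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("no intergenic sites")
    null_mean = float(null.mean())

    rows = []
    tested = [g for g, v in values.items() if v.size >= min_sites]
    m = len(tested)
    for gene, v in sorted(values.items()):
        n = int(v.size)
        mean_r = float(v.mean()) if n else float("nan")
        median_r = float(np.median(v)) if n else float("nan")
        if n < min_sites:
            rows.append((gene, n, np.nan, np.nan, np.nan, mean_r, median_r,
                         False, "", "too_few_sites"))
            continue
        U, p = mann_whitney(v, null, method=method)
        rows.append((gene, n, U, p, np.nan, mean_r, median_r, False,
                     "down" if mean_r < null_mean else "up", "tested"))
    df = pd.DataFrame(
        rows,
        columns=["gene", "n_sites", "U", "p", "p_bonf", "mean_r", "median_r",
                 "significant", "direction", "status"],
    ).set_index("gene")
    mask = df["status"] == "tested"
    if correction == "bonferroni":
        df.loc[mask, "p_bonf"] = np.minimum(1.0, df.loc[mask, "p"] * m)
    elif correction == "bh":
        df.loc[mask, "p_bonf"] = _benjamini_hochberg(df.loc[mask, "p"].to_numpy())
    else:
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    df.loc[mask, "significant"] = df.loc[mask, "p_bonf"] < alpha
    return ComparisonResult(
        comparison=comparison,
        results=df,
        null_mean=null_mean,
        null_median=float(np.median(null)),
        n_null=int(null.size),
        n_tested=m,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


def test_comparison(
    table: pd.DataFrame,
    pre: str,
    post: str,
    alpha: float = ALPHA,
    min_sites: int = MIN_SITES,
    method: str = "auto",
    correction: str = "bonferroni",
) -> ComparisonResult:
    """Fold changes plus gene tests for one pre/post sample pair."""
    fc = fold_changes(table, pre, post)
    if "feature" not in fc.columns:
        raise ValueError("table must carry a 'feature' column (assign_features)")
    return gene_test(
        gene_values(fc), intergenic_null(fc), comparison=f"{post}/{pre}",
        alpha=alpha, min_sites=min_sites, method=method, correction=correction,
    )


# ---------------------------------------------------------------------------
# classification across comparisons


def classify(
    short: ComparisonResult, long: ComparisonResult, alpha: float = ALPHA
) -> pd.DataFrame:
    """Combine the two post-sex comparisons into per-gene classifications.

    ``required_for_sex``: significant in at least one outgrowth with mean r
    below the null mean in every significant comparison.
    ``repressor_candidate``: significant with mean r above the null mean.
    Genes significant in opposite directions follow the more significant
    comparison and are flagged in ``direction_conflict``.
    """
    genes = short.results.index.union(long.results.index)
    rows = []
    for gene in genes:
        entries = []
        for res in (short, long):
            if gene in res.results.index:
                row = res.results.loc[gene]
                entries.append((res, row))
        n_sites = max(int(row["n_sites"]) for _, row in entries)
        if all(row["status"] == "too_few_sites" for _, row in entries):
            rows.append((gene, n_sites, "too_few_sites", False))
            continue
        sig = [(res, row) for res, row in entries if row["significant"]]
        if not sig:
            rows.append((gene, n_sites, "not_significant", False))
            continue
        directions = {row["direction"] for _, row in sig}
        conflict = len(directions) > 1
        if conflict:
            _, best = min(sig, key=lambda e: e[1]["p_bonf"])
            direction = best["direction"]
        else:
            direction = directions.pop()
        cls = "required_for_sex" if direction == "down" else "repressor_candidate"
        rows.append((gene, n_sites, cls, conflict))
    return pd.DataFrame(
        rows, columns=["gene", "n_sites", "classification", "direction_conflict"]
    ).set_index("gene")


def growth_confound(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    min_sites: int = MIN_SITES,
    method: str = "auto",
) -> pd.DataFrame:
    """Flag growth-rate confounds from the two vegetative comparisons.

    Runs the same gene-versus-intergenic test on T2/T1 (pre-sex vegetative
    growth) and T4/T3 (post-germination outgrowth). A significant decrease
    sets ``impaired_pre_sex`` / ``impaired_post_germination``; a
    significant increase sets the corresponding advantage flag. Genes with
    an advantage at both vegetative steps are ``growth_advantage_suspect``
    — repressor candidates among them likely reflect growth rate, not
    repression of sex. ``impaired_both`` marks genes impaired at both
    stages.
    """
    pre = test_comparison(table, "T1", "T2", alpha=alpha, min_sites=min_sites,
                          method=method)
    post = test_comparison(table, "T3", "T4", alpha=alpha, min_sites=min_sites,
                           method=method)
    genes = pre.results.index.union(post.results.index)
    flags = pd.DataFrame(
        False,
        index=genes,
        columns=[
            "impaired_pre_sex", "impaired_post_germination",
            "advantage_pre_sex", "advantage_post_germination",
            "impaired_both", "growth_advantage_suspect",
        ],
    )
    for res, imp_col, adv_col in (
        (pre, "impaired_pre_sex", "advantage_pre_sex"),
        (post, "impaired_post_germination", "advantage_post_germination"),
    ):
        sig = res.results.loc[res.results["significant"]]
        flags.loc[sig.index[sig["direction"] == "down"], imp_col] = True
        flags.loc[sig.index[sig["direction"] == "up"], adv_col] = True
    flags["impaired_both"] = flags["impaired_pre_sex"] & flags["impaired_post_germination"]
    flags["growth_advantage_suspect"] = (
        flags["advantage_pre_sex"] & flags["advantage_post_germination"]
    )
    flags.index.name = "gene"
    return flags


def analyze(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    min_sites: int = MIN_SITES,
    method: str = "auto",
    correction: str = "bonferroni",
) -> dict:
    """Full gene-level analysis of a feature-annotated SiteCountTable.

    Returns the per-comparison :class:`ComparisonResult` objects, the
    combined classification, and the growth-confound flags, plus a flat
    per-gene summary table suitable for TSV export.
    """
    short = test_comparison(table, "T2", "T3", alpha=alpha, min_sites=min_sites,
                            method=method, correction=correction)
    long = test_comparison(table, "T2", "T4", alpha=alpha, min_sites=min_sites,
                           method=method, correction=correction)
    classes = classify(short, long, alpha=alpha)
    flags = growth_confound(table, alpha=alpha, min_sites=min_sites, method=method)

    summary = classes.join(flags, how="left").fillna(False)
    for res, tag in ((short, "short"), (long, "long")):
        cols = res.results[["U", "p", "p_bonf", "mean_r", "median_r"]]
        summary = summary.join(cols.add_suffix(f"_{tag}"), how="left")
    return {
        "short": short,
        "long": long,
        "classification": classes,
        "growth_flags": flags,
        "summary": summary.reset_index(),
    }


# ---------------------------------------------------------------------------
# annotation-set tests


def annotation_set_test(
    member_values: np.ndarray, background_values: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U of an annotation set's fold changes versus background.

    Used both for functional-annotation sets (member genes' site fold
    changes versus all other genes') and for a single non-coding feature
    versus the intergenic null. Returns ``(U, p)``.
    """
    return mann_whitney(
        np.asarray(member_values, float), np.asarray(background_values, float),
        method=method,
    )


def annotation_set_test_genes(
    fc: pd.DataFrame, member_genes: set[str], method: str = "auto"
) -> tuple[float, float]:
    """Annotation-set test at site level: fold changes of sites inside
    member genes versus sites inside all non-member genes."""
    values = gene_values(fc)
    member = np.concatenate([v for g, v in values.items() if g in member_genes])
    other = np.concatenate([v for g, v in values.items() if g not in member_genes])
    return annotation_set_test(member, other, method=method)
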