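"""Reporting utilities and the static run report.

Small, exact helpers for the headline ratios a TN-seq screen reports —
percent of reference insertion sites recovered at a later timepoint, and
overlap of the screen's hit list with an external gene set — plus the
static HTML/SVG report that replaces an interactive viewer: a volcano plot,
a ranked hits table, and per-gene fold-change summaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


# ---------------------------------------------------------------------------
# headline ratios


def percent_recovered(n_recovered: int, n_reference: int, ndigits: int = 1) -> float:
    """Percent of reference sites recovered, rounded for reporting.

    E.g. 475,815 of 655,561 pre-sex sites recovered post-sex -> 72.6.
    """
    if n_reference <= 0:
        raise ValueError("reference count must be positive")
    if n_recovered < 0:
        raise ValueError("recovered count must be non-negative")
    return round(100.0 * n_recovered / n_reference, ndigits)


def screen_overlap(n_overlap: int, n_assayed: int, ndigits: int = 1) -> float:
    """Percent of an external screen's assayed genes recovered as hits."""
    return percent_recovered(n_overlap, n_assayed, ndigits)


def site_recovery(table: pd.DataFrame, reference: str = "T2") -> dict[str, float]:
    """Per-sample percent of reference-detected sites still detected.

    A site counts as detected when its unique-UMI count is > 0. Computed on
    whichever table is passed (pre- or post-filter).
    """
    cols = [c for c in table.columns if c != "feature"]
    ref_detected = table[reference] > 0
    n_ref = int(ref_detected.sum())
    return {
        c: percent_recovered(int((table.loc[ref_detected, c] > 0).sum()), n_ref)
        for c in cols
    }


def funnel(raw: pd.DataFrame, filtered: pd.DataFrame, results: pd.DataFrame) -> dict:
    """The screen's reporting funnel: total sites, post-filter sites, genes
    with enough sites to test, and hits."""
    classes = results["classification"].value_counts().to_dict()
    return {
        "sites_total": int(len(raw)),
        "sites_post_filter": int(len(filtered)),
        "genes_tested": int(
            (results["classification"] != "too_few_sites").sum()
        ),
        "genes_required_for_sex": int(classes.get("required_for_sex", 0)),
        "genes_repressor_candidate": int(classes.get("repressor_candidate", 0)),
    }


# ---------------------------------------------------------------------------
# plots and report


def volcano_plot(
    results: pd.DataFrame, out: str | Path, tag: str = "short", alpha: float = 0.05
) -> None:
    """Mean fold change versus -log10 Bonferroni p for one comparison."""
    mean_r = results[f"mean_r_{tag}"]
    p = results[f"p_bonf_{tag}"].clip(lower=1e-300)
    sig = p < alpha
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(mean_r[~sig], -np.log10(p[~sig]), s=8, c="seagreen", alpha=0.6,
               label="not significant")
    ax.scatter(mean_r[sig], -np.log10(p[sig]), s=8, c="darkorange", alpha=0.8,
               label=f"p < {alpha} (Bonferroni)")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="grey")
    ax.set_xlabel("mean log10 fold change (post-sex / pre-sex)")
    ax.set_ylabel("-log10 corrected p")
    ax.set_title(f"{tag} outgrowth")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def html_report(
    summary: pd.DataFrame,
    funnel_stats: dict,
    out_dir: str | Path,
    volcano_files: dict[str, str] | None = None,
) -> Path:
    """Write a static HTML report; idempotent for identical inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts = ["<html><head><title>sexfit report</title></head><body>",
             "<h1>TN-seq sexual reproduction screen</h1>"]
    parts.append("<h2>Funnel</h2><ul>")
    for k in sorted(funnel_stats):
        parts.append(f"<li>{k}: {funnel_stats[k]}</li>")
    parts.append("</ul>")
    if volcano_files:
        parts.append("<h2>Volcano plots</h2>")
        for tag, fname in volcano_files.items():
            parts.append(f'<div><img src="{fname}" alt="volcano {tag}"/></div>')
    hits = summary.loc[
        summary["classification"].isin(["required_for_sex", "repressor_candidate"])
    ]
    if hits.empty:
        parts.append("<p><b>No genes tested or no significant genes.</b></p>")
    else:
        order_col = "p_bonf_short" if "p_bonf_short" in hits.columns else None
        if order_col:
            hits = hits.sort_values(order_col)
        parts.append("<h2>Ranked hits</h2>")
        parts.append(hits.to_html(index=False, float_format=lambda v: f"{v:.3g}"))
    parts.append("</body></html>")
    path = out_dir / "report.html"
    path.write_text("\n".join(parts))
    return path
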