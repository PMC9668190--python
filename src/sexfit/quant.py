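"""Per-site unique-UMI quantification.

Collapses junction calls into per-site counts of distinct UMIs (distinct
barcoded ligation products), merges sequencing runs per sample, zero-fills
sites that drop out at later timepoints, applies the pre-sex site-depth
filter, assigns sites to genes or the intergenic pool, and converts counts
to within-sample frequencies.

Site counts live in a :class:`pandas.DataFrame` indexed by
``(chrom, pos, strand)`` with one integer column per timepoint — the
package's ``SiteCountTable``. Insertions on opposite strands of the same
coordinate are distinct sites by default; pass ``strand_merged=True`` where
supported to pool them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Ordered timepoint roles: T1 initial library, T2 revived pre-sex culture
#: (the filtering reference), T3 short post-sex outgrowth, T4 long post-sex
#: outgrowth.
TIMEPOINTS = ("T1", "T2", "T3", "T4")

ROLE_NAMES = {
    "T1": "pre_sex_initial",
    "T2": "pre_sex_plated",
    "T3": "post_sex_short",
    "T4": "post_sex_long",
}

SITE_KEY = ["chrom", "pos", "strand"]

#: Default site filter: keep sites with strictly more than 8 unique
#: barcoded ligation products in the pre-sex reference sample.
MIN_PRODUCTS = 9


@dataclass
class SampleDesign:
    """Maps the four assay roles to sample ids and their run files.

    Exactly one sample per role; T2 (the revived, plated pre-sex culture)
    is the designated reference for the site filter.
    """

    samples: Mapping[str, str]  # role -> sample id
    runs: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.samples) != set(TIMEPOINTS):
            raise ValueError(
                f"design must map exactly the roles {TIMEPOINTS}, "
                f"got {sorted(self.samples)}"
            )
        ids = list(self.samples.values())
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be distinct")

    @property
    def reference(self) -> str:
        return self.samples["T2"]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleDesign":
        return cls(samples=dict(d["samples"]), runs=dict(d.get("runs", {})))


# ---------------------------------------------------------------------------
# counting and merging


def count_umis(calls: pd.DataFrame) -> pd.DataFrame:
    """Count distinct UMIs per insertion site in one sequencing run.

    ``calls`` is a JunctionCall table (columns ``chrom, pos, strand, umi,
    status``); only ``mapped_unique`` rows contribute. PCR duplicates —
    identical (site, UMI) pairs — collapse to one product; the same UMI at
    two different sites counts once at each.
    """
    ok = calls.loc[calls["status"] == "mapped_unique", SITE_KEY + ["umi"]]
    if ok.empty:
        return pd.DataFrame(columns=SITE_KEY + ["count"])
    counts = (
        ok.drop_duplicates()
        .groupby(SITE_KEY, sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def merge_runs(
    per_sample_runs: Mapping[str, Iterable[pd.DataFrame]],
    design: SampleDesign | None = None,
) -> pd.DataFrame:
    """Combine per-run site counts into a zero-filled SiteCountTable.

    ``per_sample_runs`` maps a timepoint role (or sample id) to the list of
    per-run count frames from :func:`count_umis`. The output is indexed by
    site and holds the per-sample sums over runs; any site seen in any run
    of any sample appears in every column, zero-filled, so sites present in
    the initial library but missing later remain visible as zeros.
    """
    columns: dict[str, pd.Series] = {}
    for sample, run_frames in per_sample_runs.items():
        pieces = [
            f.set_index(SITE_KEY)["count"]
            for f in run_frames
            if f is not None and len(f)
        ]
        if pieces:
            columns[sample] = pd.concat(pieces).groupby(level=SITE_KEY).sum()
        else:
            columns[sample] = pd.Series(
                dtype=np.int64,
                index=pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY),
            )
    table = pd.DataFrame(columns).fillna(0).astype(np.int64)
    table.index.names = SITE_KEY
    return table.sort_index()


def filter_sites(
    table: pd.DataFrame,
    reference_sample: str = "T2",
    min_products: int = MIN_PRODUCTS,
) -> pd.DataFrame:
    """Drop low-depth sites by their pre-sex reference count.

    Retains exactly the sites whose reference-sample count is
    ``>= min_products`` (default 9, i.e. strictly more than 8 unique
    barcoded ligation products); all sample columns subset identically.
    """
    if reference_sample not in table.columns:
        raise ValueError(
            f"reference sample {reference_sample!r} absent from table columns"
        )
    return table.loc[table[reference_sample] >= min_products]


# ---------------------------------------------------------------------------
# feature assignment


def _gene_trees(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    genes = annotation.loc[annotation["feature_type"] == "gene"]
    for row in genes.itertuples(index=False):
        # IntervalTree is half-open; gene spans are 1-based inclusive
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, row.feature_id
        )
    return trees


def assign_site_features(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Label each site genic or intergenic by position.

    A site is genic when its position falls within a gene's ``[start, end]``
    span (introns included; strand ignored). Sites inside several
    overlapping genes get all owner ids joined with ``;`` — downstream they
    count in each gene's distribution and are excluded from the intergenic
    null.
    """
    trees = _gene_trees(annotation)
    out = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree[pos]) if tree is not None else []
        out.append(";".join(hits) if hits else "intergenic")
    return pd.Series(out, index=sites.index, name="feature")


def assign_features(table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``feature`` column to a SiteCountTable."""
    sites = table.index.to_frame(index=False)
    feature = assign_site_features(sites, annotation)
    out = table.copy()
    out["feature"] = feature.values
    return out


# ---------------------------------------------------------------------------
# frequencies and summaries


def sample_totals(table: pd.DataFrame) -> pd.Series:
    """Per-sample totals (sums of the retained counts)."""
    cols = [c for c in table.columns if c != "feature"]
    return table[cols].sum()


def frequencies(table: pd.DataFrame, per: float = 1.0) -> pd.DataFrame:
    """Within-sample insert frequencies: count / sample total.

    ``per`` rescales for display (e.g. ``per=1e7`` for frequency per 10^7
    inserts). Frequencies in each sample sum to ``per``.
    """
    cols = [c for c in table.columns if c != "feature"]
    totals = table[cols].sum()
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"zero sample total for {zero}")
    freq = table[cols].div(totals, axis=1) * per
    if "feature" in table.columns:
        freq["feature"] = table["feature"]
    return freq


def quantification_summary(
    raw: pd.DataFrame, filtered: pd.DataFrame, reference_sample: str = "T2"
) -> dict:
    """Site-funnel summary: sites before/after the depth filter and the
    per-sample fraction of retained sites still detected (count > 0)."""
    cols = [c for c in raw.columns if c != "feature"]
    present_raw = {c: int((raw[c] > 0).sum()) for c in cols}
    present_filt = {c: int((filtered[c] > 0).sum()) for c in cols}
    return {
        "sites_before_filter": int(len(raw)),
        "sites_after_filter": int(len(filtered)),
        "retention_fraction": (len(filtered) / len(raw)) if len(raw) else float("nan"),
        "sites_detected_before_filter": present_raw,
        "sites_detected_after_filter": present_filt,
        "reference_sample": reference_sample,
    }


# ---------------------------------------------------------------------------
# I/O


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(SITE_KEY)


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
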