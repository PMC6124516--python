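"""Promoter methylation from CpG-level bisulfite calls.

CpG records carry methylated and total read counts per position per
sample.  The promoter statistic is the coverage-weighted methylation
level over a +/-1,000 bp window around the TSS: the sum of methylated
reads over the sum of total reads across the window's qualifying CpGs
(coverage >= 10x), defined only when at least 4 distinct CpGs qualify.
Group comparisons use Mann-Whitney U (each group vs the inactivated
reference) and Kruskal-Wallis across all groups.

Coordinates are 0-based half-open internally; the +/-1,000 bp window is
symmetric, so strand does not change the interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_cpgs",
    "promoter_windows",
    "assign_to_promoters",
    "weighted_promoter_methylation",
    "sex_methylation_difference",
    "group_comparison",
]

MIN_COVERAGE = 10
MIN_CPGS = 4
PROMOTER_FLANK = 1000

VALID_CATEGORIES = {
    "inactivated",
    "escaped_placenta_specific",
    "escaped_common",
    "male_biased",
}

_CPG_COLUMNS = ["chromosome", "position", "methylated_reads", "total_reads",
                "sample_id"]


def _validate_cpgs(records: pd.DataFrame) -> None:
    missing = [c for c in _CPG_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"CpG records missing columns: {missing}")
    if len(records) == 0:
        return
    if (records["total_reads"] < 0).any() or (records["methylated_reads"] < 0).any():
        bad = records.index[(records["total_reads"] < 0)
                            | (records["methylated_reads"] < 0)][0]
        raise ValueError(f"negative read count at record {bad}")
    if (records["methylated_reads"] > records["total_reads"]).any():
        bad = records.index[records["methylated_reads"]
                            > records["total_reads"]][0]
        raise ValueError(f"methylated_reads > total_reads at record {bad}")


def filter_cpgs(records: pd.DataFrame,
                min_coverage: int = MIN_COVERAGE) -> pd.DataFrame:
    """Keep CpGs with total coverage >= ``min_coverage``; order preserved."""
    _validate_cpgs(records)
    if len(records) == 0:
        return records.copy()
    return records.loc[records["total_reads"] >= min_coverage].copy()


def promoter_windows(annotation: pd.DataFrame,
                     flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """0-based half-open promoter windows spanning TSS +/- ``flank``.

    Windows are clipped at the chromosome start (position 0).
    """
    ann = annotation.reset_index() if "gene_id" not in annotation.columns \
        else annotation
    start = np.maximum(ann["tss"].to_numpy(dtype=int) - flank, 0)
    end = ann["tss"].to_numpy(dtype=int) + flank
    return pd.DataFrame({
        "gene_id": ann["gene_id"].to_numpy(),
        "chromosome": ann["chromosome"].to_numpy(),
        "start": start,
        "end": end,
    })


def assign_to_promoters(records: pd.DataFrame,
                        windows: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``gene_id`` to each CpG record inside a promoter window.

    A CpG overlapping several promoters appears once per overlapped gene.
    """
    _validate_cpgs(records)
    out = []
    for chrom, win in windows.groupby("chromosome", sort=False):
        recs = records.loc[records["chromosome"] == chrom]
        if len(recs) == 0:
            continue
        pos = recs["position"].to_numpy()
        for _, w in win.iterrows():
            inside = (pos >= w["start"]) & (pos < w["end"])
            if inside.any():
                sub = recs.loc[inside].copy()
                sub["gene_id"] = w["gene_id"]
                out.append(sub)
    if not out:
        cols = list(records.columns) + ["gene_id"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def weighted_promoter_methylation(records: pd.DataFrame,
                                  min_cpgs: int = MIN_CPGS) -> pd.DataFrame:
    """Coverage-weighted promoter methylation per (gene, sample).

    level = sum(methylated_reads) / sum(total_reads) over distinct CpG
    positions in the window; undefined (NaN level) when fewer than
    ``min_cpgs`` distinct CpGs are present.  Records must already be
    coverage-filtered and window-assigned (``gene_id`` column present).

    Raises on duplicate (gene, sample, position) records — the promoter
    level would be ambiguous.
    """
    _validate_cpgs(records)
    if "gene_id" not in records.columns:
        raise ValueError("records must carry gene_id (run assign_to_promoters)")
    if len(records) == 0:
        return pd.DataFrame(columns=["gene_id", "sample_id", "level",
                                     "n_cpgs_used", "defined"])
    dup = records.duplicated(subset=["gene_id", "sample_id", "position"])
    if dup.any():
        r = records.loc[dup].iloc[0]
        raise ValueError(
            "duplicate CpG record for gene "
            f"{r['gene_id']}, sample {r['sample_id']}, "
            f"position {r['position']}: ambiguous promoter level")
    g = records.groupby(["gene_id", "sample_id"], sort=True)
    agg = g.agg(meth=("methylated_reads", "sum"),
                total=("total_reads", "sum"),
                n_cpgs_used=("position", "nunique")).reset_index()
    defined = agg["n_cpgs_used"] >= min_cpgs
    level = np.where(defined & (agg["total"] > 0),
                     agg["meth"] / agg["total"], np.nan)
    return pd.DataFrame({
        "gene_id": agg["gene_id"],
        "sample_id": agg["sample_id"],
        "level": level,
        "n_cpgs_used": agg["n_cpgs_used"],
        "defined": defined,
    })


def sex_methylation_difference(levels: pd.DataFrame,
                               sex_labels: pd.Series) -> pd.Series:
    """Per-gene female-minus-male mean promoter methylation.

    Uses defined levels only; a gene lacking a defined level in one sex
    is reported as missing (NaN), not zero.
    """
    df = levels.loc[levels["defined"]].copy()
    df["sex"] = df["sample_id"].map(sex_labels)
    if df["sex"].isna().any():
        missing = sorted(df.loc[df["sex"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without sex label: {missing}")
    per_sex = df.pivot_table(index="gene_id", columns="sex", values="level",
                             aggfunc="mean")
    for s in ("F", "M"):
        if s not in per_sex.columns:
            per_sex[s] = np.nan
    diff = per_sex["F"] - per_sex["M"]
    diff.name = "female_minus_male"
    return diff


def group_comparison(differences: pd.Series, category_per_gene: pd.Series,
                     reference: str = "inactivated") -> dict:
    """Rank tests of per-gene sex differences across escape categories.

    Two-sided Mann-Whitney U for each non-reference group vs the
    ``inactivated`` reference, plus a Kruskal-Wallis test across all
    groups.  Exact Mann-Whitney p-values for tiny groups, normal
    approximation with tie correction otherwise (scipy's ``method="auto"``).
    """
    unknown = set(category_per_gene.unique()) - VALID_CATEGORIES
    if unknown:
        raise ValueError(f"unknown category label(s): {sorted(unknown)}")
    cat = category_per_gene.reindex(differences.index)
    d = differences.dropna()
    cat = cat.reindex(d.index)
    groups = {c: d[cat == c].to_numpy() for c in cat.dropna().unique()}
    for c, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group '{c}' has fewer than 2 genes")
    if reference not in groups:
        raise ValueError(f"reference group '{reference}' absent")
    ref = groups[reference]
    mw: dict[str, float] = {}
    for c, v in groups.items():
        if c == reference:
            continue
        if np.ptp(np.concatenate([v, ref])) == 0:
            mw[c] = 1.0  # every observation tied: no evidence either way
            continue
        res = stats.mannwhitneyu(v, ref, alternative="two-sided",
                                 method="auto")
        mw[c] = float(res.pvalue)
    if len(groups) >= 2 and np.ptp(d.to_numpy()) > 0:
        kw = float(stats.kruskal(*groups.values()).pvalue)
    else:
        kw = 1.0
    return {
        "mann_whitney_vs_inactivated": mw,
        "kruskal_wallis_p": kw,
        "group_sizes": {c: int(len(v)) for c, v in groups.items()},
        "group_medians": {c: float(np.median(v)) for c, v in groups.items()},
    }
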