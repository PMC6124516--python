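"""Per-gene X-inactivation escape classification.

Integrates the placental sex-bias calls, the cross-tissue partition and
the gene annotation into one of five categories per X gene:

- ``escaped_placenta_specific`` — female-biased in placenta, female-biased
  in no comparison tissue;
- ``escaped_common`` — female-biased in placenta and in at least one
  comparison tissue;
- ``male_biased`` — male-biased in placenta;
- ``inactivated`` — expressed (mean normalised count above the filter)
  but not sex-biased;
- ``unclassified`` — below the expression filter.

Promoter methylation acts as corroboration only: an escaped gene is
consistent when its female-minus-male promoter difference is near zero,
an inactivated (or male-biased) gene when the difference shows female
hypermethylation.  The flag never changes the category.
"""

from __future__ import annotations

import pandas as pd

from .expression import MIN_MEAN_COUNT
from .methylation import group_comparison

__all__ = ["classify", "methylation_corroboration"]

CONSISTENCY_THRESHOLD = 0.1


def classify(placenta_calls: pd.DataFrame,
             cross_tissue_partition: dict[str, list[str]],
             annotation: pd.DataFrame,
             min_mean: float = MIN_MEAN_COUNT) -> pd.DataFrame:
    """Deterministic escape category per X gene.

    ``placenta_calls`` is the X-chromosome calling table (with
    ``bias_call``); ``cross_tissue_partition`` the
    placenta-specific/common split of its female-biased genes.  Returns a
    DataFrame indexed by gene id with ``category``, ``known_xci_status``
    and evidence columns.  The categories partition the X genes.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns \
        else annotation
    missing = placenta_calls.index.difference(ann.index)
    if len(missing) > 0:
        raise ValueError(
            f"genes present in calls but absent from annotation: "
            f"{list(missing[:5])}")
    specific = set(cross_tissue_partition.get("placenta_specific", []))
    common = set(cross_tissue_partition.get("common", []))

    rows = []
    for gene_id, row in placenta_calls.iterrows():
        if row["mean_normalized_count"] <= min_mean:
            cat = "unclassified"
        elif row["bias_call"] == "female":
            cat = "escaped_common" if gene_id in common else \
                "escaped_placenta_specific"
        elif row["bias_call"] == "male":
            cat = "male_biased"
        else:
            cat = "inactivated"
        rows.append({
            "gene_id": gene_id,
            "category": cat,
            "known_xci_status": ann.loc[gene_id].get("known_xci_status",
                                                     "unknown"),
            "mean_normalized_count": row["mean_normalized_count"],
            "fc_female_over_male": row["fc_female_over_male"],
            "adjusted_p": row["adjusted_p"],
            "bias_call": row["bias_call"],
            "n_other_tissues_female_biased": int(gene_id in common),
        })
    out = pd.DataFrame(rows).set_index("gene_id")
    return out


def methylation_corroboration(
    escape_calls: pd.DataFrame,
    sex_methylation_differences: pd.Series,
    threshold: float = CONSISTENCY_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Flag per-gene methylation consistency and attach the group tests.

    Escaped genes are consistent when |female - male promoter
    methylation| < ``threshold``; inactivated and male-biased genes when
    the difference exceeds ``threshold`` (female hypermethylation).
    Genes without a methylation difference keep a missing flag; the
    category is never changed by this step.

    Returns ``(calls_with_flags, group_test_report)``.
    """
    calls = escape_calls.copy()
    diff = sex_methylation_differences.reindex(calls.index)
    calls["meth_female_minus_male"] = diff

    flag = pd.Series(pd.NA, index=calls.index, dtype="boolean")
    has = diff.notna()
    escaped = calls["category"].isin(
        ["escaped_placenta_specific", "escaped_common"])
    hyper = calls["category"].isin(["inactivated", "male_biased"])
    flag[has & escaped] = diff[has & escaped].abs() < threshold
    flag[has & hyper] = diff[has & hyper] > threshold
    calls["methylation_consistent"] = flag

    classified = calls.loc[(calls["category"] != "unclassified") & has]
    counts = classified["category"].value_counts()
    usable = counts[counts >= 2].index
    sub = classified.loc[classified["category"].isin(usable)]
    if "inactivated" in usable and len(usable) >= 2:
        report = group_comparison(sub["meth_female_minus_male"],
                                  sub["category"])
    else:
        report = {"mann_whitney_vs_inactivated": {}, "kruskal_wallis_p": None,
                  "group_sizes": counts.to_dict(), "group_medians": {}}
    return calls, report
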