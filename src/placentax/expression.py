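"""Sex-biased expression calling on gene-level count matrices.

The substrate is a genes x samples matrix of integer read counts with a
fetal-sex label per sample.  The workflow is:

1. :func:`estimate_size_factors` — median-of-ratios library-size
   normalisation.
2. :func:`test_sex_bias` — per-gene negative-binomial Wald test of
   female vs male mean expression, with a method-of-moments dispersion
   estimate (no fold-change shrinkage; gene-level p-values therefore
   differ from shrinkage-based DE engines, while the downstream calling
   thresholds are unchanged).
3. :func:`call_sex_biased` — the calling rule: mean normalised count
   > 10, fold change > 10% in either direction, and Benjamini-Hochberg
   adjusted P < 0.01 with the correction applied over exactly the genes
   of the chromosome set under test (chromosome X by default).
4. :func:`chromosome_enrichment_test` — Fisher's exact test for
   enrichment of sex-biased genes on X over the autosomes (Y excluded).
5. :func:`cross_tissue_female_bias` — partition of placental
   female-biased genes into placenta-specific vs common, by whether any
   comparison tissue also calls them female-biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "estimate_size_factors",
    "test_sex_bias",
    "call_sex_biased",
    "chromosome_enrichment_test",
    "cross_tissue_female_bias",
]

#: default calling thresholds
MIN_MEAN_COUNT = 10.0
FC_THRESHOLD = 1.10
ADJUSTED_P_THRESHOLD = 0.01
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample sex labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample.
    sex
        Series indexed by sample id with values ``"F"`` / ``"M"``.
    tissue
        Free-text tissue label (e.g. ``"placenta"``).
    """

    counts: pd.DataFrame
    sex: pd.Series
    tissue: str = "placenta"

    def __post_init__(self) -> None:
        self.sex = self.sex.reindex(self.counts.columns)
        if self.sex.isna().any():
            missing = list(self.sex.index[self.sex.isna()])
            raise ValueError(f"samples without sex label: {missing}")
        bad = set(self.sex.unique()) - {"F", "M"}
        if bad:
            raise ValueError(f"sex labels must be 'F' or 'M', got {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes g of count_gj / geomean_g, restricted to
    genes whose geometric mean over samples is nonzero.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or not (x > 0).any():
        raise ValueError("degenerate input: count matrix has no nonzero entries")
    with np.errstate(divide="ignore"):
        loggeo = np.log(x).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError(
            "degenerate input: no gene has nonzero counts in every sample"
        )
    ratios = x[usable] / np.exp(loggeo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("degenerate input: non-positive size factor")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                  n_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene MLE of the group mean in a log-link NB model with offsets.

    Solves sum_j (y_gj - mu_g s_j) / (1 + alpha_g mu_g s_j) = 0 for mu_g by
    Newton on beta = log(mu), vectorised over genes.  Returns (mu, info)
    where info is the expected Fisher information of beta at the MLE,
    sum_j mu s_j / (1 + alpha mu s_j).

    Genes with all-zero counts get mu floored at half a normalised count so
    the Wald contrast stays finite; their tests are handled by convention
    upstream.
    """
    total_s = s.sum()
    floor = PSEUDOCOUNT / total_s
    mu = np.maximum((y / s).mean(axis=1), floor)
    beta = np.log(mu)
    for _ in range(n_iter):
        mu = np.exp(beta)
        m = mu[:, None] * s[None, :]
        denom = 1.0 + alpha[:, None] * m
        # score wrt beta = sum_j (y - m)/denom; Fisher scoring step
        score_beta = ((y - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = score_beta / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        beta = np.maximum(beta, np.log(floor))
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(beta)
    m = mu[:, None] * s[None, :]
    info = (m / (1.0 + alpha[:, None] * m)).sum(axis=1)
    return mu, info


def _moment_dispersion(q: np.ndarray, female: np.ndarray,
                       inv_s_mean: float) -> np.ndarray:
    """Method-of-moments NB dispersion from normalised counts.

    Uses the pooled within-sex variance so a real sex effect does not
    inflate the estimate.  Var(q_j) ~ mu/s_j + alpha mu^2, so
    alpha = (var_within - mu * mean(1/s)) / mu^2, clipped to [0, 10].
    """
    groups = [q[:, female], q[:, ~female]]
    n_tot = sum(g.shape[1] for g in groups)
    ss = np.zeros(q.shape[0])
    for g in groups:
        ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var_within = ss / max(n_tot - 2, 1)
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mu * inv_s_mean) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.clip(alpha, 0.0, 10.0)


def test_sex_bias(counts: pd.DataFrame, size_factors: pd.Series,
                  sex: pd.Series) -> pd.DataFrame:
    """Per-gene NB Wald test of female vs male expression.

    Returns a DataFrame indexed by gene id with columns
    ``mean_normalized_count``, ``fc_female_over_male``,
    ``log2_fc_female_over_male`` and ``raw_p``.

    Fold change uses normalised group means with a pseudocount of 0.5 for
    stability at low counts.  All-zero genes get fold change 1 and p = 1 by
    convention.
    """
    sex = sex.reindex(counts.columns)
    female = (sex == "F").to_numpy()
    male = (sex == "M").to_numpy()
    for label, mask in (("F", female), ("M", male)):
        if not mask.any():
            raise ValueError(f"no samples of sex '{label}' in input")

    y = np.asarray(counts, dtype=float)
    s = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    q = y / s
    mean_norm = q.mean(axis=1)
    mean_f = q[:, female].mean(axis=1)
    mean_m = q[:, male].mean(axis=1)
    fc = (mean_f + PSEUDOCOUNT) / (mean_m + PSEUDOCOUNT)

    alpha = _moment_dispersion(q, female, float((1.0 / s).mean()))
    mu_f, info_f = _nb_group_mle(y[:, female], s[female], alpha)
    mu_m, info_m = _nb_group_mle(y[:, male], s[male], alpha)
    with np.errstate(divide="ignore"):
        b1 = np.log(mu_f) - np.log(mu_m)
    se = np.sqrt(1.0 / np.maximum(info_f, 1e-12)
                 + 1.0 / np.maximum(info_m, 1e-12))
    z = b1 / se
    raw_p = 2.0 * stats.norm.sf(np.abs(z))

    # degenerate conventions: all-zero gene, or no within-gene variation
    all_zero = (y.sum(axis=1) == 0)
    constant = (np.ptp(q, axis=1) == 0)
    raw_p = np.where(all_zero, 1.0, raw_p)
    raw_p = np.where(constant & ~all_zero, 1.0, raw_p)
    fc = np.where(all_zero, 1.0, fc)

    return pd.DataFrame(
        {
            "mean_normalized_count": mean_norm,
            "fc_female_over_male": fc,
            "log2_fc_female_over_male": np.log2(fc),
            "raw_p": np.clip(raw_p, 0.0, 1.0),
        },
        index=counts.index,
    )


def call_sex_biased(table: pd.DataFrame, annotation: pd.DataFrame,
                    chromosome: str | list[str] = "chrX",
                    min_mean: float = MIN_MEAN_COUNT,
                    fc_threshold: float = FC_THRESHOLD,
                    adjusted_p: float = ADJUSTED_P_THRESHOLD) -> pd.DataFrame:
    """Apply the sex-bias calling rule over one chromosome set.

    The BH correction runs over exactly the genes of the requested
    chromosome(s), mirroring a per-chromosome-set multiple-testing scope.
    A gene is called female-biased iff mean normalised count > ``min_mean``
    AND fold change > ``fc_threshold`` AND adjusted P < ``adjusted_p``;
    male-biased with fold change < 1/``fc_threshold``; otherwise ``none``.

    Returns the input rows restricted to the chromosome set, with
    ``chromosome``, ``adjusted_p`` and ``bias_call`` columns added.
    """
    chroms = [chromosome] if isinstance(chromosome, str) else list(chromosome)
    present = set(annotation["chromosome"])
    absent = [c for c in chroms if c not in present]
    if absent:
        raise ValueError(f"chromosome(s) not in annotation: {absent}")
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns \
        else annotation
    genes = ann.index[ann["chromosome"].isin(chroms)]
    sub = table.loc[table.index.intersection(genes)].copy()
    sub["chromosome"] = ann.loc[sub.index, "chromosome"]
    if len(sub) == 0:
        sub["adjusted_p"] = pd.Series(dtype=float)
        sub["bias_call"] = pd.Series(dtype=object)
        return sub
    _, adj, _, _ = multipletests(sub["raw_p"].to_numpy(), method="fdr_bh")
    sub["adjusted_p"] = adj
    expressed = sub["mean_normalized_count"] > min_mean
    sig = sub["adjusted_p"] < adjusted_p
    female = expressed & sig & (sub["fc_female_over_male"] > fc_threshold)
    male = expressed & sig & (sub["fc_female_over_male"] < 1.0 / fc_threshold)
    sub["bias_call"] = np.select([female, male], ["female", "male"], "none")
    return sub


def chromosome_enrichment_test(calls: pd.DataFrame) -> tuple[float, float]:
    """Fisher's exact test for X-over-autosome enrichment of biased genes.

    ``calls`` must carry ``chromosome`` and ``bias_call`` for both the X
    and the autosomal gene sets (each called with its own BH scope);
    chromosome-Y genes are excluded.  Returns ``(p_value, odds_ratio)``
    from the two-sided test on the 2x2 table
    {X, autosome} x {biased, not biased}.
    """
    keep = calls["chromosome"] != "chrY"
    sub = calls.loc[keep]
    is_x = sub["chromosome"] == "chrX"
    biased = sub["bias_call"] != "none"
    tab = np.array(
        [
            [int((is_x & biased).sum()), int((is_x & ~biased).sum())],
            [int((~is_x & biased).sum()), int((~is_x & ~biased).sum())],
        ]
    )
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        warnings.warn("empty margin in enrichment table; p = 1", stacklevel=2)
        return 1.0, float("nan")
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p), float(odds)


def cross_tissue_female_bias(
    placenta_calls: pd.DataFrame,
    other_tissue_calls: list[pd.DataFrame],
) -> dict[str, list[str]]:
    """Partition placental female-biased genes by cross-tissue behaviour.

    ``placenta_specific``: female-biased in placenta and in zero comparison
    tissues; ``common``: female-biased in placenta and in at least one
    comparison tissue.  With zero comparison tissues every placental
    female-biased gene is placenta-specific (vacuous quantifier).
    """
    for i, t in enumerate(other_tissue_calls):
        if "bias_call" not in t.columns:
            raise ValueError(
                f"tissue table {i} lacks a 'bias_call' column; run the "
                "calling pipeline (with sex labels) on it first"
            )
    placental = placenta_calls.index[placenta_calls["bias_call"] == "female"]
    biased_elsewhere: set[str] = set()
    for t in other_tissue_calls:
        biased_elsewhere |= set(t.index[t["bias_call"] == "female"])
    specific = [g for g in placental if g not in biased_elsewhere]
    common = [g for g in placental if g in biased_elsewhere]
    return {"placenta_specific": specific, "common": common}
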