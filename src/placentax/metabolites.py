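"""Serum metabolomics preprocessing and the two-stage fetal-sex screen.

Preprocessing expresses each metabolite as multiples of its run-day
median (run-day normalisation) and imputes missing values — assumed to
fall below the detection limit — with the metabolite's minimum observed
relative abundance.

The screen is two-stage.  Stage 1 fits, per metabolite, a longitudinal
linear mixed model on log relative abundance over the early visits
(12/20/28 wkGA by default) with a subject random intercept and fixed
effects visit (categorical), fetal sex and sex x visit; the composite
test is a joint Wald chi-square on every sex-containing coefficient
(df = number of visits), and the 10 metabolites with the lowest
composite p are carried forward.  Stage 2 validates each candidate on
the held-out last visit (36 wkGA) with an ordinary regression of log
abundance on fetal sex; a candidate is selected iff validation
p < 0.01 (strict).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "normalize_run_day",
    "impute_minimum",
    "longitudinal_sex_screen",
    "validate_at_36",
]

TOP_K = 10
VALIDATION_P = 0.01


def normalize_run_day(table: pd.DataFrame,
                      value_col: str = "raw_ion_count") -> pd.DataFrame:
    """Divide each value by its (metabolite, run day) median.

    Missing values stay missing and are excluded from the median.  A
    (metabolite, run day) cell with no observed value at all is an
    error.  Adds/overwrites a ``relative_abundance`` column; the output
    median within every cell is 1, so the operation is idempotent.
    """
    out = table.copy()
    grp = out.groupby(["metabolite_id", "run_day"])[value_col]
    med = grp.transform("median")
    all_missing = grp.transform("count") == 0
    if all_missing.any():
        cells = out.loc[all_missing, ["metabolite_id", "run_day"]] \
            .drop_duplicates().itertuples(index=False)
        raise ValueError(
            "all values missing for (metabolite, run_day) cell(s): "
            + ", ".join(f"({m}, {d})" for m, d in cells))
    out["relative_abundance"] = out[value_col] / med
    return out


def impute_minimum(table: pd.DataFrame,
                   value_col: str = "relative_abundance") -> pd.DataFrame:
    """Replace missing values with the metabolite's minimum observed value."""
    out = table.copy()
    mins = out.groupby("metabolite_id")[value_col].transform("min")
    fully_missing = mins.isna()
    if fully_missing.any():
        bad = sorted(out.loc[fully_missing, "metabolite_id"].unique())
        raise ValueError(f"metabolite(s) with no observed values: {bad}")
    out[value_col] = out[value_col].fillna(mins)
    return out


def _composite_wald(df_sub: pd.DataFrame, visits: list[int]) -> tuple[float, int, float, bool]:
    """Fit the mixed model for one metabolite; return (chi2, df, p, converged)."""
    visit_levels = visits[1:]
    female = (df_sub["fetal_sex"] == "F").to_numpy(dtype=float)
    cols = {"const": np.ones(len(df_sub))}
    for v in visit_levels:
        cols[f"visit_{v}"] = (df_sub["visit_wkGA"] == v).to_numpy(dtype=float)
    cols["female"] = female
    for v in visit_levels:
        cols[f"female_x_visit_{v}"] = cols[f"visit_{v}"] * female
    exog = pd.DataFrame(cols, index=df_sub.index)
    sex_terms = ["female"] + [f"female_x_visit_{v}" for v in visit_levels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df_sub["log_value"].to_numpy(), exog,
                           groups=df_sub["subject_id"].to_numpy())
        fit = None
        for method in (None, "powell"):
            try:
                fit = model.fit(reml=True) if method is None else \
                    model.fit(reml=True, method=method)
                break
            except Exception:
                continue
        if fit is None:
            return np.nan, len(sex_terms), np.nan, False
    if not np.isfinite(fit.params[sex_terms]).all():
        return np.nan, len(sex_terms), np.nan, False
    beta = fit.params[sex_terms].to_numpy()
    cov = fit.cov_params().loc[sex_terms, sex_terms].to_numpy()
    try:
        chi2 = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        return np.nan, len(sex_terms), np.nan, False
    dof = len(sex_terms)
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p, True


def longitudinal_sex_screen(table: pd.DataFrame,
                            visits: tuple[int, ...] = (12, 20, 28),
                            top_k: int = TOP_K,
                            value_col: str = "relative_abundance",
                            log_transform: bool = True) -> pd.DataFrame:
    """Stage-1 composite mixed-model screen over the early visits.

    Returns a DataFrame indexed by metabolite id with
    ``composite_chi2_stat``, ``composite_df``, ``screen_p``, ``rank``
    (ascending p, ties broken by metabolite id), ``candidate``
    (rank <= ``top_k``) and ``converged``.  Non-converging metabolites
    are flagged and excluded from ranking.
    """
    sexes = set(table["fetal_sex"].unique())
    if sexes < {"F", "M"}:
        raise ValueError(f"both fetal sexes required, found {sorted(sexes)}")
    visits = sorted(visits)
    sub = table.loc[table["visit_wkGA"].isin(visits)].copy()
    vals = sub[value_col].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("non-positive abundances; impute before the screen")
    sub["log_value"] = np.log(vals) if log_transform else vals

    rows = []
    for mid, g in sub.groupby("metabolite_id", sort=True):
        chi2, dof, p, ok = _composite_wald(g, visits)
        rows.append({"metabolite_id": mid, "composite_chi2_stat": chi2,
                     "composite_df": dof, "screen_p": p, "converged": ok})
    res = pd.DataFrame(rows).set_index("metabolite_id")
    ranked = res.loc[res["converged"]].sort_values(
        ["screen_p", "metabolite_id"], kind="mergesort")
    res["rank"] = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index)
    res["candidate"] = res["rank"] <= top_k
    res["candidate"] = res["candidate"].fillna(False)
    return res


def validate_at_36(screen: pd.DataFrame, table36: pd.DataFrame,
                   validation_alpha: float = VALIDATION_P,
                   value_col: str = "relative_abundance",
                   log_transform: bool = True) -> pd.DataFrame:
    """Stage-2 validation of screen candidates on the held-out last visit.

    Ordinary least-squares regression of log abundance on a fetal-sex
    indicator; a candidate is ``selected`` iff its two-sided coefficient
    p is strictly below ``validation_alpha``.  A candidate missing from
    the 36 wkGA data keeps a missing validation p and a failure flag.
    """
    out = screen.copy()
    out["validation_p"] = np.nan
    out["validation_failed"] = False
    out["selected"] = False
    for mid in out.index[out["candidate"]]:
        g = table36.loc[table36["metabolite_id"] == mid]
        female = (g["fetal_sex"] == "F").to_numpy(dtype=float)
        if len(g) == 0 or female.sum() < 2 or (1 - female).sum() < 2:
            out.loc[mid, "validation_failed"] = True
            continue
        y = g[value_col].to_numpy(dtype=float)
        if (y <= 0).any():
            raise ValueError("non-positive abundances at validation visit")
        y = np.log(y) if log_transform else y
        X = sm.add_constant(female)
        fit = sm.OLS(y, X).fit()
        out.loc[mid, "validation_p"] = float(fit.pvalues[1])
    out["selected"] = out["candidate"] & (out["validation_p"] < validation_alpha)
    return out
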