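"""Case-cohort risk analysis of metabolite quintiles against pregnancy
outcomes.

The design comprises every term case of the outcomes of interest plus a
random subcohort of the full pregnancy cohort.  Preeclampsia (PE) is the
union of case groups f, h and i (any severe preeclampsia or nonsevere
nonsuperimposed preeclampsia at term); fetal growth restriction (FGR) is
the union of groups g and j (customised birthweight centile < 3rd, or
< 10th combined with the lowest abdominal-circumference growth-velocity
decile).  Preterm births are excluded from both.  Cohort-level case
proportions weight the sampled noncases by the inverse of the subcohort
sampling fraction; odds ratios come from (unweighted) logistic models,
which are consistent for the OR under outcome-dependent sampling.

Exposure handling: quintile cut points are the 20/40/60/80 empirical
percentiles of the noncase distribution; cases are assigned with the
same cuts (closed on the right: quintile k iff cut_{k-1} < x <= cut_k).
The continuous analysis standardises the (transformed) exposure to a
Z score with noncase mean 0 and SD 1 and reports the OR per 1 SD,
unadjusted and adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "cohort_size_after_exclusions",
    "sampling_weight",
    "derive_outcomes",
    "compute_quintiles",
    "assign_quintile",
    "weighted_case_proportion",
    "fit_logistic",
    "LogisticResult",
    "RiskResult",
    "trend_and_continuous_analysis",
    "stratified_analysis",
]

PE_GROUPS = ("f", "h", "i")
FGR_GROUPS = ("g", "j")


class SeparationError(ValueError):
    """Raised when a logistic fit shows perfect separation."""


def cohort_size_after_exclusions(n_enrolled: int,
                                 exclusions: tuple[int, ...]) -> int:
    """Analysis cohort size after the stated exclusions."""
    return int(n_enrolled - sum(exclusions))


def sampling_weight(cohort_size: int, subcohort_size: int) -> float:
    """Inverse of the random subcohort sampling fraction."""
    if subcohort_size <= 0 or cohort_size <= 0:
        raise ValueError("cohort and subcohort sizes must be positive")
    return cohort_size / subcohort_size


def derive_outcomes(flags: pd.DataFrame, term: pd.Series) -> pd.DataFrame:
    """PE and FGR labels from the case-group flags.

    PE = (f or h or i) and term delivery; FGR = (g or j) and term
    delivery.  Both may be true for the same subject.  ``flags`` holds
    boolean columns ``flag_a`` .. ``flag_j``.
    """
    term = term.reindex(flags.index).astype(bool)
    pe = np.zeros(len(flags), dtype=bool)
    for g in PE_GROUPS:
        pe |= flags[f"flag_{g}"].to_numpy(dtype=bool)
    fgr = np.zeros(len(flags), dtype=bool)
    for g in FGR_GROUPS:
        fgr |= flags[f"flag_{g}"].to_numpy(dtype=bool)
    return pd.DataFrame({"PE": pe & term.to_numpy(), "FGR": fgr & term.to_numpy()},
                        index=flags.index)


def compute_quintiles(noncase_values: np.ndarray) -> np.ndarray:
    """Quintile cut points (20/40/60/80 percentiles) of the noncases."""
    x = np.asarray(noncase_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 noncase values for quintiles")
    cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("degenerate quintile cuts: noncase values too tied")
    return cuts


def assign_quintile(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Quintile 1..5 per value; quintile k iff cut_{k-1} < x <= cut_k."""
    return np.searchsorted(np.asarray(cuts, dtype=float),
                           np.asarray(values, dtype=float),
                           side="left") + 1


def weighted_case_proportion(n_cases: int, n_noncases: int,
                             weight: float) -> float:
    """Cohort-level case proportion with up-weighted sampled noncases."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    if n_cases < 0 or n_noncases < 0:
        raise ValueError("counts must be non-negative")
    denom = n_cases + weight * n_noncases
    if denom == 0:
        return float("nan")
    return n_cases / denom


@dataclass
class LogisticResult:
    """Coefficients, standard errors and Wald inference of a logistic fit."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray  # (k, 2) on the log-odds scale

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def or_ci(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return (float(np.exp(self.params[i])),
                float(np.exp(self.conf_int[i, 0])),
                float(np.exp(self.conf_int[i, 1])))


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame,
                 tol: float = 1e-8, maxiter: int = 100) -> LogisticResult:
    """Maximum-likelihood logistic regression via IRLS.

    Raises :class:`SeparationError` on perfect separation and
    ``ValueError`` naming collinear columns on a rank-deficient design.
    The design matrix must already contain an intercept column if one is
    wanted.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns not adding rank
        culprits = []
        seen: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, seen + [j]]) == len(seen):
                culprits.append(names[j])
            else:
                seen.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(tol=tol, maxiter=maxiter)
    eta = X @ fit.params
    p = 1.0 / (1.0 + np.exp(-eta))
    perfectly = np.all((p > 1 - 1e-8) == (y == 1)) and \
        np.all((p < 1e-8) == (y == 0)) and \
        np.all((p > 1 - 1e-8) | (p < 1e-8))
    if perfectly or not np.isfinite(fit.bse).all() or np.max(np.abs(fit.params)) > 1e2:
        raise SeparationError("perfect separation detected in logistic fit")
    ci = np.column_stack([fit.params - 1.959963984540054 * fit.bse,
                          fit.params + 1.959963984540054 * fit.bse])
    return LogisticResult(names=names, params=np.asarray(fit.params),
                          bse=np.asarray(fit.bse),
                          pvalues=np.asarray(fit.pvalues), conf_int=ci)


@dataclass
class RiskResult:
    """Quintile, trend and continuous-Z association for one outcome."""

    exposure: str
    outcome: str
    quintile_case_counts: dict[int, int]
    quintile_noncase_counts: dict[int, int]
    weighted_proportions: dict[int, float]
    categorical: LogisticResult | None
    trend_or: float = np.nan
    trend_p: float = np.nan
    continuous_or: tuple[float, float, float] | None = None  # OR, lo, hi
    continuous_p: float = np.nan
    adjusted_or: tuple[float, float, float] | None = None
    adjusted_p: float = np.nan


def _covariate_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: categoricals as indicators, booleans as 0/1."""
    out = {}
    for c in covariates.columns:
        col = covariates[c]
        if col.isna().mean() > 0.5:
            raise ValueError(f"covariate '{c}' missing for >50% of subjects")
        if col.dtype == bool:
            out[c] = col.astype(float)
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True,
                                     dtype=float)
            for d in dummies.columns:
                out[d] = dummies[d]
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out, index=covariates.index)


def trend_and_continuous_analysis(
    outcome: pd.Series, quintile: pd.Series, z_value: pd.Series,
    covariates: pd.DataFrame | None = None,
    weight: float = 1.0, exposure: str = "metabolite",
) -> RiskResult:
    """The three logistic views of one exposure-outcome association.

    (i) categorical model on quintile indicators (reference quintile 1);
    (ii) linear-trend model with the quintile index 1-5 as a continuous
    score; (iii) continuous model on the Z score, OR per 1 SD, with and
    without covariate adjustment.  Case proportions per quintile weight
    noncases by ``weight``.
    """
    idx = outcome.index
    y = outcome.astype(int)
    q = quintile.reindex(idx)
    z = z_value.reindex(idx)

    case_counts, noncase_counts, props = {}, {}, {}
    for k in range(1, 6):
        nk = int(((q == k) & (y == 1)).sum())
        mk = int(((q == k) & (y == 0)).sum())
        case_counts[k] = nk
        noncase_counts[k] = mk
        props[k] = weighted_case_proportion(nk, mk, weight)

    # categorical quintile model
    cat_design = pd.DataFrame({"const": 1.0}, index=idx)
    for k in range(2, 6):
        cat_design[f"q{k}"] = (q == k).astype(float)
    try:
        categorical = fit_logistic(y.to_numpy(), cat_design)
    except (SeparationError, ValueError):
        categorical = None

    trend_design = pd.DataFrame({"const": 1.0, "quintile": q.astype(float)},
                                index=idx)
    trend_fit = fit_logistic(y.to_numpy(), trend_design)
    trend_or = float(np.exp(trend_fit.coef("quintile")))
    trend_p = trend_fit.p("quintile")

    cont_design = pd.DataFrame({"const": 1.0, "z": z.astype(float)}, index=idx)
    cont_fit = fit_logistic(y.to_numpy(), cont_design)

    adjusted_or = None
    adjusted_p = np.nan
    if covariates is not None:
        cov = _covariate_matrix(covariates.reindex(idx))
        adj_design = pd.concat([cont_design, cov], axis=1)
        adj_fit = fit_logistic(y.to_numpy(), adj_design)
        adjusted_or = adj_fit.or_ci("z")
        adjusted_p = adj_fit.p("z")

    return RiskResult(
        exposure=exposure, outcome=str(outcome.name or "outcome"),
        quintile_case_counts=case_counts,
        quintile_noncase_counts=noncase_counts,
        weighted_proportions=props,
        categorical=categorical,
        trend_or=trend_or, trend_p=trend_p,
        continuous_or=cont_fit.or_ci("z"), continuous_p=cont_fit.p("z"),
        adjusted_or=adjusted_or, adjusted_p=adjusted_p,
    )


def stratified_analysis(strata: dict[str, pd.Series], controls: pd.Series,
                        z_value: pd.Series) -> pd.DataFrame:
    """Continuous-Z logistic fit per case stratum vs the shared controls.

    ``strata`` maps stratum name to a boolean case mask; strata must be
    mutually exclusive within the outcome.  Strata with fewer than 5
    cases are fitted anyway and flagged ``low_n``; an empty stratum
    yields a missing OR without raising.
    """
    masks = list(strata.values())
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if (a & b).any():
                raise ValueError("strata must be mutually exclusive")
    rows = []
    for name, mask in strata.items():
        n_cases = int(mask.sum())
        row = {"stratum": name, "n_cases": n_cases,
               "low_n": bool(0 < n_cases < 5),
               "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p": np.nan}
        if n_cases > 0:
            use = mask | controls
            y = mask.loc[use].astype(int)
            design = pd.DataFrame(
                {"const": 1.0, "z": z_value.reindex(y.index).astype(float)},
                index=y.index)
            try:
                fit = fit_logistic(y.to_numpy(), design)
                orr, lo, hi = fit.or_ci("z")
                row.update(odds_ratio=orr, ci_low=lo, ci_high=hi,
                           p=fit.p("z"))
            except (SeparationError, ValueError):
                pass
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
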