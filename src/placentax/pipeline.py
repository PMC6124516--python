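"""End-to-end orchestration: simulate (or read) inputs, run every
analysis stage, write per-stage reports.

Stages, in the order the method runs:

1. expression — size factors, per-gene NB Wald tests, X and autosome
   calling, X-over-autosome enrichment, cross-tissue partition;
2. methylation — CpG filtering, promoter windows, weighted promoter
   levels, per-gene sex differences;
3. escape classification with methylation corroboration;
4. metabolite screen — run-day normalisation, minimum imputation,
   longitudinal composite screen on the early visits, validation at the
   last visit;
5. case-cohort risk — outcome derivation, quintile construction on
   noncases, trend/continuous logistic models, stratified analyses, with
   noncases weighted by the inverse subcohort sampling fraction.

All randomness flows from the single config seed; a fixed seed produces
byte-identical reports.
"""

from __future__ import annotations

import importlib.metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import casecohort, escape, expression, io, metabolites, methylation
from .config import PipelineConfig
from .expression import CountMatrix
from .simulate import (simulate_metabolome_casecohort, simulate_methylation,
                       simulate_multi_tissue)

__all__ = ["simulate_inputs", "run_pipeline"]

_FLOAT_FMT = "%.10g"


def simulate_inputs(config: PipelineConfig, outdir: str | Path) -> None:
    """Generate every pipeline input under ``outdir`` (plus the truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    placenta, others, truth = simulate_multi_tissue(
        sim, config.n_comparison_tissues, seed=config.seed)
    io.write_count_matrix(placenta, outdir / "counts_placenta.tsv",
                          outdir / "samples_placenta.csv")
    for i, cm in enumerate(others):
        io.write_count_matrix(cm, outdir / f"counts_tissue{i + 1:02d}.tsv",
                              outdir / f"samples_tissue{i + 1:02d}.csv")
    io.write_annotation(truth.annotation.set_index("gene_id"),
                        outdir / "annotation.tsv")

    cpgs = simulate_methylation(sim, truth, seed=config.seed)
    meth_sheet = cpgs[["sample_id", "sex"]].drop_duplicates()
    meth_sheet["tissue"] = "placenta"
    meth_sheet.to_csv(outdir / "samples_methylation.csv", index=False)
    for sample_id, g in cpgs.groupby("sample_id"):
        io.write_cpg_coverage(g, outdir / f"cpg_{sample_id}.cov.tsv")

    table, design, mtruth = simulate_metabolome_casecohort(
        sim, seed=config.seed)
    io.write_metabolite_table(table, outdir / "metabolites.csv")
    design.to_csv(outdir / "design.csv", index_label="subject_id")

    gt = truth.to_jsonable()
    gt.update(mtruth.to_jsonable())
    io.write_json(gt, outdir / "ground_truth.json")


def _load_inputs(config: PipelineConfig, indir: Path):
    placenta = io.read_count_matrix(indir / "counts_placenta.tsv",
                                    indir / "samples_placenta.csv")
    others = []
    for path in sorted(indir.glob("counts_tissue*.tsv")):
        tag = path.stem.replace("counts_", "")
        others.append(io.read_count_matrix(path, indir / f"samples_{tag}.csv"))
    annotation = io.read_annotation(indir / "annotation.tsv")
    meth_sheet = io.read_sample_sheet(indir / "samples_methylation.csv")
    cpg_frames = []
    for sample_id, row in meth_sheet.iterrows():
        cpg_frames.append(io.read_cpg_coverage(
            indir / f"cpg_{sample_id}.cov.tsv", sample_id, row["sex"]))
    cpgs = pd.concat(cpg_frames, ignore_index=True)
    table = io.read_metabolite_table(indir / "metabolites.csv")
    design = pd.read_csv(indir / "design.csv", index_col="subject_id")
    return placenta, others, annotation, cpgs, table, design


def _expression_stage(config: PipelineConfig, placenta: CountMatrix,
                      others: list[CountMatrix], annotation: pd.DataFrame):
    sf = expression.estimate_size_factors(placenta.counts)
    bias = expression.test_sex_bias(placenta.counts, sf, placenta.sex)
    kw = dict(min_mean=config.min_mean_count, fc_threshold=config.fc_threshold,
              adjusted_p=config.adjusted_p)
    x_calls = expression.call_sex_biased(bias, annotation, "chrX", **kw)
    autosomes = sorted({c for c in annotation["chromosome"]
                        if c not in ("chrX", "chrY")})
    auto_calls = expression.call_sex_biased(bias, annotation, autosomes, **kw)
    genome_calls = pd.concat([x_calls, auto_calls])
    enr_p, enr_or = expression.chromosome_enrichment_test(genome_calls)

    other_calls = []
    for cm in others:
        sft = expression.estimate_size_factors(cm.counts)
        bt = expression.test_sex_bias(cm.counts, sft, cm.sex)
        other_calls.append(
            expression.call_sex_biased(bt, annotation, "chrX", **kw))
    partition = expression.cross_tissue_female_bias(x_calls, other_calls)
    return sf, x_calls, genome_calls, (enr_p, enr_or), partition


def _methylation_stage(config: PipelineConfig, cpgs: pd.DataFrame,
                       annotation: pd.DataFrame):
    kept = methylation.filter_cpgs(cpgs, config.min_cpg_coverage)
    windows = methylation.promoter_windows(annotation, config.promoter_flank)
    assigned = methylation.assign_to_promoters(kept, windows)
    levels = methylation.weighted_promoter_methylation(
        assigned, min_cpgs=config.min_cpgs)
    sex_labels = cpgs[["sample_id", "sex"]].drop_duplicates() \
        .set_index("sample_id")["sex"]
    diffs = methylation.sex_methylation_difference(levels, sex_labels)
    return windows, levels, diffs


def _screen_stage(config: PipelineConfig, table: pd.DataFrame,
                  design: pd.DataFrame):
    flags = [c for c in design.columns if c.startswith("flag_")]
    healthy = design.index[design["in_subcohort"]
                           & ~design[flags].any(axis=1)]
    norm = metabolites.normalize_run_day(table)
    imp = metabolites.impute_minimum(norm)
    log_transform = config.metabolite_transform == "log"
    screen_input = imp.loc[imp["subject_id"].isin(healthy)]
    screen = metabolites.longitudinal_sex_screen(
        screen_input, visits=config.screen_visits, top_k=config.top_k,
        log_transform=log_transform)
    t36 = screen_input.loc[screen_input["visit_wkGA"]
                           == config.validation_visit]
    screen = metabolites.validate_at_36(
        screen, t36, validation_alpha=config.validation_p,
        log_transform=log_transform)
    return imp, screen


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.log(values)
    if how == "sqrt":
        return np.sqrt(values)
    return np.asarray(values, dtype=float)


def _risk_stage(config: PipelineConfig, imputed: pd.DataFrame,
                design: pd.DataFrame, exposure_ids: list[str]):
    outcomes = casecohort.derive_outcomes(
        design[[f"flag_{g}" for g in "abcdefghij"]], design["term_delivery"])
    weight = casecohort.sampling_weight(
        len(design), int(design["in_subcohort"].sum()))
    flags = [c for c in design.columns if c.startswith("flag_")]
    healthy = design["in_subcohort"] & ~design[flags].any(axis=1)

    results: dict[str, dict] = {}
    for mid in exposure_ids:
        g = imputed.loc[(imputed["metabolite_id"] == mid)
                        & (imputed["visit_wkGA"] == config.validation_visit)]
        values = g.set_index("subject_id")["relative_abundance"]
        x = pd.Series(_transform(values.to_numpy(), config.metabolite_transform),
                      index=values.index)
        # analysis population: measured at the last visit and term delivery
        pop = x.index.intersection(
            design.index[design["term_delivery"]])
        x = x.loc[pop]
        is_control = healthy.loc[pop]
        cuts = casecohort.compute_quintiles(x[is_control].to_numpy())
        q = pd.Series(casecohort.assign_quintile(x.to_numpy(), cuts),
                      index=pop)
        mu = float(x[is_control].mean())
        sd = float(x[is_control].std())
        z = (x - mu) / sd
        covs = design.loc[pop, ["log_sflt1_plgf", "fetal_sex", "maternal_age",
                                "height", "bmi", "ethnicity", "smoking"]]
        per_outcome = {}
        for oc in ("PE", "FGR"):
            y = outcomes.loc[pop, oc]
            use = y | is_control  # cases vs shared healthy comparison group
            rr = casecohort.trend_and_continuous_analysis(
                y.loc[use].rename(oc), q.loc[use], z.loc[use],
                covariates=covs.loc[use], weight=weight, exposure=mid)
            if oc == "FGR":
                strata = {
                    "bw_3rd_10th_acgvd1":
                        design["flag_g"] & ~design["flag_j"],
                    "bw_lt3rd_acgvd2_10":
                        design["flag_j"] & ~design["flag_g"],
                    "bw_lt3rd_acgvd1":
                        design["flag_g"] & design["flag_j"],
                }
            else:
                severe = design["flag_f"] | design["flag_h"]
                strata = {"nonsevere": design["flag_i"] & ~severe,
                          "severe": severe}
            strata = {k: (v & y.reindex(design.index, fill_value=False))
                      .reindex(pop, fill_value=False)
                      for k, v in strata.items()}
            strat = casecohort.stratified_analysis(strata, is_control, z)
            per_outcome[oc] = {"risk": rr, "stratified": strat}
        results[mid] = per_outcome
    return outcomes, weight, results


def _risk_jsonable(results: dict) -> dict:
    out: dict = {}
    for mid, per_outcome in results.items():
        out[mid] = {}
        for oc, d in per_outcome.items():
            rr = d["risk"]
            out[mid][oc] = {
                "quintile_case_counts": rr.quintile_case_counts,
                "quintile_noncase_counts": rr.quintile_noncase_counts,
                "weighted_proportions": {
                    str(k): (None if np.isnan(v) else round(v, 8))
                    for k, v in rr.weighted_proportions.items()},
                "trend_or": round(rr.trend_or, 8),
                "trend_p": float(f"{rr.trend_p:.6g}"),
                "continuous_or": [round(v, 8) for v in rr.continuous_or],
                "continuous_p": float(f"{rr.continuous_p:.6g}"),
                "adjusted_or": ([round(v, 8) for v in rr.adjusted_or]
                                if rr.adjusted_or else None),
                "adjusted_p": (float(f"{rr.adjusted_p:.6g}")
                               if np.isfinite(rr.adjusted_p) else None),
                "stratified": {
                    s: {k: (None if isinstance(v, float) and np.isnan(v)
                            else (round(v, 8) if isinstance(v, float) else v))
                        for k, v in row.items()}
                    for s, row in d["stratified"].to_dict("index").items()},
            }
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns a dict of the in-memory stage results.  Stage failures
    propagate with the failing stage named; reports written before the
    failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        sim = config.simulation
        placenta, others, truth = simulate_multi_tissue(
            sim, config.n_comparison_tissues, seed=config.seed)
        annotation = truth.annotation
        cpgs = simulate_methylation(sim, truth, seed=config.seed)
        table, design, _ = simulate_metabolome_casecohort(
            sim, seed=config.seed)
    else:
        if config.input_dir is None:
            raise ValueError("usage error: input_dir required when not simulating")
        indir = Path(config.input_dir)
        if not indir.exists():
            raise FileNotFoundError(f"usage error: missing input path {indir}")
        placenta, others, annotation, cpgs, table, design = _load_inputs(
            config, indir)

    stage = "expression"
    try:
        sf, x_calls, genome_calls, (enr_p, enr_or), partition = \
            _expression_stage(config, placenta, others, annotation)
        sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t",
                             float_format=_FLOAT_FMT)
        genome_calls.sort_index().to_csv(outdir / "sex_bias_table.tsv",
                                         sep="\t", float_format=_FLOAT_FMT,
                                         index_label="gene_id")
        io.write_json({"fisher_p": float(f"{enr_p:.6g}"),
                       "odds_ratio": (round(enr_or, 6)
                                      if np.isfinite(enr_or) else None),
                       "cross_tissue": {k: sorted(v)
                                        for k, v in partition.items()}},
                      outdir / "enrichment.json")

        stage = "methylation"
        windows, levels, diffs = _methylation_stage(config, cpgs, annotation)
        io.write_promoter_bed(windows, outdir / "promoter_windows.bed")
        levels.to_csv(outdir / "promoter_methylation.tsv", sep="\t",
                      index=False, float_format=_FLOAT_FMT)
        diffs.to_frame().to_csv(outdir / "methylation_differences.tsv",
                                sep="\t", float_format=_FLOAT_FMT,
                                index_label="gene_id")

        stage = "escape_classification"
        calls = escape.classify(x_calls, partition, annotation,
                                min_mean=config.min_mean_count)
        calls, group_report = escape.methylation_corroboration(
            calls, diffs, threshold=config.meth_consistency_threshold)
        calls.sort_index().to_csv(outdir / "escape_calls.tsv", sep="\t",
                                  float_format=_FLOAT_FMT,
                                  index_label="gene_id")
        io.write_json(group_report, outdir / "methylation_group_tests.json")

        stage = "metabolite_screen"
        imputed, screen = _screen_stage(config, table, design)
        screen.sort_index().to_csv(outdir / "screen_results.tsv", sep="\t",
                                   float_format=_FLOAT_FMT,
                                   index_label="metabolite_id")

        stage = "case_cohort_risk"
        selected = sorted(screen.index[screen["selected"]])
        outcomes, weight, risk = _risk_stage(config, imputed, design, selected)
        io.write_json({"sampling_weight": round(weight, 6),
                       "n_cohort": int(len(design)),
                       "n_subcohort": int(design["in_subcohort"].sum()),
                       "n_PE": int(outcomes["PE"].sum()),
                       "n_FGR": int(outcomes["FGR"].sum()),
                       "selected_metabolites": selected,
                       "results": _risk_jsonable(risk)},
                      outdir / "risk_results.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    try:
        version = importlib.metadata.version("placentax")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    io.write_json({"version": version, "seed": config.seed,
                   "thresholds": {
                       "min_mean_count": config.min_mean_count,
                       "fc_threshold": config.fc_threshold,
                       "adjusted_p": config.adjusted_p,
                       "min_cpg_coverage": config.min_cpg_coverage,
                       "min_cpgs": config.min_cpgs,
                       "promoter_flank": config.promoter_flank,
                       "top_k": config.top_k,
                       "validation_p": config.validation_p}},
                  outdir / "run_log.json")
    return {"size_factors": sf, "x_calls": x_calls,
            "genome_calls": genome_calls, "enrichment": (enr_p, enr_or),
            "cross_tissue": partition, "promoter_levels": levels,
            "methylation_differences": diffs, "escape_calls": calls,
            "methylation_group_tests": group_report, "screen": screen,
            "outcomes": outcomes, "weight": weight, "risk": risk}
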