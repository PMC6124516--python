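"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a pregnancy cohort multiomics
study: sex-dimorphic X-linked expression under dosage compensation with
planted escapees, female promoter hypermethylation at inactivated X
genes, longitudinal serum-metabolite trajectories with run-day batch
effects and detection-limit censoring, and a case-cohort sample in which
one target metabolite carries opposite-sign effects on two pregnancy
outcomes (preeclampsia positive, fetal growth restriction negative).

Every generator takes an explicit seed and is byte-deterministic under
it, and emits a :class:`GroundTruth` alongside the data so downstream
callers can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_multi_tissue",
    "simulate_methylation",
    "simulate_metabolome_casecohort",
]

CATEGORIES = (
    "escaped_placenta_specific",
    "escaped_common",
    "inactivated",
    "male_biased",
)


def _default_meth_beta_means() -> dict[str, float]:
    # promoter methylation means: in females one X is silenced and
    # methylated at inactivated promoters; escaped promoters stay low in
    # both sexes; male-biased promoters behave like inactivated ones
    return {
        "inactivated_female": 0.55,
        "inactivated_male": 0.15,
        "escaped": 0.15,
        "male_biased_female": 0.55,
        "male_biased_male": 0.15,
    }


def _default_outcome_coefficients() -> dict[str, dict[str, float]]:
    # per-1-SD log-odds on the target metabolite at the last visit.
    # The slope magnitude 0.61 is calibrated numerically so the
    # model-implied case proportion ratio between the extreme noncase
    # quintiles of the measured metabolite is 5-fold (accounting for
    # within-quintile averaging and ~0.975 measurement reliability);
    # intercepts are solved so marginal prevalences give ~134 and ~162
    # cases in a 4,177-woman cohort.
    return {
        "PE": {"intercept": -3.58, "slope": 0.61},
        "FGR": {"intercept": -3.38, "slope": -0.61},
    }


@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults reflect the cohort being emulated: 64 female / 67 male
    placentas for expression, a 4,177-woman cohort with a 325-woman
    random subcohort for the case-cohort metabolite analysis, serum
    sampling at 12/20/28/36 wkGA, an 837-metabolite panel run in batches
    of 36, and 2 sex-affected metabolites.  Quantities the study design
    does not pin down (negative-binomial dispersion, methylation beta
    means, batch SD, detection-limit quantile) are field-realistic
    choices documented in the methods note.
    """

    # expression
    n_female: int = 64
    n_male: int = 67
    n_autosomal: int = 2000
    n_x_genes: int = 300
    n_y_genes: int = 20
    escape_fraction: float = 0.15
    common_escape_fraction: float = 0.53  # of escapees, biased in >=1 other tissue
    escape_fold: float = 1.5
    male_bias_fraction: float = 0.04
    male_bias_fold: float = 1.5
    nb_dispersion: float = 0.05
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    # methylation
    meth_samples_per_sex: int = 2
    meth_coverage_mean: float = 30.0
    meth_cpgs_per_promoter_mean: float = 10.0
    meth_beta_means: dict[str, float] = field(
        default_factory=_default_meth_beta_means)
    meth_overdispersion: float = 0.05
    # metabolome / case-cohort
    n_subjects: int = 4177
    visit_schedule: tuple[int, ...] = (12, 20, 28, 36)
    n_metabolites: int = 837
    n_sex_affected_metabolites: int = 2
    sex_effect_size: float = 0.5
    batch_size: int = 36
    batch_sd: float = 0.2
    lod_quantile: float = 0.05
    outcome_logit_coefficients: dict[str, dict[str, float]] = field(
        default_factory=_default_outcome_coefficients)
    subcohort_fraction: float = 325.0 / 4177.0
    # shared
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_female": self.n_female, "n_male": self.n_male,
            "n_autosomal": self.n_autosomal, "n_x_genes": self.n_x_genes,
            "n_subjects": self.n_subjects, "n_metabolites": self.n_metabolites,
            "meth_samples_per_sex": self.meth_samples_per_sex,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"configuration error: {name} must be >= 1")
        if self.escape_fold <= 1.0:
            raise ValueError("configuration error: escape_fold must be > 1")
        for name in ("escape_fraction", "male_bias_fraction",
                     "common_escape_fraction", "subcohort_fraction",
                     "lod_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"configuration error: {name} outside [0, 1]")
        vs = tuple(self.visit_schedule)
        if any(b <= a for a, b in zip(vs, vs[1:])):
            raise ValueError(
                "configuration error: visit_schedule must be strictly increasing")
        self.visit_schedule = vs


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every generated dataset."""

    category: pd.Series | None = None          # X-gene id -> category
    annotation: pd.DataFrame | None = None     # gene annotation used
    common_bias_tissues: dict[str, list[int]] | None = None
    sex_affected_metabolites: dict[str, float] | None = None
    target_metabolite: str | None = None
    outcome_coefficients: dict[str, dict[str, float]] | None = None
    z_true: pd.Series | None = None            # subject -> latent exposure Z
    case_labels: pd.DataFrame | None = None    # subject -> PE/FGR truth

    def to_jsonable(self) -> dict:
        out: dict = {}
        if self.category is not None:
            out["category"] = self.category.to_dict()
        if self.sex_affected_metabolites is not None:
            out["sex_affected_metabolites"] = dict(self.sex_affected_metabolites)
        if self.target_metabolite is not None:
            out["target_metabolite"] = self.target_metabolite
        if self.outcome_coefficients is not None:
            out["outcome_coefficients"] = self.outcome_coefficients
        if self.case_labels is not None:
            out["case_labels"] = {
                c: self.case_labels[c].astype(int).to_dict()
                for c in self.case_labels.columns
            }
        return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _make_annotation(config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    ids, chroms, tss, strand = [], [], [], []
    per_chrom_counter: dict[str, int] = {}

    def add(gene_id: str, chrom: str) -> None:
        k = per_chrom_counter.get(chrom, 0)
        per_chrom_counter[chrom] = k + 1
        ids.append(gene_id)
        chroms.append(chrom)
        tss.append(5000 + 10_000 * k)
        strand.append("+" if (len(ids) % 2) else "-")

    for i in range(config.n_autosomal):
        add(f"GA{i + 1:05d}", f"chr{(i % 22) + 1}")
    for i in range(config.n_x_genes):
        add(f"GX{i + 1:05d}", "chrX")
    for i in range(config.n_y_genes):
        add(f"GY{i + 1:05d}", "chrY")
    return pd.DataFrame(
        {"gene_id": ids, "chromosome": chroms, "tss": tss, "strand": strand}
    )


def _plant_categories(config: SimulationConfig, x_ids: list[str],
                      rng: np.random.Generator) -> pd.Series:
    n = len(x_ids)
    u = rng.random(n)
    cat = np.full(n, "inactivated", dtype=object)
    esc = u < config.escape_fraction
    mb = (~esc) & (u < config.escape_fraction + config.male_bias_fraction)
    common = rng.random(n) < config.common_escape_fraction
    cat[esc & common] = "escaped_common"
    cat[esc & ~common] = "escaped_placenta_specific"
    cat[mb] = "male_biased"
    return pd.Series(cat, index=pd.Index(x_ids, name="gene_id"),
                     name="category")


def _known_status(category: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Prior-literature XCI labels: escapees are only partly 'known'."""
    status = np.empty(len(category), dtype=object)
    for i, c in enumerate(category):
        if c.startswith("escaped"):
            status[i] = rng.choice(
                ["escaped", "inactive", "variable", "unknown"],
                p=[0.40, 0.25, 0.15, 0.20])
        else:
            status[i] = rng.choice(
                ["inactive", "variable", "unknown"], p=[0.6, 0.1, 0.3])
    return pd.Series(status, index=category.index, name="known_xci_status")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _expression_means(config: SimulationConfig, annotation: pd.DataFrame,
                      category: pd.Series, base: np.ndarray,
                      female_biased_x: set[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene female and male mean expression given the planted truth."""
    mean_f = base.copy()
    mean_m = base.copy()
    chrom = annotation["chromosome"].to_numpy()
    gid = annotation["gene_id"].to_numpy()
    for i in range(len(gid)):
        if chrom[i] == "chrY":
            mean_f[i] = 0.0
        elif chrom[i] == "chrX":
            c = category.loc[gid[i]]
            if c in ("escaped_placenta_specific", "escaped_common"):
                if gid[i] in female_biased_x:
                    mean_f[i] = base[i] * config.escape_fold
            elif c == "male_biased":
                mean_m[i] = base[i] * config.male_bias_fold
    return mean_f, mean_m


def _sample_counts(config: SimulationConfig, annotation: pd.DataFrame,
                   mean_f: np.ndarray, mean_m: np.ndarray,
                   rng: np.random.Generator, tissue: str,
                   prefix: str) -> CountMatrix:
    nf, nm = config.n_female, config.n_male
    sample_ids = [f"{prefix}F{j + 1:03d}" for j in range(nf)] + \
                 [f"{prefix}M{j + 1:03d}" for j in range(nm)]
    sex = pd.Series(["F"] * nf + ["M"] * nm, index=sample_ids, name="sex")
    mu = np.concatenate(
        [np.repeat(mean_f[:, None], nf, axis=1),
         np.repeat(mean_m[:, None], nm, axis=1)], axis=1)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    df = pd.DataFrame(counts, index=annotation["gene_id"].to_numpy(),
                      columns=sample_ids)
    df.index.name = "gene_id"
    return CountMatrix(counts=df, sex=sex, tissue=tissue)


def simulate_expression(
    config: SimulationConfig, seed: int | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Generate a placental count matrix with planted XCI-escape truth.

    Autosomal genes and inactivated X genes are sex-balanced (dosage
    compensation); escaped X genes have female mean = ``escape_fold`` x
    male mean; male-biased X genes the reverse; Y-linked genes are
    expressed only in males.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    annotation = _make_annotation(config, rng)
    x_ids = list(annotation.loc[annotation["chromosome"] == "chrX", "gene_id"])
    category = _plant_categories(config, x_ids, rng)
    annotation["known_xci_status"] = "unknown"
    known = _known_status(category, rng)
    annotation = annotation.set_index("gene_id")
    annotation.loc[known.index, "known_xci_status"] = known
    annotation = annotation.reset_index()

    lo, hi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(annotation)))
    escapees = set(category.index[category.str.startswith("escaped")])
    mean_f, mean_m = _expression_means(config, annotation, category, base,
                                       female_biased_x=escapees)
    cm = _sample_counts(config, annotation, mean_f, mean_m, rng,
                        tissue="placenta", prefix="PL")
    truth = GroundTruth(category=category, annotation=annotation)
    return cm, truth


def simulate_multi_tissue(
    config: SimulationConfig, n_tissues: int, seed: int | None = None,
) -> tuple[CountMatrix, list[CountMatrix], GroundTruth]:
    """Placenta plus ``n_tissues`` comparison tissues.

    Placenta-specific escapees are sex-balanced in every non-placenta
    tissue; common escapees are female-biased in at least one comparison
    tissue (a random nonempty subset).  Returns
    ``(placenta, other_tissues, truth)`` with ``len(other_tissues) ==
    n_tissues``.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    base_seed = config.seed if seed is None else seed
    placenta, truth = simulate_expression(config, seed=base_seed)
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 1]))

    common = [g for g, c in truth.category.items() if c == "escaped_common"]
    bias_tissues: dict[str, list[int]] = {}
    for g in common:
        k = 1 + rng.binomial(n_tissues - 1, 0.3)
        bias_tissues[g] = sorted(
            rng.choice(n_tissues, size=min(k, n_tissues), replace=False).tolist())
    truth.common_bias_tissues = bias_tissues

    annotation = truth.annotation
    lo, hi = config.baseline_mean_range
    others: list[CountMatrix] = []
    for t in range(n_tissues):
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(annotation)))
        fb = {g for g, ts in bias_tissues.items() if t in ts}
        # in comparison tissues only the selected common escapees are
        # female-biased; male-biased genes are placental
        mean_f = base.copy()
        mean_m = base.copy()
        chrom = annotation["chromosome"].to_numpy()
        gid = annotation["gene_id"].to_numpy()
        for i in range(len(gid)):
            if chrom[i] == "chrY":
                mean_f[i] = 0.0
            elif gid[i] in fb:
                mean_f[i] = base[i] * config.escape_fold
        others.append(
            _sample_counts(config, annotation, mean_f, mean_m, rng,
                           tissue=f"tissue{t + 1:02d}", prefix=f"T{t + 1:02d}"))
    return placenta, others, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _beta_binomial(rng: np.random.Generator, mean: np.ndarray,
                   rho: float, coverage: np.ndarray) -> np.ndarray:
    """Beta-binomial methylated counts with mean `mean`, overdispersion rho."""
    mean = np.clip(mean, 1e-6, 1.0 - 1e-6)
    if rho <= 0:
        return rng.binomial(coverage, mean)
    conc = 1.0 / rho - 1.0
    p = rng.beta(mean * conc, (1.0 - mean) * conc)
    return rng.binomial(coverage, p)


def simulate_methylation(
    config: SimulationConfig, ground_truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-CpG methylation calls for the X-gene promoters.

    Emits a long DataFrame (chromosome, position, methylated_reads,
    total_reads, sample_id, sex) with category-specific promoter
    methylation means: inactivated promoters female-high / male-low,
    escaped promoters low in both sexes, male-biased promoters
    female-high.  Coverage is Poisson around ``meth_coverage_mean`` and
    at least 4 CpGs are placed per promoter.
    """
    if ground_truth.category is None or ground_truth.annotation is None:
        raise ValueError("ground truth with categories and annotation required")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed if seed is None else seed, 2]))
    ann = ground_truth.annotation.set_index("gene_id")
    means = config.meth_beta_means
    samples = (
        [(f"ME_F{j + 1}", "F") for j in range(config.meth_samples_per_sex)]
        + [(f"ME_M{j + 1}", "M") for j in range(config.meth_samples_per_sex)]
    )
    rows: list[pd.DataFrame] = []
    for gene_id, cat in ground_truth.category.items():
        tss = int(ann.loc[gene_id, "tss"])
        chrom = str(ann.loc[gene_id, "chromosome"])
        n_cpgs = max(4, int(rng.poisson(config.meth_cpgs_per_promoter_mean)))
        lo = max(0, tss - 1000)
        pos = np.sort(rng.choice(np.arange(lo, tss + 1000), size=n_cpgs,
                                 replace=False))
        for sample_id, sex in samples:
            if cat in ("escaped_placenta_specific", "escaped_common"):
                m = means["escaped"]
            elif cat == "male_biased":
                m = means[f"male_biased_{'female' if sex == 'F' else 'male'}"]
            else:
                m = means[f"inactivated_{'female' if sex == 'F' else 'male'}"]
            cov = rng.poisson(config.meth_coverage_mean, size=n_cpgs)
            meth = _beta_binomial(rng, np.full(n_cpgs, m),
                                  config.meth_overdispersion, cov)
            rows.append(pd.DataFrame({
                "chromosome": chrom, "position": pos,
                "methylated_reads": meth, "total_reads": cov,
                "sample_id": sample_id, "sex": sex,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# metabolome + case-cohort
# ---------------------------------------------------------------------------

_SUBJECT_SD = np.sqrt(0.5)   # between-subject intercept SD (log scale)
_RESID_SD = np.sqrt(0.5)     # within-subject residual SD (log scale)


def _sex_effect(config: SimulationConfig, effect: float,
                ga: np.ndarray) -> np.ndarray:
    """Sex effect per visit: the full planted effect at the first visit,
    plus a sex-by-gestation interaction growing to +50% by the last."""
    ga0, ga1 = config.visit_schedule[0], config.visit_schedule[-1]
    ramp = (ga - ga0) / (ga1 - ga0)
    return effect * (1.0 + 0.5 * ramp)


def simulate_metabolome_casecohort(
    config: SimulationConfig, seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the serum metabolome and the case-cohort design.

    Outcomes are generated at full-cohort level from a logistic model on
    the target metabolite's standardized last-visit log level, then
    case-cohort sampling is applied (all term PE/FGR cases + a random
    subcohort), so the inverse-sampling-fraction weight is recoverable
    from the design.  Metabolite records are materialised for the
    measured subjects only (cases and subcohort members).

    Returns ``(metabolite_table, design, truth)``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3]))
    n = config.n_subjects
    visits = np.array(config.visit_schedule, dtype=float)
    nv = len(visits)
    subjects = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")
    female = rng.random(n) < 0.5
    sex = np.where(female, "F", "M")

    metab_ids = [f"M{j + 1:04d}" for j in range(config.n_metabolites)]
    n_aff = min(config.n_sex_affected_metabolites, config.n_metabolites)
    # alternating signs; the first (target) metabolite is higher in
    # female-fetus pregnancies
    sex_effects = {
        metab_ids[j]: config.sex_effect_size * (1 if j % 2 == 0 else -1)
        for j in range(n_aff)
    }
    target = metab_ids[0]

    # --- target metabolite latent trajectory for the FULL cohort -----------
    ga_c = (visits - visits.mean()) / (visits[-1] - visits[0])
    slope_t = rng.normal(0.0, 0.3)
    b_subj_t = rng.normal(0.0, _SUBJECT_SD, size=n)
    eps_t = rng.normal(0.0, _RESID_SD, size=(n, nv))
    sexeff_t = _sex_effect(config, sex_effects.get(target, 0.0), visits)
    log_target = (slope_t * ga_c[None, :] + b_subj_t[:, None]
                  + female[:, None] * sexeff_t[None, :] + eps_t)
    last = log_target[:, -1]
    z_true = (last - last.mean()) / last.std()

    # --- outcomes at full-cohort level --------------------------------------
    coefs = config.outcome_logit_coefficients
    def _draw(outcome: str) -> np.ndarray:
        c = coefs[outcome]
        p = 1.0 / (1.0 + np.exp(-(c["intercept"] + c["slope"] * z_true)))
        return rng.random(n) < p

    pe = _draw("PE")
    fgr = _draw("FGR")

    flags = {k: np.zeros(n, dtype=bool) for k in "abcdefghij"}
    term = np.ones(n, dtype=bool)
    # PE cases split into case groups f/h/i (severe nonsuperimposed,
    # severe superimposed, nonsevere nonsuperimposed; all term)
    pe_idx = np.where(pe)[0]
    pe_grp = rng.choice(["f", "h", "i"], size=len(pe_idx), p=[0.52, 0.17, 0.31])
    for g in "fhi":
        flags[g][pe_idx[pe_grp == g]] = True
    # FGR strata: (BW 3rd-10th & ACGVD1) -> g; (<3rd & ACGVD2-10) -> j;
    # (<3rd & ACGVD1) -> g and j
    fgr_idx = np.where(fgr)[0]
    fgr_strat = rng.choice(["g_only", "j_only", "g_and_j"], size=len(fgr_idx),
                           p=[0.32, 0.49, 0.19])
    flags["g"][fgr_idx[(fgr_strat == "g_only") | (fgr_strat == "g_and_j")]] = True
    flags["j"][fgr_idx[(fgr_strat == "j_only") | (fgr_strat == "g_and_j")]] = True
    # other case groups among remaining subjects; a/b/e are preterm
    rest = ~(pe | fgr)
    other = rest & (rng.random(n) < 0.06)
    other_grp = rng.choice(list("abcde"), size=int(other.sum()))
    oi = np.where(other)[0]
    for g in "abcde":
        flags[g][oi[other_grp == g]] = True
    term[flags["a"] | flags["b"] | flags["e"]] = False

    in_subcohort = rng.random(n) < config.subcohort_fraction

    # adjustment covariates
    log_sflt1_plgf = rng.normal(0.0, 1.0, n) + 0.9 * pe + 0.4 * fgr
    design = pd.DataFrame({
        "fetal_sex": sex,
        **{f"flag_{g}": flags[g] for g in "abcdefghij"},
        "term_delivery": term,
        "in_subcohort": in_subcohort,
        "maternal_age": rng.normal(30.2, 4.3, n).round(1),
        "height": rng.normal(164.5, 6.8, n).round(1),
        "bmi": np.exp(rng.normal(np.log(24.3), 0.17, n)).round(1),
        "ethnicity": rng.choice(["white", "asian", "black", "other"], size=n,
                                p=[0.93, 0.03, 0.02, 0.02]),
        "smoking": rng.random(n) < 0.05,
        "log_sflt1_plgf": log_sflt1_plgf.round(4),
    }, index=subjects)

    # --- metabolite panel for measured subjects ------------------------------
    measured = in_subcohort | pe | fgr
    mi = np.where(measured)[0]
    nm_subj = len(mi)
    n_met = config.n_metabolites

    # run-day batches hold the measured samples only, interleaving cases
    # and noncases so every batch has similar case/control proportions
    is_case = (pe | fgr)[mi]
    ci = rng.permutation(np.where(is_case)[0])
    ni = rng.permutation(np.where(~is_case)[0])
    pos = np.concatenate([(np.arange(len(ci)) + 0.5) / max(len(ci), 1),
                          (np.arange(len(ni)) + 0.5) / max(len(ni), 1)])
    order = np.concatenate([ci, ni])[np.argsort(pos, kind="stable")]
    batch_of_measured = np.empty(nm_subj, dtype=int)
    batch_of_measured[order] = np.arange(nm_subj) // config.batch_size
    n_batches = int(batch_of_measured.max()) + 1

    mu_m = rng.normal(0.0, 0.5, n_met)
    slope_m = rng.normal(0.0, 0.3, n_met)
    slope_m[0] = slope_t
    scale_m = np.exp(rng.normal(11.0, 1.0, n_met))
    batch_fac = np.exp(rng.normal(0.0, config.batch_sd, (n_batches, n_met)))

    b_subj = rng.normal(0.0, _SUBJECT_SD, size=(nm_subj, n_met))
    b_subj[:, 0] = b_subj_t[mi]
    eps = rng.normal(0.0, _RESID_SD, size=(nm_subj, nv, n_met))
    eps[:, :, 0] = eps_t[mi]

    log_ab = (mu_m[None, None, :]
              + slope_m[None, None, :] * ga_c[None, :, None]
              + b_subj[:, None, :]
              + eps)
    fem_meas = female[mi]
    for j, (mid, eff) in enumerate(sex_effects.items()):
        se = _sex_effect(config, eff, visits)
        log_ab[:, :, j] += fem_meas[:, None] * se[None, :]

    raw = np.exp(log_ab) * scale_m[None, None, :] \
        * batch_fac[batch_of_measured][:, None, :]
    # left-censoring at the per-metabolite detection-limit quantile
    if config.lod_quantile > 0:
        lod = np.quantile(raw.reshape(-1, n_met), config.lod_quantile, axis=0)
        raw = np.where(raw < lod[None, None, :], np.nan, raw)

    table = pd.DataFrame({
        "subject_id": np.repeat(subjects[mi], nv * n_met),
        "visit_wkGA": np.tile(np.repeat(visits.astype(int), n_met), nm_subj),
        "run_day": np.repeat(batch_of_measured, nv * n_met),
        "metabolite_id": np.tile(metab_ids, nm_subj * nv),
        "raw_ion_count": raw.reshape(-1),
        "fetal_sex": np.repeat(sex[mi], nv * n_met),
    })

    truth = GroundTruth(
        sex_affected_metabolites=sex_effects,
        target_metabolite=target,
        outcome_coefficients={k: dict(v) for k, v in coefs.items()},
        z_true=pd.Series(z_true, index=subjects, name="z_true"),
        case_labels=pd.DataFrame({"PE": pe, "FGR": fgr}, index=subjects),
    )
    return table, design, truth
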