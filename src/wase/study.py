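"""End-to-end study protocols.

Orchestrates the full simulation study: cohort generation, scoring, linkage
calibration, outcome simulation, full-cohort diagnostics with bootstrap CIs,
stratified 5-fold cross-validation, subgroup analysis with DeLong AUC
comparisons, Hosmer-Lemeshow calibration, and the weight-sensitivity
analysis.  Outcomes are simulated exactly once per replicate; threshold
re-derivation and weight perturbation never re-draw injuries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import (
    DeLongResult,
    MetricReport,
    bootstrap_ci,
    confusion_metrics,
    delong_test,
    hosmer_lemeshow,
    roc_auc,
    roc_curve,
    youden_threshold,
)
from .model import COMPONENTS, DEFAULT_WEIGHTS, WeightVector
from .simulate import (
    Cohort,
    LinkageConfig,
    PopulationConfig,
    calibrate_linkage,
    generate_cohort,
    score_cohort,
    simulate_injuries,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "CVResult",
    "SubgroupResult",
    "SensitivityResult",
    "run_full_study",
    "run_cross_validation",
    "run_subgroup_analysis",
    "run_weight_sensitivity",
]

AGE_BANDS = (("18-25", 18.0, 25.0), ("26-35", 25.0, 35.0))  # (label, lo, hi]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce the full study."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    weights: WeightVector = DEFAULT_WEIGHTS
    target_prevalence: float = 0.20
    target_auc: float = 0.89
    cv_folds: int = 5
    bootstrap_B: int = 2000
    hl_bins: int = 10
    sensitivity_delta: float = 0.05
    n_weight_configs: int = 100
    replicates: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    def to_dict(self) -> dict:
        return {
            "population": self.population.to_dict(),
            "weights": dict(zip(COMPONENTS, self.weights.as_tuple())),
            "target_prevalence": self.target_prevalence,
            "target_auc": self.target_auc,
            "cv_folds": self.cv_folds,
            "bootstrap_B": self.bootstrap_B,
            "hl_bins": self.hl_bins,
            "sensitivity_delta": self.sensitivity_delta,
            "n_weight_configs": self.n_weight_configs,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "population" in d:
            d["population"] = PopulationConfig.from_dict(d["population"])
        if "weights" in d:
            w = d["weights"]
            d["weights"] = WeightVector(**{k: w[k] for k in COMPONENTS})
        return cls(**d)


@dataclass
class CVResult:
    folds: pd.DataFrame  # fold, n, auc, sensitivity, specificity, accuracy, threshold
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "folds": self.folds.to_dict(orient="records"),
            "mean": self.mean,
            "sd": self.sd,
        }


@dataclass
class SubgroupResult:
    metrics: dict[str, MetricReport | None]  # None when single-class subgroup
    sizes: dict[str, int]
    comparisons: dict[str, DeLongResult]

    def to_dict(self) -> dict:
        return {
            "metrics": {
                k: (m.to_dict() if m is not None else None)
                for k, m in self.metrics.items()
            },
            "sizes": self.sizes,
            "comparisons": {k: c.to_dict() for k, c in self.comparisons.items()},
        }


@dataclass
class SensitivityResult:
    baseline_auc: float
    single: pd.DataFrame  # component, direction, auc, delta_auc
    random: pd.DataFrame  # config, auc, delta_auc
    max_abs_single: float
    max_abs_random: float

    def to_dict(self) -> dict:
        return {
            "baseline_auc": self.baseline_auc,
            "single": self.single.to_dict(orient="records"),
            "random": self.random.to_dict(orient="records"),
            "max_abs_single": self.max_abs_single,
            "max_abs_random": self.max_abs_random,
        }


@dataclass
class StudyReport:
    """All study outputs for one configuration."""

    config: StudyConfig
    population_summary: dict
    linkage: LinkageConfig
    full_cohort: MetricReport
    cv: CVResult
    subgroups: SubgroupResult
    calibration: dict
    sensitivity: SensitivityResult
    replicate_table: pd.DataFrame  # one row of headline metrics per replicate
    replicate_means: dict[str, float]
    cohort: Cohort | None = None  # primary-replicate cohort (not serialized)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "population_summary": self.population_summary,
            "linkage": self.linkage.to_dict(),
            "full_cohort": self.full_cohort.to_dict(),
            "cv": self.cv.to_dict(),
            "subgroups": self.subgroups.to_dict(),
            "calibration": self.calibration,
            "sensitivity": self.sensitivity.to_dict(),
            "replicates": self.replicate_table.to_dict(orient="records"),
            "replicate_means": self.replicate_means,
        }

    def to_markdown(self) -> str:
        return _report_markdown(self)


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    """Primary replicate uses the master seed itself; the rest use derived
    streams (kept below 2**31 so they remain valid seeds everywhere)."""
    if replicates == 1:
        return [seed]
    derived = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    return [seed] + [int(s) for s in derived[1:]]


def _simulate_replicate(
    config: StudyConfig, rep_seed: int
) -> tuple[Cohort, LinkageConfig]:
    pop = replace(config.population, seed=rep_seed)
    cohort = score_cohort(generate_cohort(pop), config.weights)
    linkage = calibrate_linkage(
        cohort, config.target_prevalence, config.target_auc
    )
    return simulate_injuries(cohort, linkage), linkage


def run_cross_validation(
    cohort: Cohort, k: int = 5, seed: int | None = None
) -> CVResult:
    """Stratified k-fold cross-validation of the fixed scoring formula.

    The formula itself has no trainable parameters; "training" re-derives
    the Youden operating threshold on the k-1 training folds, which is then
    applied to the held-out fold.  Folds are stratified by injury status
    with seed-controlled shuffling.
    """
    scores = cohort.scores()
    labels = cohort.labels()
    n_cases = int(labels.sum())
    if k < 2 or k > n_cases or k > len(labels) - n_cases:
        raise ValueError(f"infeasible fold count k={k} for {n_cases} cases")
    rng = np.random.default_rng(seed)
    case_idx = rng.permutation(np.flatnonzero(labels == 1))
    ctrl_idx = rng.permutation(np.flatnonzero(labels == 0))
    case_folds = np.array_split(case_idx, k)
    ctrl_folds = np.array_split(ctrl_idx, k)

    rows = []
    for i in range(k):
        test = np.concatenate((case_folds[i], ctrl_folds[i]))
        train = np.concatenate(
            [case_folds[j] for j in range(k) if j != i]
            + [ctrl_folds[j] for j in range(k) if j != i]
        )
        if labels[test].min() == labels[test].max():
            raise ValueError(f"fold {i + 1} contains a single class; reduce k")
        thr = youden_threshold(roc_curve(scores[train], labels[train]))
        m = confusion_metrics(scores[test], labels[test], thr)
        rows.append(
            {
                "fold": i + 1,
                "n": len(test),
                "auc": m.auc,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "threshold": thr,
            }
        )
    folds = pd.DataFrame(rows)
    metric_cols = ["auc", "sensitivity", "specificity", "accuracy"]
    mean = {c: float(folds[c].mean()) for c in metric_cols}
    sd = {c: float(folds[c].std(ddof=1)) for c in metric_cols}
    return CVResult(folds=folds, mean=mean, sd=sd)


def _subgroup_masks(cohort: Cohort) -> dict[str, np.ndarray]:
    df = cohort.df
    masks: dict[str, np.ndarray] = {}
    for sex in ("male", "female"):
        masks[sex] = (df["sex"] == sex).to_numpy()
    age = df["age"].to_numpy()
    lo0 = AGE_BANDS[0][1]
    masks[AGE_BANDS[0][0]] = (age >= lo0) & (age <= AGE_BANDS[0][2])
    masks[AGE_BANDS[1][0]] = (age > AGE_BANDS[1][1]) & (age <= AGE_BANDS[1][2])
    for sport in ("running", "jumping", "cutting"):
        masks[sport] = (df["sport"] == sport).to_numpy()
    return masks


def run_subgroup_analysis(
    cohort: Cohort, threshold: float | None = None
) -> SubgroupResult:
    """Per-subgroup metrics at the full-cohort Youden threshold, with
    unpaired DeLong AUC comparisons between disjoint subgroups.

    The three sports are compared pairwise; the headline "sport" comparison
    is the pair with the largest AUC gap (max vs min AUC).
    """
    scores = cohort.scores()
    labels = cohort.labels()
    if threshold is None:
        threshold = youden_threshold(roc_curve(scores, labels))
    masks = _subgroup_masks(cohort)

    metrics: dict[str, MetricReport | None] = {}
    sizes: dict[str, int] = {}
    for name, mask in masks.items():
        sizes[name] = int(mask.sum())
        sub_y = labels[mask]
        if mask.sum() == 0 or sub_y.min() == sub_y.max():
            metrics[name] = None
            continue
        metrics[name] = confusion_metrics(scores[mask], sub_y, threshold)

    comparisons: dict[str, DeLongResult] = {}

    def compare(key: str, a: str, b: str) -> None:
        if metrics.get(a) is not None and metrics.get(b) is not None:
            ma, mb = masks[a], masks[b]
            comparisons[key] = delong_test(
                scores[ma], labels[ma], scores[mb], labels[mb]
            )

    compare("male_vs_female", "male", "female")
    compare("age_18-25_vs_26-35", AGE_BANDS[0][0], AGE_BANDS[1][0])
    sport_names = [s for s in ("running", "jumping", "cutting") if metrics.get(s)]
    for i, a in enumerate(sport_names):
        for b in sport_names[i + 1 :]:
            compare(f"{a}_vs_{b}", a, b)
    if len(sport_names) >= 2:
        best = max(sport_names, key=lambda s: metrics[s].auc)
        worst = min(sport_names, key=lambda s: metrics[s].auc)
        if best != worst:
            compare("sport_max_vs_min", best, worst)

    return SubgroupResult(metrics=metrics, sizes=sizes, comparisons=comparisons)


def _weights_from_array(w: np.ndarray) -> WeightVector:
    return WeightVector(**dict(zip(COMPONENTS, (float(x) for x in w))))


def run_weight_sensitivity(
    cohort: Cohort,
    base_weights: WeightVector = DEFAULT_WEIGHTS,
    delta: float = 0.05,
    n_configs: int = 100,
    seed: int | None = None,
) -> SensitivityResult:
    """Re-score a fixed cohort (fixed outcomes) under perturbed weights.

    Each of the four weights is shifted by +/-delta and the vector is
    renormalised to sum to 1; additionally ``n_configs`` random weight
    vectors are drawn uniformly in the +/-delta box around the defaults and
    renormalised.  Reported deltas are against the base-weights AUC.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    labels = cohort.labels()
    x = cohort.df[list(COMPONENTS)].to_numpy(dtype=float)
    base = np.asarray(base_weights.as_tuple())

    def auc_for(w: np.ndarray) -> float:
        return roc_auc(np.clip(x @ w, 0.0, 1.0), labels)

    baseline = auc_for(base)
    rows = []
    for i, name in enumerate(COMPONENTS):
        for sign, tag in ((+1.0, "+"), (-1.0, "-")):
            w = base.copy()
            w[i] += sign * delta
            if w[i] <= 0 or w[i] >= 1:
                raise ValueError(
                    f"perturbing {name} by {tag}{delta} leaves the weight simplex"
                )
            w = w / w.sum()
            a = auc_for(w)
            rows.append(
                {
                    "component": name,
                    "direction": tag,
                    "weights": [float(v) for v in w],
                    "auc": a,
                    "delta_auc": a - baseline,
                }
            )
    single = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    rand_rows = []
    for c in range(n_configs):
        w = rng.uniform(base - delta, base + delta)
        w = np.clip(w, 1e-6, None)
        w = w / w.sum()
        a = auc_for(w)
        rand_rows.append({"config": c + 1, "auc": a, "delta_auc": a - baseline})
    random_df = pd.DataFrame(rand_rows)

    return SensitivityResult(
        baseline_auc=baseline,
        single=single,
        random=random_df,
        max_abs_single=float(single["delta_auc"].abs().max()),
        max_abs_random=(
            float(random_df["delta_auc"].abs().max()) if n_configs else 0.0
        ),
    )


def _population_summary(cohort: Cohort) -> dict:
    df = cohort.df
    out = {
        "n": len(df),
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)),
        "sex_counts": df["sex"].value_counts().to_dict(),
        "sport_counts": df["sport"].value_counts().to_dict(),
        "train_hours_mean": float(df["train_hours"].mean()),
        "train_hours_sd": float(df["train_hours"].std(ddof=1)),
        "component_ranges": {
            c: [float(df[c].min()), float(df[c].max())] for c in COMPONENTS
        },
    }
    injured = df["injured"]
    if not injured.isna().any():
        out["n_injured"] = int(injured.sum())
        out["injury_rate"] = float(injured.mean())
    return out


def run_full_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the complete study; a pure function of (config, seed).

    The primary replicate (master seed) carries the full battery: bootstrap
    CIs, cross-validation, subgroup and calibration analyses, and the
    weight-sensitivity sweep on its fixed cohort and outcomes.  Additional
    replicates re-run the generate/calibrate/simulate/evaluate pipeline
    under derived seeds, and headline metrics are reported as replicate
    means.
    """
    seeds = _replicate_seeds(config.seed, config.replicates)
    rep_rows = []
    primary: tuple[Cohort, LinkageConfig] | None = None
    for r, rep_seed in enumerate(seeds):
        cohort, linkage = _simulate_replicate(config, rep_seed)
        scores, labels = cohort.scores(), cohort.labels()
        thr = youden_threshold(roc_curve(scores, labels))
        m = confusion_metrics(scores, labels, thr)
        cv = run_cross_validation(cohort, config.cv_folds, seed=rep_seed)
        rep_rows.append(
            {
                "replicate": r + 1,
                "seed": rep_seed,
                "prevalence": float(labels.mean()),
                "auc": m.auc,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "accuracy": m.accuracy,
                "cv_mean_auc": cv.mean["auc"],
                "threshold": thr,
            }
        )
        if r == 0:
            primary = (cohort, linkage)
            primary_metrics, primary_cv, primary_thr = m, cv, thr

    assert primary is not None
    cohort, linkage = primary
    scores, labels = cohort.scores(), cohort.labels()

    # bootstrap CIs on the primary replicate (threshold held fixed)
    thr = primary_thr
    stat_fns = {
        "auc": lambda s, y: roc_auc(s, y),
        "sensitivity": lambda s, y: confusion_metrics(s, y, thr).sensitivity,
        "specificity": lambda s, y: confusion_metrics(s, y, thr).specificity,
        "ppv": lambda s, y: confusion_metrics(s, y, thr).ppv,
        "npv": lambda s, y: confusion_metrics(s, y, thr).npv,
        "accuracy": lambda s, y: confusion_metrics(s, y, thr).accuracy,
    }
    ci_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(stat_fns) + 1
    ) % (2**31)
    for (name, fn), s in zip(stat_fns.items(), ci_seeds):
        primary_metrics.ci[name] = bootstrap_ci(
            fn, scores, labels, B=config.bootstrap_B, seed=int(s)
        )

    subgroups = run_subgroup_analysis(cohort, threshold=thr)
    hl = hosmer_lemeshow(
        cohort.df["p_injury"].to_numpy(), labels, g=config.hl_bins
    )
    sensitivity = run_weight_sensitivity(
        cohort,
        config.weights,
        delta=config.sensitivity_delta,
        n_configs=config.n_weight_configs,
        seed=int(ci_seeds[-1]),
    )

    replicate_table = pd.DataFrame(rep_rows)
    mean_cols = [
        "prevalence",
        "auc",
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "accuracy",
        "cv_mean_auc",
    ]
    replicate_means = {c: float(replicate_table[c].mean()) for c in mean_cols}

    return StudyReport(
        config=config,
        population_summary=_population_summary(cohort),
        linkage=linkage,
        full_cohort=primary_metrics,
        cv=primary_cv,
        subgroups=subgroups,
        calibration=hl.to_dict(),
        sensitivity=sensitivity,
        replicate_table=replicate_table,
        replicate_means=replicate_means,
        cohort=cohort,
    )


def _fmt(x, nd: int = 3) -> str:
    if x is None:
        return "—"
    return f"{x:.{nd}f}"


def _report_markdown(report: StudyReport) -> str:
    """Human-readable study report (population, performance, CV, subgroups)."""
    pop = report.population_summary
    lines = ["# Simulation study report", ""]
    lines += ["## Population", ""]
    lines += ["| Characteristic | Value |", "|---|---|"]
    lines.append(f"| Sample size | {pop['n']} |")
    lines.append(f"| Age (years) | {pop['age_mean']:.1f} ± {pop['age_sd']:.1f} |")
    sexes = ", ".join(f"{k}: {v}" for k, v in sorted(pop["sex_counts"].items()))
    lines.append(f"| Sex | {sexes} |")
    sports = ", ".join(f"{k}: {v}" for k, v in sorted(pop["sport_counts"].items()))
    lines.append(f"| Sport | {sports} |")
    lines.append(
        f"| Training hours/week | {pop['train_hours_mean']:.1f} ± "
        f"{pop['train_hours_sd']:.1f} |"
    )
    if "injury_rate" in pop:
        lines.append(
            f"| Injuries | {pop['n_injured']} ({100 * pop['injury_rate']:.1f}%) |"
        )
    m = report.full_cohort
    lines += ["", "## Full-cohort performance", ""]
    lines += ["| Metric | Value | 95% CI |", "|---|---|---|"]
    for name in ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy"):
        ci = m.ci.get(name)
        ci_s = f"{ci[0]:.3f}–{ci[1]:.3f}" if ci else "—"
        lines.append(f"| {name} | {_fmt(getattr(m, name))} | {ci_s} |")
    lines.append(f"| threshold (Youden) | {_fmt(m.threshold)} | — |")
    lines += ["", "## Cross-validation", ""]
    lines += [
        "| Fold | AUC | Sensitivity | Specificity | Accuracy |",
        "|---|---|---|---|---|",
    ]
    for _, row in report.cv.folds.iterrows():
        lines.append(
            f"| {int(row['fold'])} | {_fmt(row['auc'])} | {_fmt(row['sensitivity'])}"
            f" | {_fmt(row['specificity'])} | {_fmt(row['accuracy'])} |"
        )
    mean, sd = report.cv.mean, report.cv.sd
    lines.append(
        f"| mean ± SD | {mean['auc']:.3f} ± {sd['auc']:.3f} | "
        f"{mean['sensitivity']:.3f} ± {sd['sensitivity']:.3f} | "
        f"{mean['specificity']:.3f} ± {sd['specificity']:.3f} | "
        f"{mean['accuracy']:.3f} ± {sd['accuracy']:.3f} |"
    )
    lines += ["", "## Subgroups", ""]
    lines += ["| Subgroup | N | AUC | Sensitivity | Specificity |", "|---|---|---|---|---|"]
    for name, sm in report.subgroups.metrics.items():
        if sm is None:
            lines.append(f"| {name} | {report.subgroups.sizes[name]} | — | — | — |")
        else:
            lines.append(
                f"| {name} | {report.subgroups.sizes[name]} | {_fmt(sm.auc)} | "
                f"{_fmt(sm.sensitivity)} | {_fmt(sm.specificity)} |"
            )
    lines += ["", "| Comparison | ΔAUC | z | p |", "|---|---|---|---|"]
    for key, cmp_ in report.subgroups.comparisons.items():
        lines.append(
            f"| {key} | {cmp_.auc_a - cmp_.auc_b:+.3f} | {cmp_.z:.2f} | "
            f"{cmp_.p_value:.2f} |"
        )
    cal = report.calibration
    lines += [
        "",
        "## Calibration",
        "",
        f"Hosmer–Lemeshow χ² = {cal['chi2']:.2f}, df = {cal['df']}, "
        f"p = {cal['p_value']:.2f}",
    ]
    sens = report.sensitivity
    lines += [
        "",
        "## Weight sensitivity",
        "",
        f"Baseline AUC {sens.baseline_auc:.3f}; max |ΔAUC| over ±"
        f"{report.config.sensitivity_delta} single-weight perturbations: "
        f"{sens.max_abs_single:.4f}; over {len(sens.random)} random "
        f"configurations: {sens.max_abs_random:.4f}",
    ]
    if report.config.replicates > 1:
        rm = report.replicate_means
        lines += [
            "",
            f"## Replicate means ({report.config.replicates} seeds)",
            "",
            "| prevalence | AUC | sensitivity | specificity | accuracy | CV mean AUC |",
            "|---|---|---|---|---|---|",
            f"| {rm['prevalence']:.3f} | {rm['auc']:.3f} | {rm['sensitivity']:.3f} "
            f"| {rm['specificity']:.3f} | {rm['accuracy']:.3f} "
            f"| {rm['cv_mean_auc']:.3f} |",
        ]
    lines.append("")
    return "\n".join(lines)
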