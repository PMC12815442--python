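"""Virtual-cohort simulator and injury linkage.

Generates a cohort of virtual athletes in five stages:

1. stratified demographics (sex, sport) with exact counts, plus truncated
   normal age and weekly training hours;
2. true biomechanical components drawn from a correlated 4-variate normal,
   rejection-sampled into the observed component ranges;
3. multiplicative Gaussian measurement noise (5% CV by default), re-drawn
   per element until it respects the same ranges;
4. composite scoring (cross-sectional, Omega = 1);
5. injury outcomes through a logistic linkage on the standardised score,
   calibrated so the cohort hits a target injury prevalence and a target
   expected AUC.

Randomness discipline: one master seed spawns named substreams
(demographics, components, noise, outcomes), so adding a stage never
perturbs the draws of an earlier one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .model import COMPONENTS, DEFAULT_WEIGHTS, WeightVector

__all__ = [
    "PopulationConfig",
    "LinkageConfig",
    "Cohort",
    "DEFAULT_CORRELATION",
    "build_covariance",
    "stratified_counts",
    "generate_cohort",
    "score_cohort",
    "expected_auc",
    "calibrate_linkage",
    "simulate_injuries",
]

SEXES = ("male", "female")
SPORTS = ("running", "jumping", "cutting")

#: default inter-component correlations (FV, TA, LD, BA order), chosen to
#: span the empirically reported 0.25-0.65 range; positive definite
DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.45, 0.35, 0.55],
        [0.45, 1.00, 0.25, 0.65],
        [0.35, 0.25, 1.00, 0.30],
        [0.55, 0.65, 0.30, 1.00],
    ]
)


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the virtual athletic population.

    Defaults reproduce the reference simulation study: 1,000 athletes, age
    24.5 +/- 5.2 y in [18, 35], balanced sex, 40/30/30 running/jumping/
    cutting, 8.5 +/- 3.1 weekly training hours, component means/SDs
    (0.15/0.04, 0.08/0.03, 0.12/0.05, 0.10/0.04) truncated to the observed
    ranges, 5% CV measurement noise, master seed 42.
    """

    n: int = 1000
    age_mean: float = 24.5
    age_sd: float = 5.2
    age_bounds: tuple[float, float] = (18.0, 35.0)
    sex_split: float = 0.5  # proportion male
    sport_props: tuple[float, float, float] = (0.4, 0.3, 0.3)
    train_mean: float = 8.5
    train_sd: float = 3.1
    component_means: tuple[float, ...] = (0.15, 0.08, 0.12, 0.10)
    component_sds: tuple[float, ...] = (0.04, 0.03, 0.05, 0.04)
    component_bounds: tuple[tuple[float, float], ...] = (
        (0.08, 0.25),
        (0.05, 0.20),
        (0.10, 0.28),
        (0.06, 0.22),
    )
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    noise_cv: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 <= self.sex_split <= 1.0:
            raise ValueError("sex_split must be in [0, 1]")
        if abs(sum(self.sport_props) - 1.0) > 1e-9:
            raise ValueError(f"sport_props sum to {sum(self.sport_props)}, expected 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (4, 4):
            raise ValueError("correlation must be 4x4")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation must have a unit diagonal")
        off = corr[~np.eye(4, dtype=bool)]
        if np.any(np.abs(off) > 1.0):
            raise ValueError("correlation off-diagonals must lie in [-1, 1]")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        object.__setattr__(self, "correlation", corr)
        for name, (lo, hi), mu, sd in zip(
            COMPONENTS, self.component_bounds, self.component_means, self.component_sds
        ):
            if not lo < hi:
                raise ValueError(f"{name}: bounds ({lo}, {hi}) degenerate")
            if not lo <= mu <= hi:
                raise ValueError(f"{name}: mean {mu} outside bounds ({lo}, {hi})")
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
        if not self.age_bounds[0] < self.age_bounds[1]:
            raise ValueError("age_bounds degenerate")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_bounds": list(self.age_bounds),
            "sex_split": self.sex_split,
            "sport_props": list(self.sport_props),
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "component_means": list(self.component_means),
            "component_sds": list(self.component_sds),
            "component_bounds": [list(b) for b in self.component_bounds],
            "correlation": np.asarray(self.correlation).tolist(),
            "noise_cv": self.noise_cv,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        d["age_bounds"] = tuple(d.get("age_bounds", (18.0, 35.0)))
        d["sport_props"] = tuple(d.get("sport_props", (0.4, 0.3, 0.3)))
        d["component_means"] = tuple(d.get("component_means", (0.15, 0.08, 0.12, 0.10)))
        d["component_sds"] = tuple(d.get("component_sds", (0.04, 0.03, 0.05, 0.04)))
        if "component_bounds" in d:
            d["component_bounds"] = tuple(tuple(b) for b in d["component_bounds"])
        if "correlation" in d:
            d["correlation"] = np.asarray(d["correlation"], dtype=float)
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class LinkageConfig:
    """Logistic injury linkage on the standardised composite score.

    p(injury) = expit(beta0 + beta1 * (score - score_mean) / score_sd)
    """

    beta0: float
    beta1: float
    score_mean: float
    score_sd: float
    target_prevalence: float | None = None
    target_auc: float | None = None

    def __post_init__(self) -> None:
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        if self.beta1 < 0:
            raise ValueError("beta1 must be non-negative (risk increases with score)")

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "target_prevalence": self.target_prevalence,
            "target_auc": self.target_auc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkageConfig":
        return cls(**d)


@dataclass
class Cohort:
    """A simulated cohort held as a DataFrame, one row per participant.

    Columns: id, age, sex, sport, train_hours, {fv,ta,ld,ba}_true (noise-free
    components), fv..ba (measured), wase, p_injury, injured.  Score and
    outcome columns are NaN until filled by :func:`score_cohort` /
    :func:`simulate_injuries`.
    """

    df: pd.DataFrame
    seed: int
    config_digest: str = ""

    @property
    def n(self) -> int:
        return len(self.df)

    def scores(self) -> np.ndarray:
        s = self.df["wase"].to_numpy(dtype=float)
        if np.isnan(s).any():
            raise ValueError("cohort has unscored participants; run score_cohort first")
        return s

    def labels(self) -> np.ndarray:
        y = self.df["injured"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("cohort has no outcomes; run simulate_injuries first")
        return y.astype(int)


def build_covariance(sds: Sequence[float], corr: np.ndarray) -> np.ndarray:
    """Covariance Sigma_ij = corr_ij * sd_i * sd_j; validated positive definite."""
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    if corr.shape != (len(sds), len(sds)):
        raise ValueError("correlation shape does not match sds")
    if not np.allclose(corr, corr.T, atol=1e-12) or not np.allclose(
        np.diag(corr), 1.0, atol=1e-12
    ):
        raise ValueError("correlation must be symmetric with unit diagonal")
    if np.any(np.abs(corr) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    cov = corr * np.outer(sds, sds)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    return cov


def stratified_counts(n: int, props: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n into integer strata counts."""
    props = np.asarray(props, dtype=float)
    exact = n * props
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    # distribute leftover units to largest remainders; ties to earlier strata
    order = np.argsort(-remainder, kind="stable")
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("demographics", "components", "noise", "outcomes")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_MAX_REJECTION_ROUNDS = 500


def _sample_components(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n joint component vectors inside the bounds box."""
    cov = build_covariance(config.component_sds, config.correlation)
    lo = np.array([b[0] for b in config.component_bounds])
    hi = np.array([b[1] for b in config.component_bounds])
    mean = np.asarray(config.component_means)
    kept: list[np.ndarray] = []
    need = config.n
    for _ in range(_MAX_REJECTION_ROUNDS):
        if need <= 0:
            break
        batch = max(2 * need, 256)
        draw = rng.multivariate_normal(mean, cov, size=batch, method="cholesky")
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        kept.append(draw[ok])
        need -= int(ok.sum())
    else:
        raise RuntimeError(
            "rejection sampling failed to fill the cohort; bounds are too tight "
            "for the configured component distribution"
        )
    return np.vstack(kept)[: config.n]


def _apply_noise(
    true: np.ndarray, config: PopulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Gaussian noise, re-drawn per element to stay in bounds."""
    if config.noise_cv == 0:
        return true.copy()
    lo = np.array([b[0] for b in config.component_bounds])
    hi = np.array([b[1] for b in config.component_bounds])
    measured = true * (1.0 + rng.normal(0.0, config.noise_cv, size=true.shape))
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = (measured < lo) | (measured > hi)
        if not bad.any():
            return measured
        redraw = true[bad] * (1.0 + rng.normal(0.0, config.noise_cv, size=int(bad.sum())))
        measured[bad] = redraw
    raise RuntimeError("noise re-draw failed to respect component bounds")


def generate_cohort(config: PopulationConfig) -> Cohort:
    """Generate demographics and biomechanical components (no outcomes).

    Sex and sport counts are exact (largest-remainder apportionment of the
    configured proportions), with assignment order shuffled.  Fully
    reproducible from ``config.seed``.
    """
    rngs = _substreams(config.seed)
    n = config.n
    rng_d = rngs["demographics"]

    n_male, n_female = stratified_counts(n, (config.sex_split, 1 - config.sex_split))
    sex = np.array(["male"] * n_male + ["female"] * n_female, dtype=object)
    rng_d.shuffle(sex)
    sport_counts = stratified_counts(n, config.sport_props)
    sport = np.array(
        [s for s, c in zip(SPORTS, sport_counts) for _ in range(c)], dtype=object
    )
    rng_d.shuffle(sport)
    age = _truncnorm_rvs(
        config.age_mean, config.age_sd, *config.age_bounds, size=n, rng=rng_d
    )
    train = _truncnorm_rvs(
        config.train_mean, config.train_sd, 0.0, np.inf, size=n, rng=rng_d
    )

    true = _sample_components(config, rngs["components"])
    measured = _apply_noise(true, config, rngs["noise"])

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df["age"] = age
    df["sex"] = sex
    df["sport"] = sport
    df["train_hours"] = train
    for j, name in enumerate(COMPONENTS):
        df[f"{name}_true"] = true[:, j]
    for j, name in enumerate(COMPONENTS):
        df[name] = measured[:, j]
    df["wase"] = np.nan
    df["p_injury"] = np.nan
    df["injured"] = np.nan
    return Cohort(df=df, seed=config.seed, config_digest=config.digest())


def score_cohort(
    cohort: Cohort,
    weights: WeightVector = DEFAULT_WEIGHTS,
    use_true: bool = False,
) -> Cohort:
    """Fill the composite score column (cross-sectional mode, Omega = 1).

    By default the score uses the measured (noisy) components, mirroring what
    an observer could compute; ``use_true`` switches to the noise-free
    components for sensitivity experiments.
    """
    cols = [f"{c}_true" for c in COMPONENTS] if use_true else list(COMPONENTS)
    x = cohort.df[cols].to_numpy(dtype=float)
    w = np.asarray(weights.as_tuple())
    df = cohort.df.copy()
    df["wase"] = np.clip(x @ w, 0.0, 1.0)
    return Cohort(df=df, seed=cohort.seed, config_digest=cohort.config_digest)


def expected_auc(scores: np.ndarray, p: np.ndarray) -> float:
    """Expected AUC of ``scores`` under per-participant injury risks ``p``.

    Treats each participant as a case with weight p_i and a control with
    weight 1 - p_i, and accumulates P(case score > control score) + half the
    tie mass via a single rank-sum pass — no outcome resampling involved.
    """
    scores = np.asarray(scores, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    a = p[order]
    b = 1.0 - a
    boundaries = np.r_[True, s[1:] != s[:-1]]
    group = np.cumsum(boundaries) - 1
    a_g = np.bincount(group, weights=a)
    b_g = np.bincount(group, weights=b)
    b_below = np.concatenate(([0.0], np.cumsum(b_g)[:-1]))
    num = float(np.sum(a_g * (b_below + 0.5 * b_g)))
    denom = float(a.sum() * b.sum())
    if denom == 0:
        raise ValueError("degenerate risks: no case or no control mass")
    return num / denom


def calibrate_linkage(
    cohort: Cohort,
    target_prevalence: float = 0.20,
    target_auc: float = 0.89,
    *,
    beta1_bracket: tuple[float, float] = (0.0, 50.0),
    beta0_bracket: tuple[float, float] = (-20.0, 20.0),
    xtol: float = 1e-6,
) -> LinkageConfig:
    """Calibrate the logistic linkage to hit prevalence and expected AUC.

    Nested one-dimensional root-finding: the outer search adjusts the slope
    beta1 so the expected (weight-based, resampling-free) AUC matches
    ``target_auc``; for every candidate slope the inner search re-solves the
    intercept beta0 so the mean injury probability matches
    ``target_prevalence``.  Both residuals are verified below 1e-4.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must be in (0, 1)")
    if not 0.5 < target_auc < 1:
        raise ValueError("target_auc must be in (0.5, 1)")
    scores = cohort.scores()
    mu = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("zero score variance; linkage cannot discriminate")
    z = (scores - mu) / sd

    def beta0_for(beta1: float) -> float:
        f = lambda b0: float(expit(b0 + beta1 * z).mean()) - target_prevalence
        lo, hi = beta0_bracket
        # prevalence is monotone in beta0 but a steep slope can push the root
        # outside the nominal bracket; widen geometrically until it is inside
        for _ in range(60):
            if f(lo) <= 0 <= f(hi):
                break
            lo, hi = 2 * lo, 2 * hi
        else:
            raise ValueError("could not bracket the intercept for the target prevalence")
        return brentq(f, lo, hi, xtol=xtol)

    def auc_residual(beta1: float) -> float:
        p = expit(beta0_for(beta1) + beta1 * z)
        return expected_auc(scores, p) - target_auc

    lo, hi = beta1_bracket
    if auc_residual(hi) < 0:
        raise ValueError(
            f"target AUC {target_auc} unreachable within beta1 bracket {beta1_bracket}"
        )
    beta1 = brentq(auc_residual, lo, hi, xtol=xtol)
    beta0 = beta0_for(beta1)
    p = expit(beta0 + beta1 * z)
    assert abs(float(p.mean()) - target_prevalence) < 1e-4
    assert abs(expected_auc(scores, p) - target_auc) < 1e-4
    return LinkageConfig(
        beta0=float(beta0),
        beta1=float(beta1),
        score_mean=mu,
        score_sd=sd,
        target_prevalence=target_prevalence,
        target_auc=target_auc,
    )


def simulate_injuries(
    cohort: Cohort, linkage: LinkageConfig, seed: int | None = None
) -> Cohort:
    """Draw independent Bernoulli injury outcomes from the logistic linkage.

    With ``seed=None`` the draw uses the cohort's dedicated outcomes
    substream, so the full pipeline stays reproducible from the master seed.
    """
    scores = cohort.scores()
    z = (scores - linkage.score_mean) / linkage.score_sd
    p = expit(linkage.beta0 + linkage.beta1 * z)
    if seed is None:
        rng = _substreams(cohort.seed)["outcomes"]
    else:
        rng = np.random.default_rng(seed)
    injured = (rng.random(len(p)) < p).astype(int)
    df = cohort.df.copy()
    df["p_injury"] = p
    df["injured"] = injured
    return Cohort(df=df, seed=cohort.seed, config_digest=cohort.config_digest)
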