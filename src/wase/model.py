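"""Core composite-score model.

The WASe score aggregates four biomechanical components — Force Variability
(FV), Temporal Asymmetry (TA), Load Distribution (LD) and Bilateral
Asymmetry (BA) — into a single injury-risk index:

    WASe = (w1*FV + w2*TA + w3*LD + w4*BA) * Omega

The weights are derived from literature-reported contribution ranges
(midpoint of each range, normalised to sum to one) and the convergence
factor Omega is an early-warning term from critical-transitions theory,

    Omega = sum_i(w_i * V_i * sigma_i^2) / (sqrt(T) * dH),

combining weighted component variances over an observation window T with an
entropy shift dH.  In cross-sectional use (a single observation per athlete,
as in the simulation study) Omega is fixed at 1 and the score is the plain
weighted sum, clipped to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Sequence

__all__ = [
    "COMPONENTS",
    "ComponentProfile",
    "WeightVector",
    "ComponentSpec",
    "ConvergenceInputs",
    "WASeScore",
    "DEFAULT_WEIGHTS",
    "DEFAULT_COMPONENT_SPECS",
    "derive_weights",
    "compute_omega",
    "compute_wase",
    "flag_components",
]

#: canonical component order used everywhere in the package
COMPONENTS: tuple[str, ...] = ("fv", "ta", "ld", "ba")


@dataclass(frozen=True)
class ComponentProfile:
    """One athlete's four biomechanical component values.

    All four are dimensionless non-negative ratios: fv is the coefficient of
    variation of peak vertical ground-reaction force, ta the stance-time
    difference ratio, ld a pressure-distribution index and ba a
    kinematic/kinetic limb-comparison index.
    """

    fv: float
    ta: float
    ld: float
    ba: float

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"component {name!r} is not finite: {v!r}")
            lo, hi = _PLAUSIBILITY[name]
            if not (lo <= v <= hi):
                raise ValueError(
                    f"component {name!r}={v} outside plausibility bounds [{lo}, {hi}]"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.fv, self.ta, self.ld, self.ba)


_PLAUSIBILITY = {name: (0.0, 0.5) for name in COMPONENTS}


@dataclass(frozen=True)
class WeightVector:
    """Component weighting coefficients; must sum to 1 at two decimals."""

    fv: float
    ta: float
    ld: float
    ba: float

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            w = getattr(self, name)
            if not (0.0 < w < 1.0):
                raise ValueError(f"weight {name!r}={w} outside (0, 1)")
        total = self.fv + self.ta + self.ld + self.ba
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"weights sum to {total:.6f}, expected 1.00")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.fv, self.ta, self.ld, self.ba)


#: default weights: midpoints of the literature contribution ranges
#: FV 30-40%, TA 25-30%, LD 20-25%, BA 10-20%, normalised and rounded
DEFAULT_WEIGHTS = WeightVector(0.35, 0.28, 0.22, 0.15)


@dataclass(frozen=True)
class ComponentSpec:
    """Normative range and risk threshold for one component."""

    name: str
    weight: float
    normal_lo: float
    normal_hi: float
    risk_threshold: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.name not in COMPONENTS:
            raise ValueError(f"unknown component {self.name!r}")
        if not self.normal_lo < self.normal_hi:
            raise ValueError(
                f"{self.name}: normal_lo {self.normal_lo} must be < normal_hi {self.normal_hi}"
            )
        if not self.risk_threshold > self.normal_lo:
            raise ValueError(
                f"{self.name}: risk_threshold {self.risk_threshold} must exceed normal_lo"
            )


#: normative ranges and risk thresholds for the four components
DEFAULT_COMPONENT_SPECS: tuple[ComponentSpec, ...] = (
    ComponentSpec("fv", 0.35, 0.08, 0.15, 0.18, "Force Variability"),
    ComponentSpec("ta", 0.28, 0.05, 0.12, 0.15, "Temporal Asymmetry"),
    ComponentSpec("ld", 0.22, 0.10, 0.18, 0.22, "Load Distribution"),
    ComponentSpec("ba", 0.15, 0.06, 0.14, 0.18, "Bilateral Asymmetry"),
)


@dataclass(frozen=True)
class ConvergenceInputs:
    """Inputs to the convergence factor Omega.

    v       -- current value V_i of each component (canonical order)
    sigma2  -- variance of each component over the observation window
    t_window-- window length T (observation sessions), strictly positive
    delta_h -- entropy shift dH, dimensionless; sign carries direction
    """

    v: tuple[float, float, float, float]
    sigma2: tuple[float, float, float, float]
    t_window: float
    delta_h: float

    def __post_init__(self) -> None:
        if len(self.v) != 4 or len(self.sigma2) != 4:
            raise ValueError("v and sigma2 must each have four entries")
        if any(s < 0 for s in self.sigma2):
            raise ValueError("variances must be non-negative")
        if not self.t_window > 0:
            raise ValueError(f"t_window must be positive, got {self.t_window}")


@dataclass(frozen=True)
class WASeScore:
    """A computed score: raw weighted sum, Omega, clipped value in [0, 1]."""

    raw: float
    omega: float
    value: float
    clipped: bool
    mode: str  # "cross_sectional" | "dynamic"


def derive_weights(ranges: Sequence[tuple[float, float]]) -> WeightVector:
    """Derive component weights from four literature contribution ranges.

    Two-step procedure: take the midpoint of each (lo, hi) percentage range,
    normalise the midpoints to sum to 1, and round to two decimals with
    round-half-to-even.  If rounding breaks the unit sum, the largest weight
    absorbs a single +/-0.01 correction; anything worse is an error.

    >>> derive_weights([(30, 40), (25, 30), (20, 25), (10, 20)]).as_tuple()
    (0.35, 0.28, 0.22, 0.15)
    """
    if len(ranges) != 4:
        raise ValueError(f"expected four ranges, got {len(ranges)}")
    mids: list[Decimal] = []
    for lo, hi in ranges:
        if not (0 < lo < hi < 100):
            raise ValueError(f"degenerate range ({lo}, {hi}): need 0 < lo < hi < 100")
        mids.append((Decimal(repr(lo)) + Decimal(repr(hi))) / 2)
    total = sum(mids)
    cent = Decimal("0.01")
    rounded = [(m / total).quantize(cent, rounding=ROUND_HALF_EVEN) for m in mids]
    deficit = Decimal(1) - sum(rounded)
    if deficit != 0:
        if abs(deficit) == cent:
            i = max(range(4), key=lambda j: rounded[j])
            rounded[i] += deficit
        else:
            raise ValueError(
                f"rounded weights sum to {sum(rounded)}; cannot reconcile to 1.00"
            )
    return WeightVector(*(float(w) for w in rounded))


def compute_omega(
    inputs: ConvergenceInputs,
    weights: WeightVector = DEFAULT_WEIGHTS,
    *,
    eps_h: float = 1e-6,
) -> float:
    """Convergence factor Omega = sum(w_i V_i sigma_i^2) / (sqrt(T) dH).

    An entropy shift within ``eps_h`` of zero makes the factor undefined
    (division blow-up) and raises.  A negative result (entropy decreasing,
    i.e. the system moving away from a transition) is clamped to 0 with a
    warning, keeping the score bounded below by zero.
    """
    if abs(inputs.delta_h) <= eps_h:
        raise ValueError(
            f"entropy shift {inputs.delta_h} within eps_h={eps_h} of zero; "
            "convergence factor undefined"
        )
    num = sum(
        w * v * s2
        for w, v, s2 in zip(weights.as_tuple(), inputs.v, inputs.sigma2)
    )
    omega = num / (math.sqrt(inputs.t_window) * inputs.delta_h)
    if omega < 0:
        warnings.warn(
            "negative convergence factor (entropy decreasing); clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return omega


def compute_wase(
    profile: ComponentProfile,
    weights: WeightVector = DEFAULT_WEIGHTS,
    omega: float = 1.0,
    mode: str = "cross_sectional",
) -> WASeScore:
    """Compute the composite score for one athlete.

    In ``cross_sectional`` mode (single observation; the mode used throughout
    the simulation study) Omega is forced to 1.  In ``dynamic`` mode the
    caller supplies a non-negative Omega from :func:`compute_omega`.
    """
    if mode == "cross_sectional":
        omega = 1.0
    elif mode == "dynamic":
        if omega < 0:
            raise ValueError(f"omega must be non-negative in dynamic mode, got {omega}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    raw = sum(w * c for w, c in zip(weights.as_tuple(), profile.as_tuple()))
    product = raw * omega
    value = min(max(product, 0.0), 1.0)
    return WASeScore(
        raw=raw, omega=omega, value=value, clipped=(value != product), mode=mode
    )


def flag_components(
    profile: ComponentProfile,
    specs: Iterable[ComponentSpec] = DEFAULT_COMPONENT_SPECS,
) -> set[str]:
    """Return the components whose value strictly exceeds its risk threshold.

    Thresholds are strict ("greater than"); a value exactly at the threshold
    is not flagged.
    """
    by_name = {s.name: s for s in specs}
    missing = set(COMPONENTS) - set(by_name)
    if missing:
        raise ValueError(f"missing spec for component(s): {sorted(missing)}")
    return {
        name
        for name in COMPONENTS
        if getattr(profile, name) > by_name[name].risk_threshold
    }
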