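"""Policy: Gaussian daily insulin-regimen updates and their improvement.

The control action for each controlled quantity S in {basal rate, IC ratio}
is the fractional day-to-day change P, drawn from a Gaussian policy

    u ~ N(P_d(x), sigma),   P_d = h * P_a + (1-h) * P_s,

where P_a = x.T @ theta is the learned linear action, P_s is a conservative
rule-based supervisory action (direction guard, +/- 10% of the dominant
feature), and sigma follows the state norm so exploration shrinks as control
improves.  The policy parameters are improved by the score-function
(likelihood-ratio-derivative) gradient using the Critic's TD error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .glycemic_state import StateFeatures

__all__ = [
    "PolicyParameters",
    "InsulinRegimen",
    "RegimenBounds",
    "ExplorationConfig",
    "ActionRecord",
    "deterministic_action",
    "supervisory_action",
    "total_deterministic",
    "exploration_sigma",
    "sample_action",
    "likelihood_ratio_derivative",
    "actor_update",
    "apply_regimen_update",
    "bolus_from_meal",
]


@dataclass(frozen=True)
class PolicyParameters:
    """Per-quantity policy vector theta = [theta1, theta2] (fractional change per unit feature)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float).ravel())
        if self.theta.size != 2 or not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be a finite length-2 vector")

    @classmethod
    def zeros(cls) -> "PolicyParameters":
        return cls(np.zeros(2))


@dataclass(frozen=True)
class RegimenBounds:
    """Hard safety limits on the regimen and on the per-day fractional change."""

    basal_min: float = 0.05  # U/h
    basal_max: float = 5.0
    ic_min: float = 0.01  # U/g
    ic_max: float = 0.5
    max_daily_change: float = 0.3  # |P| cap per day

    def __post_init__(self) -> None:
        if not (0 < self.basal_min < self.basal_max):
            raise ValueError("invalid basal bounds")
        if not (0 < self.ic_min < self.ic_max):
            raise ValueError("invalid IC bounds")
        if self.max_daily_change <= 0:
            raise ValueError("max_daily_change must be positive")


@dataclass(frozen=True)
class InsulinRegimen:
    """Current regimen: basal rate (U/h) and insulin:carbohydrate ratio (U/g)."""

    basal_rate: float
    ic_ratio: float

    def __post_init__(self) -> None:
        if self.basal_rate <= 0 or self.ic_ratio <= 0:
            raise ValueError("regimen values must be positive")


@dataclass(frozen=True)
class ExplorationConfig:
    """Exploration and mixing constants of the stochastic policy."""

    ks: float = 0.05  # variance gain: sigma^2 = ks * ||x||^2
    sigma_min: float = 1e-3  # sd floor keeping the density proper at x = 0
    h: float = 0.5  # weight of the learned vs supervisory action

    def __post_init__(self) -> None:
        if self.ks < 0:
            raise ValueError("ks must be non-negative")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")
        if not (0 <= self.h <= 1):
            raise ValueError("h must be in [0, 1]")


@dataclass(frozen=True)
class ActionRecord:
    """Audit record of one daily decision for one controlled quantity."""

    controlled: str  # "BR" or "IC"
    pa: float
    ps: float
    pd: float
    pe: float
    sigma: float
    psi: np.ndarray = field(default_factory=lambda: np.zeros(2))


def deterministic_action(state: StateFeatures, params: PolicyParameters) -> float:
    """Learned linear action P_a = x.T @ theta."""
    return float(state.as_array() @ params.theta)


def supervisory_action(
    state: StateFeatures, controlled: str, *, ic_opposite_sign: bool = False
) -> float:
    """Rule-based direction guard P_s.

    Hypoglycaemia takes precedence: any x2 > 0 demands less insulin
    (P_s = -0.1*x2 for the basal rate), otherwise hyperglycaemia demands
    more (P_s = +0.1*x1); at target the advice is zero.

    By default the IC ratio follows the same sign convention as the basal
    rate — with IC in U/g, more insulin per gram corrects hyperglycaemia,
    so an insulin-increasing change is positive for both quantities.  The
    opposite-sign convention for IC (treating a *larger* grams-per-unit
    ratio as more insulin) is available via ``ic_opposite_sign=True``.
    """
    if controlled not in ("BR", "IC"):
        raise ValueError("controlled must be 'BR' or 'IC'")
    sign = -1.0 if (controlled == "IC" and ic_opposite_sign) else 1.0
    if state.x2 > 0:
        return -sign * 0.1 * state.x2
    if state.x1 > 0:
        return sign * 0.1 * state.x1
    return 0.0


def total_deterministic(pa: float, ps: float, h: float) -> float:
    """Weighted blend P_d = h*P_a + (1-h)*P_s."""
    if not (0 <= h <= 1):
        raise ValueError("h must be in [0, 1]")
    return h * pa + (1 - h) * ps


def exploration_sigma(
    state: StateFeatures, cfg: ExplorationConfig = ExplorationConfig()
) -> float:
    """State-dependent exploration sd: sigma = sqrt(ks)*||x||, floored at sigma_min."""
    return max(math.sqrt(cfg.ks) * state.norm, cfg.sigma_min)


def sample_action(pd: float, sigma: float, rng: np.random.Generator) -> float:
    """Draw the applied action P_e from N(P_d, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(rng.normal(pd, sigma))


def likelihood_ratio_derivative(
    u: float, pd: float, sigma: float, grad_pd_theta: np.ndarray
) -> np.ndarray:
    """Score function psi = grad_theta ln mu(u|x,theta) = ((u-P_d)/sigma^2) * grad_theta P_d.

    For the blended policy, grad_theta P_d = h * x (the supervisory part is
    theta-free).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grad = np.asarray(grad_pd_theta, dtype=float).ravel()
    return (u - pd) / sigma**2 * grad


def actor_update(
    params: PolicyParameters, td: float, psi: np.ndarray, beta: float
) -> PolicyParameters:
    """Policy-gradient step theta <- theta - beta * d * psi.

    The learning rate beta is set equal to the exploration variance sigma^2
    in the daily loop, so learning slows as the patient approaches target.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    theta_new = params.theta - beta * td * np.asarray(psi, dtype=float).ravel()
    if not np.all(np.isfinite(theta_new)):
        raise ValueError("actor update diverged to non-finite values")
    return PolicyParameters(theta_new)


def apply_regimen_update(
    regimen: InsulinRegimen,
    p_br: float,
    p_ic: float,
    bounds: RegimenBounds = RegimenBounds(),
) -> tuple[InsulinRegimen, bool]:
    """Apply fractional changes S <- S*(1+P) under the safety bounds.

    Each P is first capped at +/- max_daily_change and the resulting values
    clamped into their configured ranges; returns the new regimen and a flag
    marking whether any cap or clamp fired (for the decision log).
    """
    clamped = False
    cap = bounds.max_daily_change
    p_br_c = min(max(p_br, -cap), cap)
    p_ic_c = min(max(p_ic, -cap), cap)
    clamped |= p_br_c != p_br or p_ic_c != p_ic
    basal = regimen.basal_rate * (1.0 + p_br_c)
    ic = regimen.ic_ratio * (1.0 + p_ic_c)
    basal_cl = min(max(basal, bounds.basal_min), bounds.basal_max)
    ic_cl = min(max(ic, bounds.ic_min), bounds.ic_max)
    clamped |= basal_cl != basal or ic_cl != ic
    return InsulinRegimen(basal_cl, ic_cl), clamped


def bolus_from_meal(ic_ratio: float, announced_cho: float) -> float:
    """Meal bolus in U: IC ratio (U/g) times the announced carbohydrate grams."""
    if announced_cho < 0:
        raise ValueError("announced carbohydrate must be non-negative")
    return ic_ratio * announced_cho
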