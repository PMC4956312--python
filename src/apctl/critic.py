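"""Policy evaluation: TD(lambda) over likelihood-ratio-derivative features.

The Critic approximates the discounted action-value of the current policy
linearly, Q(x, u) ~ r.T @ phi(x, u), with the basis phi chosen equal to the
score function psi of the Gaussian policy.  Learning is SARSA-style
temporal-difference with an accumulating eligibility trace:

    d   = c + gamma * Q(next) - Q(prev)
    r  <- r + a_c * d * z          (z as accumulated up to this transition)
    z  <- lam * z + phi(next)

The trace decays by ``lam`` alone (not gamma*lam); with tabular features its
fixed point is still the true discounted action-value, which the test suite
checks against a matrix-inversion oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CriticState", "approx_action_value", "td_error", "critic_update"]


@dataclass(frozen=True)
class CriticState:
    """Parameters and hyper-parameters of one Critic.

    One Critic is kept per controlled quantity (basal rate and IC ratio) by
    default; a shared-Critic mode is available at the experiment level.
    """

    r: np.ndarray
    z: np.ndarray
    gamma: float = 0.9
    lam: float = 0.5
    learning_rate: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float).ravel())
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float).ravel())
        if self.r.shape != self.z.shape:
            raise ValueError("r and z must have the same length")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if not (0 <= self.lam < 1):
            raise ValueError("lam must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.z))):
            raise ValueError("critic parameters must be finite")

    @property
    def dim(self) -> int:
        return self.r.size

    @classmethod
    def initialise(
        cls, dim: int, rng: np.random.Generator, **hyper
    ) -> "CriticState":
        """Fresh Critic: r0 uniform in [-1, 1], z0 = 0."""
        return cls(r=rng.uniform(-1.0, 1.0, size=dim), z=np.zeros(dim), **hyper)


def approx_action_value(critic: CriticState, features: np.ndarray) -> float:
    """Linear action-value estimate r.T @ phi."""
    phi = np.asarray(features, dtype=float).ravel()
    if phi.size != critic.dim:
        raise ValueError(
            f"feature length {phi.size} does not match critic dimension {critic.dim}"
        )
    return float(critic.r @ phi)


def td_error(
    cost: float, value_prev: float, value_next: float, gamma: float
) -> float:
    """One-transition temporal-difference residual d = c + gamma*Q' - Q."""
    d = cost + gamma * value_next - value_prev
    if not np.isfinite(d):
        raise ValueError("TD error is not finite")
    return float(d)


def critic_update(
    critic: CriticState, td: float, features_next: np.ndarray
) -> CriticState:
    """Apply one TD(lambda) step; returns the updated Critic.

    Order is fixed and load-bearing: the parameter step uses the eligibility
    as accumulated up to this transition, then the trace decays and absorbs
    the next feature vector.
    """
    phi_next = np.asarray(features_next, dtype=float).ravel()
    if phi_next.size != critic.dim:
        raise ValueError("feature length does not match critic dimension")
    r_new = critic.r + critic.learning_rate * td * critic.z
    z_new = critic.lam * critic.z + phi_next
    if not (np.all(np.isfinite(r_new)) and np.all(np.isfinite(z_new))):
        raise ValueError("critic update diverged to non-finite values")
    return replace(critic, r=r_new, z=z_new)
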