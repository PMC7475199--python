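"""Mathematical kernel of the preference-learning model.

An agent carries a perceived valuation ``v_hat_H`` of healthy food that is
updated by temporal-difference learning each time healthy food is consumed,
while the valuation of unhealthy food is fixed at 1 (fully formed).  Daily
food situations are governed by an environment probability ``gamma``; in a
choice situation the healthy option is picked with Luce-rule probability
``v_hat_H / (v_hat_U + v_hat_H)``.  Preferences map to a daily servings count
through the Poisson quantile function evaluated at a uniform draw on
``(0, v_hat_H]``.

All functions here are pure computation; randomness enters only through an
explicitly passed :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "Palatability",
    "PreferenceState",
    "EnvironmentParams",
    "ServingModel",
    "tdl_update",
    "choice_prob",
    "draw_gamma",
    "poisson_quantile",
    "draw_servings",
]


@dataclass(frozen=True)
class Palatability:
    """Intrinsic palatability (true valuation ceiling) of each food type.

    Both values are unitless and normalized to 1 by default: the true value
    of healthy food equals that of unhealthy food, so long-run differences in
    behavior arise purely from learning dynamics, not from taste asymmetry.
    """

    beta_H: float = 1.0
    beta_U: float = 1.0

    def __post_init__(self) -> None:
        if not (self.beta_H > 0 and self.beta_U > 0):
            raise ValueError("palatability values must be positive")


@dataclass(frozen=True)
class PreferenceState:
    """An agent's perceived food valuations and learning speed.

    ``v_hat_H`` starts at 0 (completely unformed preference for healthy
    food) and can only increase; ``v_hat_U`` is pinned at 1 because the
    preference for unhealthy food is taken as fully formed from the outset.
    ``alpha`` in (0, 1] is the fraction of the prediction error absorbed per
    healthy-consumption event.
    """

    v_hat_H: float = 0.0
    v_hat_U: float = 1.0
    alpha: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        # v_hat_H == 1.0 is tolerated as the limit point (e.g. alpha = 1)
        if not 0.0 <= self.v_hat_H <= 1.0:
            raise ValueError(f"v_hat_H must be in [0, 1], got {self.v_hat_H}")
        if self.v_hat_U != 1.0:
            raise ValueError("v_hat_U is fixed at 1 (fully formed)")


@dataclass(frozen=True)
class EnvironmentParams:
    """Parameters of the yearly environment draw.

    ``p1`` and ``p2`` bound the uniform draw for the probability ``gamma``
    of landing in a healthy-only food situation: a food-desert year draws
    gamma from (0, p1), a non-desert year from (p1, p2).  A year with FFVP
    participation adds the constant ``a`` to the draw (clipped at 1), so the
    program raises healthy-food availability additively in either
    environment.
    """

    p1: float = 0.10
    p2: float = 0.35
    a: float = 0.1635

    def __post_init__(self) -> None:
        if not (0.0 < self.p1 < self.p2 <= 1.0):
            raise ValueError(
                f"require 0 < p1 < p2 <= 1, got p1={self.p1}, p2={self.p2}"
            )
        if self.a < 0:
            raise ValueError(f"augmentation constant a must be >= 0, got {self.a}")


@dataclass(frozen=True)
class ServingModel:
    """Poisson mean for the preference-to-servings mapping (servings/day)."""

    lam: float = 3.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")


def tdl_update(state: PreferenceState, palatability: Palatability = Palatability()) -> PreferenceState:
    """One temporal-difference learning step after consuming healthy food.

    Moves the perceived valuation a fraction ``alpha`` of the way toward the
    intrinsic palatability:

        v_hat_H' = v_hat_H + alpha * (beta_H - v_hat_H)

    The update is applied only on healthy-consumption events; unhealthy
    consumption leaves the state untouched (preferences are learned, never
    forgotten).  With beta_H = 1 the valuation approaches but never reaches
    1 in finitely many steps.
    """
    v = state.v_hat_H + state.alpha * (palatability.beta_H - state.v_hat_H)
    return replace(state, v_hat_H=v)


def choice_prob(state: PreferenceState) -> float:
    """Luce-rule probability of choosing healthy food in a choice situation.

    Returns ``v_hat_H / (v_hat_U + v_hat_H)``.  With v_hat_U = 1 and
    v_hat_H <= 1 this is bounded by 1/2.  The degenerate case of both
    valuations equal to zero returns 0 by convention (healthy food is never
    chosen by an agent with no formed preference).
    """
    total = state.v_hat_U + state.v_hat_H
    if total == 0.0:
        return 0.0
    return state.v_hat_H / total


def draw_gamma(
    desert: bool,
    ffvp: bool,
    env: EnvironmentParams,
    rng: np.random.Generator,
) -> float:
    """Draw the healthy-situation probability gamma for one agent-year.

    A food-desert year draws uniformly on (0, p1); a non-desert year on
    (p1, p2).  FFVP participation adds the constant ``a`` to the draw,
    clipped to 1.  The FFVP augmentation consumes the same underlying
    uniform variate, so with a = 0 the draw is identical to the
    no-program draw from the same stream.
    """
    lo, hi = (0.0, env.p1) if desert else (env.p1, env.p2)
    gamma = rng.uniform(lo, hi)
    if ffvp:
        gamma = min(gamma + env.a, 1.0)
    return gamma


@lru_cache(maxsize=64)
def _poisson_cdf_table(lam: float) -> np.ndarray:
    """Cumulative Poisson probabilities out to negligible tail mass.

    The final entry is pinned to 1 so quantile lookups for any u < 1 stay
    inside the table (the tail beyond it carries < 1e-15 probability).
    """
    k_max = int(stats.poisson.isf(1e-15, lam)) + 2
    cdf = stats.poisson.cdf(np.arange(k_max + 1), lam)
    cdf[-1] = 1.0
    return cdf


def poisson_quantile(u, lam: float):
    """Poisson inverse CDF: smallest integer k with CDF(k; lam) >= u.

    ``u`` may be a scalar or array in [0, 1); lam > 0.  Values u >= 1 are
    rejected (the quantile diverges), which is why the model constrains the
    perceived valuation to [0, 1).  Implemented as a binary search on a
    cached CDF table, so it is cheap inside the daily simulation loop.
    """
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr >= 1):
        raise ValueError("u must satisfy 0 <= u < 1")
    cdf = _poisson_cdf_table(float(lam))
    k = np.searchsorted(cdf, u_arr, side="left")
    if np.isscalar(u) or u_arr.ndim == 0:
        return int(k)
    return k.astype(np.int64)


def draw_servings(
    state: PreferenceState,
    model: ServingModel,
    rng: np.random.Generator,
) -> int:
    """Draw a daily servings count given the current preference state.

    Draws u uniformly on (0, v_hat_H] and returns the Poisson quantile of u
    at mean ``lam``.  An agent with v_hat_H = 0 deterministically consumes 0
    servings; as v_hat_H -> 1 the draw approaches a full Poisson(lam)
    variate, so the servings distribution is stochastically increasing in
    the formed preference.
    """
    v = state.v_hat_H
    if v == 0.0:
        return 0
    u = v * (1.0 - rng.random())  # (0, v]
    return poisson_quantile(u, model.lam)
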