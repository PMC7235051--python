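"""Two-parameter logistic (2PL) measurement model for dichotomous conflict items.

The Conflict Behavior Questionnaire (Perception of the Dyad subscale) is 16
true/false items.  Each item j has a discrimination alpha_j > 0 and a
difficulty beta_j; the probability that a dyad at latent conflict level theta
endorses item j is

    P(y_j = 1 | theta) = logit^{-1}( alpha_j * (theta - beta_j) ).

This module provides the item response function, log pattern likelihoods that
skip missing items, the test information function, and item characteristic
curve grids for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ItemParameters:
    """Discrimination/difficulty pairs for a bank of dichotomous items."""

    discrimination: np.ndarray
    difficulty: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.discrimination, dtype=float)
        b = np.asarray(self.difficulty, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise ValueError("discrimination and difficulty must be 1-d and equal length")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("item parameters must be finite")
        if np.any(a <= 0):
            raise ValueError("all discriminations must be positive")
        object.__setattr__(self, "discrimination", a)
        object.__setattr__(self, "difficulty", b)

    @property
    def n_items(self) -> int:
        return self.discrimination.shape[0]


def item_prob(theta, discrimination, difficulty):
    """2PL response probability P(y=1 | theta) = 1 / (1 + exp(-a (theta - b))).

    Broadcasts over array arguments.
    """
    a = np.asarray(discrimination, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination must be positive")
    eta = a * (np.asarray(theta, dtype=float) - np.asarray(difficulty, dtype=float))
    # scipy.special.expit is numerically stable at both tails
    from scipy.special import expit

    return expit(eta)


def _bernoulli_logit_logpmf(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """log P(y | eta) for Bernoulli with logit eta, stable for large |eta|.

    y*eta - log(1 + exp(eta)) computed via -log1p(exp(-|eta|)) - relu(-s*eta).
    """
    # log sigma(eta) = -softplus(-eta); log(1-sigma) = -softplus(eta)
    sp = np.logaddexp(0.0, eta)  # softplus(eta)
    return y * eta - sp


def pattern_loglik(responses, theta, items: ItemParameters) -> float:
    """Log probability mass of an observed response pattern at trait level theta.

    Missing responses (NaN) contribute nothing: the latent level is scored from
    the observed items only.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != items.n_items:
        raise ValueError("pattern length must equal number of items")
    obs = ~np.isnan(y)
    if not np.any(obs):
        raise ValueError("pattern has no observed responses")
    yv = y[obs]
    if np.any((yv != 0) & (yv != 1)):
        raise ValueError("observed responses must be 0 or 1")
    eta = items.discrimination[obs] * (theta - items.difficulty[obs])
    return float(np.sum(_bernoulli_logit_logpmf(yv, eta)))


def test_information(theta, items: ItemParameters):
    """Fisher information of the item bank about theta.

    I(theta) = sum_j alpha_j^2 p_j (1 - p_j); additive over items, so the
    inverse square root bounds the measurement SE at each trait level.
    """
    th = np.asarray(theta, dtype=float)
    p = item_prob(th[..., None], items.discrimination, items.difficulty)
    info = np.sum(items.discrimination**2 * p * (1.0 - p), axis=-1)
    if np.ndim(theta) == 0:
        return float(info)
    return info


def icc_grid(items: ItemParameters, theta_grid) -> np.ndarray:
    """Item characteristic curves: matrix (len(grid), n_items) of P(y=1)."""
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("theta_grid must be non-empty")
    return item_prob(grid[:, None], items.discrimination, items.difficulty)


def slope_intercept(items: ItemParameters) -> tuple[np.ndarray, np.ndarray]:
    """Convert difficulty parameterization a(theta-b) to slope-intercept a*theta + c."""
    return items.discrimination.copy(), -items.discrimination * items.difficulty


def from_slope_intercept(slope, intercept) -> ItemParameters:
    slope = np.asarray(slope, float)
    return ItemParameters(slope, -np.asarray(intercept, float) / slope)
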