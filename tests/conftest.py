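"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own quadrature and item
selection code paths: EAP is recomputed by dense trapezoidal integration, and
the adaptive-administration oracle re-derives each item choice by brute-force
information comparison.  They exist so that the package's pre-computed
structures can be checked against a second, independent route.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from catform import FixtureConfig, ItemParameters, build_instrument, generate_item_bank


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def grm_probs_oracle(theta: np.ndarray, params: ItemParameters) -> np.ndarray:
    """(K, len(theta)) category probabilities from the cumulative form."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a = params.discrimination
    b = np.asarray(params.thresholds)
    cum = 1.0 / (1.0 + np.exp(-a * (theta[None, :] - b[:, None])))
    star = np.vstack([np.ones_like(theta)[None, :], cum, np.zeros_like(theta)[None, :]])
    return star[:-1] - star[1:]


def eap_oracle(
    responses, bank, n_points: int = 10001, bound: float = 6.0
) -> tuple[float, float]:
    """Dense-grid EAP by trapezoidal integration; independent of the package
    quadrature.  Returns (posterior mean, posterior sd)."""
    theta = np.linspace(-bound, bound, n_points)
    log_post = -0.5 * theta**2
    for k, params in zip(responses, bank):
        pk = grm_probs_oracle(theta, params)[int(k)]
        log_post += np.log(np.clip(pk, 1e-300, None))
    post = np.exp(log_post - log_post.max())
    z = np.trapezoid(post, theta)
    mean = np.trapezoid(post * theta, theta) / z
    var = np.trapezoid(post * (theta - mean) ** 2, theta) / z
    return float(mean), float(np.sqrt(var))


def info_oracle(theta: float, params: ItemParameters) -> float:
    """Fisher information by numerical differentiation of the category
    probabilities (central differences)."""
    h = 1e-5
    p0 = grm_probs_oracle(np.array([theta]), params)[:, 0]
    pm = grm_probs_oracle(np.array([theta - h]), params)[:, 0]
    pp = grm_probs_oracle(np.array([theta + h]), params)[:, 0]
    dp = (pp - pm) / (2 * h)
    return float(np.sum(dp**2 / p0))


def online_cat_oracle(bank, responses, grid_points: int = 61, bound: float = 4.0):
    """Reference fixed-length adaptive run: after every response, re-estimate
    the trait by EAP on the given grid and pick the unused item with the
    largest information there (lexicographic id tie-break).

    Uses its own grid-summation EAP (not the package's) so the pre-computed
    tree is checked against an independent reimplementation.
    """
    theta_grid = np.linspace(-bound, bound, grid_points)
    weights = np.exp(-0.5 * theta_grid**2)
    weights /= weights.sum()

    def eap(taken_items, taken_responses):
        post = weights.copy()
        for item, resp in zip(taken_items, taken_responses):
            p_yes = grm_probs_oracle(theta_grid, item)[1]
            post *= p_yes if resp else (1.0 - p_yes)
        post /= post.sum()
        mean = float(post @ theta_grid)
        sd = float(np.sqrt(post @ (theta_grid - mean) ** 2))
        return mean, sd

    presented: list[ItemParameters] = []
    taken: list[int] = []
    theta, sd = eap([], [])
    for response in responses:
        used = {p.item_id for p in presented}
        candidates = [p for p in bank if p.item_id not in used]

        def neg_info_then_id(p: ItemParameters):
            q = 1.0 / (1.0 + np.exp(-p.discrimination * (theta - p.thresholds[0])))
            return (-(p.discrimination**2 * q * (1 - q)), p.item_id)

        chosen = min(candidates, key=neg_info_then_id)
        presented.append(chosen)
        taken.append(int(response))
        theta, sd = eap(presented, taken)
    return [p.item_id for p in presented], theta, sd


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def dichotomous_config() -> FixtureConfig:
    return FixtureConfig(seed=3, items=3, responses=2, with_instructions=False)


@pytest.fixture
def small_instrument(dichotomous_config):
    return build_instrument(dichotomous_config)


@pytest.fixture
def small_bank(dichotomous_config):
    return generate_item_bank(dichotomous_config)


@pytest.fixture
def bank12() -> list[ItemParameters]:
    return generate_item_bank(FixtureConfig(seed=12, items=12, responses=2))


@pytest.fixture
def fixed_clock():
    """A deterministic clock ticking one second per call."""

    class Clock:
        def __init__(self):
            self.now = dt.datetime(2021, 6, 1, 12, 0, 0, tzinfo=dt.timezone.utc)

        def __call__(self):
            self.now += dt.timedelta(seconds=1)
            return self.now

    return Clock()
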