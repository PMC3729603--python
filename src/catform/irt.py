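"""Item response theory machinery: 2PL and graded response models, EAP
scoring, Fisher information, and response simulation.

The latent trait θ is the construct the instrument measures (for a mobility
instrument, self-perceived mobility).  Dichotomous items follow the
two-parameter logistic (2PL) model

    P(X = 1 | θ) = 1 / (1 + exp(-a (θ - b)))

with discrimination a > 0 and difficulty b.  Polytomous items with K ordered
categories follow Samejima's graded response model (GRM): cumulative
probabilities P*(k) = logistic(a (θ - b_k)) with strictly increasing
thresholds b_1 < … < b_{K-1}, and category probabilities
P(k) = P*(k) - P*(k+1), where P*(0) = 1 and P*(K) = 0.  At K = 2 the GRM is
exactly the 2PL.

Trait scores are expected a posteriori (EAP): the posterior mean of θ under a
standard-normal prior, evaluated on a fixed quadrature grid; the reported
standard error is the posterior standard deviation.  EAP is deterministic,
closed under all-extreme response patterns, and cheap enough to pre-compute
exhaustively, which is what lookup-table and tree-based scoring cache.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import BankFileError

__all__ = [
    "ItemParameters",
    "QuadratureGrid",
    "AbilityEstimate",
    "prob_2pl",
    "prob_grm",
    "eap_estimate",
    "item_information",
    "simulate_response",
    "read_item_bank",
    "write_item_bank",
]


@dataclass(frozen=True)
class ItemParameters:
    """IRT parameters for one item.

    ``thresholds`` has length 1 for a dichotomous (2PL) item and length K-1
    for a K-category graded-response item; it must be strictly increasing.
    """

    item_id: str
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.discrimination <= 0:
            raise ValueError(f"discrimination must be positive, got {self.discrimination}")
        diffs = np.diff(self.thresholds)
        if len(self.thresholds) == 0 or np.any(diffs <= 0):
            raise ValueError(f"thresholds must be non-empty and strictly increasing: {self.thresholds}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def is_dichotomous(self) -> bool:
        return self.n_categories == 2


@dataclass(frozen=True)
class QuadratureGrid:
    """θ grid with normalized prior weights (standard normal by default)."""

    points: np.ndarray
    weights: np.ndarray

    @classmethod
    def standard_normal(cls, n_points: int = 61, bound: float = 4.0) -> "QuadratureGrid":
        """Equally spaced grid on [-bound, bound] with N(0,1) prior weights."""
        points = np.linspace(-bound, bound, n_points)
        weights = np.exp(-0.5 * points**2)
        return cls(points=points, weights=weights / weights.sum())

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if points.size == 0:
            raise ValueError("quadrature grid must have at least one point")
        if np.any(np.diff(points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "weights", weights / weights.sum())


@dataclass(frozen=True)
class AbilityEstimate:
    """A trait score with its standard error (posterior mean and SD)."""

    theta: float
    se: float


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def prob_2pl(theta: np.ndarray | float, params: ItemParameters) -> np.ndarray | float:
    """P(affirmative | θ) under the 2PL model."""
    if not params.is_dichotomous:
        raise ValueError(f"item {params.item_id!r} is not dichotomous")
    return _logistic(params.discrimination * (np.asarray(theta, dtype=float) - params.thresholds[0]))


def prob_grm(theta: np.ndarray | float, params: ItemParameters, k: int) -> np.ndarray | float:
    """P(response category k | θ) under the graded response model.

    Categories are 0-based: 0 ≤ k ≤ K-1.  Probabilities over k sum to one.
    """
    if not 0 <= k < params.n_categories:
        raise ValueError(f"category {k} out of range for {params.n_categories}-category item")
    theta = np.asarray(theta, dtype=float)
    a = params.discrimination
    b = params.thresholds
    upper = _logistic(a * (theta - b[k - 1])) if k >= 1 else np.ones_like(theta)
    lower = _logistic(a * (theta - b[k])) if k < len(b) else np.zeros_like(theta)
    return upper - lower


def eap_estimate(
    responses: Sequence[int],
    bank: Sequence[ItemParameters],
    grid: QuadratureGrid | None = None,
) -> AbilityEstimate:
    """EAP trait estimate from category responses on matched bank items.

    ``responses[i]`` is the 0-based category index chosen on ``bank[i]``.  An
    empty pattern recovers the prior moments (θ̂ ≈ 0, se ≈ 1 within grid
    tolerance).  Deterministic given the grid.
    """
    if grid is None:
        grid = QuadratureGrid.standard_normal()
    if len(responses) != len(bank):
        raise ValueError(f"{len(responses)} responses for {len(bank)} bank items")
    posterior = grid.weights.copy()
    for response, params in zip(responses, bank):
        posterior *= np.asarray(prob_grm(grid.points, params, int(response)))
    total = posterior.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("posterior vanished on the grid; widen the grid bounds")
    posterior /= total
    theta = float(np.dot(posterior, grid.points))
    var = float(np.dot(posterior, (grid.points - theta) ** 2))
    return AbilityEstimate(theta=theta, se=float(np.sqrt(var)))


def item_information(theta: np.ndarray | float, params: ItemParameters) -> np.ndarray | float:
    """Fisher information the item contributes at θ.

    2PL: a² P (1-P).  GRM: sum over categories of (dP_k/dθ)² / P_k, computed
    from the cumulative form.  Nonnegative, vanishing as θ → ±∞.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    a = params.discrimination
    if params.is_dichotomous:
        p = np.asarray(prob_2pl(theta_arr, params))
        info = a**2 * p * (1.0 - p)
    else:
        cum = _logistic(a * (theta_arr[None, :] - np.asarray(params.thresholds)[:, None]))
        star = np.vstack([np.ones_like(theta_arr)[None, :], cum, np.zeros_like(theta_arr)[None, :]])
        dstar = np.vstack(
            [np.zeros_like(theta_arr)[None, :], a * cum * (1 - cum), np.zeros_like(theta_arr)[None, :]]
        )
        probs = star[:-1] - star[1:]
        dprobs = dstar[:-1] - dstar[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 0, dprobs**2 / np.where(probs > 0, probs, 1.0), 0.0)
        info = terms.sum(axis=0)
    return info if np.ndim(theta) else float(info[0])


def simulate_response(
    theta: float, params: ItemParameters, rng: np.random.Generator
) -> int:
    """Draw one category response at ability *theta*; reproducible via *rng*."""
    probs = np.array([prob_grm(theta, params, k) for k in range(params.n_categories)], dtype=float)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return int(rng.choice(params.n_categories, p=probs))


# ---------------------------------------------------------------------------
# Item bank files: tab-separated item_id, a, b_1[, b_2, …]
# ---------------------------------------------------------------------------


def read_item_bank(path: str | Path) -> list[ItemParameters]:
    bank: list[ItemParameters] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise BankFileError(f"line {lineno}: need item_id, a and at least one threshold")
            try:
                a = float(row[1])
                thresholds = tuple(float(x) for x in row[2:])
            except ValueError as exc:
                raise BankFileError(f"line {lineno}: {exc}") from exc
            try:
                bank.append(ItemParameters(row[0], a, thresholds))
            except ValueError as exc:
                raise BankFileError(f"line {lineno}: {exc}") from exc
    return bank


def write_item_bank(bank: Sequence[ItemParameters], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for params in bank:
            writer.writerow(
                [params.item_id, f"{params.discrimination:.6f}"]
                + [f"{b:.6f}" for b in params.thresholds]
            )
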