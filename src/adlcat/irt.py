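"""Response-probability, information, and likelihood kernels.

Two model families on a common logit metric:

* Generalized partial credit model (GPCM). For an item with
  discrimination ``a`` and step difficulties ``b_1..b_m`` the probability
  of score category ``x`` in ``0..m`` at person measure ``theta`` is::

      P(X = x) = exp(sum_{v<=x} a (theta - b_v)) /
                 sum_{c=0..m} exp(sum_{v<=c} a (theta - b_v))

  with the empty sum (``x = 0``) equal to zero.
* Dichotomous Rasch model: the ``m = 1``, ``a = 1`` special case,
  ``P(1) = logistic(theta - delta)``.

All category sums are accumulated in log space with max-subtraction so
extreme ``theta`` or user-supplied banks with large parameters do not
overflow. Fisher item information is ``a^2 * Var(X)``, the score variance
scaled by the squared slope; for Rasch items it reduces to ``P (1 - P)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .item_bank import ItemBank, ItemParameters

Response = tuple[ItemParameters, int]


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return theta


@dataclass(frozen=True)
class BankDesign:
    """Dense array view of a set of items, for vectorized kernels.

    ``steps`` is padded with zeros beyond each item's ``m``; padded
    categories are masked out of every computation via ``cat_valid``.
    """

    a: np.ndarray          # (n_items,)
    steps: np.ndarray      # (n_items, m_max)
    m: np.ndarray          # (n_items,) number of steps per item
    cat_valid: np.ndarray  # (n_items, m_max + 1) bool, category <= m
    scores: np.ndarray     # (m_max + 1,) 0..m_max

    @classmethod
    def from_items(cls, items: Sequence[ItemParameters]) -> "BankDesign":
        n = len(items)
        m = np.array([it.max_score for it in items], dtype=np.int64)
        m_max = int(m.max()) if n else 1
        steps = np.zeros((n, m_max))
        for i, it in enumerate(items):
            steps[i, : it.max_score] = it.step_difficulties
        a = np.array([it.discrimination for it in items])
        scores = np.arange(m_max + 1)
        cat_valid = scores[None, :] <= m[:, None]
        return cls(a=a, steps=steps, m=m, cat_valid=cat_valid, scores=scores)

    def __len__(self) -> int:
        return len(self.a)

    def subset(self, idx: Sequence[int]) -> "BankDesign":
        idx = np.asarray(idx, dtype=np.int64)
        return BankDesign(
            a=self.a[idx],
            steps=self.steps[idx],
            m=self.m[idx],
            cat_valid=self.cat_valid[idx],
            scores=self.scores,
        )

    def log_probs(self, thetas: np.ndarray) -> np.ndarray:
        """Log category probabilities, shape ``(T, n_items, m_max + 1)``."""
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        # psi[t, i, k] = a_i * (theta_t - b_{i,k+1})
        psi = self.a[None, :, None] * (thetas[:, None, None] - self.steps[None, :, :])
        cum = np.concatenate(
            [np.zeros((len(thetas), len(self.a), 1)), np.cumsum(psi, axis=2)], axis=2
        )
        cum = np.where(self.cat_valid[None, :, :], cum, -np.inf)
        top = np.max(cum, axis=2, keepdims=True)
        lse = top + np.log(np.sum(np.exp(cum - top), axis=2, keepdims=True))
        return cum - lse

    def probs(self, thetas: np.ndarray) -> np.ndarray:
        return np.exp(self.log_probs(thetas))

    def score_moments(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Expected score and score variance per item, shape ``(T, n_items)``."""
        p = self.probs(thetas)
        e = np.sum(p * self.scores, axis=2)
        v = np.sum(p * self.scores**2, axis=2) - e**2
        return e, np.maximum(v, 0.0)

    def information(self, thetas: np.ndarray) -> np.ndarray:
        """Fisher item information ``a^2 Var(X)``, shape ``(T, n_items)``."""
        _, v = self.score_moments(thetas)
        return self.a[None, :] ** 2 * v

    def log_likelihood(self, thetas: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Joint log-likelihood of response vector ``x``, shape ``(T,)``."""
        lp = self.log_probs(thetas)
        return np.sum(lp[:, np.arange(len(self.a)), x], axis=1)

    def loglik_grad_hess(self, theta: float, x: np.ndarray) -> tuple[float, float]:
        """First and second derivative of the log-likelihood at ``theta``.

        For the GPCM the score function is ``sum_i a_i (x_i - E_i)`` and
        the Hessian ``-sum_i a_i^2 Var_i`` (minus the test information).
        """
        e, v = self.score_moments(np.array([theta]))
        g = float(np.sum(self.a * (x - e[0])))
        h = -float(np.sum(self.a**2 * v[0]))
        return g, h


@lru_cache(maxsize=16)
def bank_design(bank: ItemBank) -> BankDesign:
    """Cached :class:`BankDesign` for a whole bank."""
    return BankDesign.from_items(bank.items)


def category_probs(theta: float, item: ItemParameters) -> np.ndarray:
    """Category probabilities ``P(X = 0..m)`` for one item at ``theta``."""
    theta = _check_theta(theta)
    design = BankDesign.from_items([item])
    return design.probs(np.array([theta]))[0, 0, : item.max_score + 1]


def item_information(theta: float, item: ItemParameters) -> float:
    """Fisher information of one item at ``theta`` (nonnegative)."""
    theta = _check_theta(theta)
    design = BankDesign.from_items([item])
    return float(design.information(np.array([theta]))[0, 0])


def _validate_responses(responses: Sequence[Response]) -> None:
    for item, x in responses:
        if not (isinstance(x, (int, np.integer)) and 0 <= x <= item.max_score):
            raise ValueError(
                f"response {x!r} out of range 0..{item.max_score} "
                f"for item {item.item_id!r}"
            )


def log_likelihood(theta: float, responses: Sequence[Response]) -> float:
    """Joint log-likelihood of observed categories at ``theta``.

    An empty response list has log-likelihood 0 (empty product).
    """
    theta = _check_theta(theta)
    if not responses:
        return 0.0
    _validate_responses(responses)
    design = BankDesign.from_items([item for item, _ in responses])
    x = np.array([x for _, x in responses], dtype=np.int64)
    return float(design.log_likelihood(np.array([theta]), x)[0])
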