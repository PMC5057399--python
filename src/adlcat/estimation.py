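"""Person-measure estimators: MLE, MAP, and EAP.

All three score a response pattern on the logit scale and report a
standard error of measurement (SEM):

* ``MLE`` maximizes the raw likelihood (Newton-Raphson with a bisection
  safeguard); SEM is ``1 / sqrt(test information)`` at the estimate.
  All-minimum / all-maximum patterns have no interior maximum and return
  the boundary of the ``[-4, 4]`` trait range with ``at_boundary=True``.
* ``MAP`` maximizes likelihood times a standard-normal population prior;
  SEM uses the posterior curvature, ``1 / sqrt(test information + 1)``.
* ``EAP`` is the posterior mean over a fixed quadrature grid (61 equally
  spaced nodes on ``[-4, 4]`` with N(0, 1) weights); SEM is the posterior
  standard deviation.

Person reliability on the unit-variance trait is ``1 - SEM^2``; the CAT
stop rule's reliability threshold of 0.90 therefore corresponds to
``SEM <= sqrt(0.1) ~= 0.316``.

Each estimator has a ``*_from_design`` variant taking a prebuilt
:class:`~adlcat.irt.BankDesign` plus a response vector; the adaptive
engine uses these on subsets of a cached full-bank design.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .irt import BankDesign, Response, _validate_responses

#: Trait range used for clamping, boundary patterns, and EAP quadrature.
THETA_BOUND = 4.0

#: EAP quadrature nodes (equally spaced) on [-THETA_BOUND, THETA_BOUND].
EAP_NODES = 61

_NEWTON_TOL = 1e-6
_NEWTON_MAX_ITER = 50
_MIN_INFO = 1e-12


class Estimator(str, Enum):
    MLE = "MLE"
    MAP = "MAP"
    EAP = "EAP"


@dataclass(frozen=True)
class PersonEstimate:
    """One scored person: measure, precision, and bookkeeping."""

    theta: float
    sem: float
    method: Estimator
    n_items: int
    converged: bool = True
    at_boundary: bool = False

    @property
    def reliability(self) -> float:
        return reliability_from_sem(self.sem)


def reliability_from_sem(sem: float) -> float:
    """Person reliability ``1 - sem^2`` on a unit-variance trait."""
    if not sem > 0:
        raise ValueError(f"sem must be positive, got {sem}")
    return 1.0 - sem**2


def _unpack(responses: Sequence[Response]) -> tuple[BankDesign, np.ndarray]:
    _validate_responses(responses)
    design = BankDesign.from_items([item for item, _ in responses])
    x = np.array([x for _, x in responses], dtype=np.int64)
    return design, x


def _sem_from_info(info: float) -> float:
    return float(1.0 / np.sqrt(max(info, _MIN_INFO)))


def _newton_argmax(
    grad_hess: Callable[[float], tuple[float, float]],
    bound: float,
) -> tuple[float, bool, bool]:
    """Maximize a strictly concave objective on ``[-bound, bound]``.

    Newton steps from 0 with a bisection fallback whenever a step leaves
    the current bracket or the curvature is not negative. Returns
    ``(theta, converged, at_boundary)``. The gradient is decreasing, so
    a gradient that never changes sign on the interval puts the maximum
    at an endpoint.
    """
    g_lo, _ = grad_hess(-bound)
    if g_lo <= 0:
        return -bound, True, True
    g_hi, _ = grad_hess(bound)
    if g_hi >= 0:
        return bound, True, True
    lo, hi = -bound, bound
    theta = 0.0
    for _ in range(_NEWTON_MAX_ITER):
        g, h = grad_hess(theta)
        if g > 0:
            lo = theta
        else:
            hi = theta
        if h < 0:
            candidate = theta - g / h
        else:
            candidate = None
        if candidate is None or not (lo < candidate < hi):
            candidate = 0.5 * (lo + hi)
        if abs(candidate - theta) < _NEWTON_TOL:
            return candidate, True, False
        theta = candidate
    return theta, False, False


def mle_from_design(design: BankDesign, x: np.ndarray) -> PersonEstimate:
    if len(x) == 0:
        raise ValueError("MLE requires at least one response")
    extreme_min = bool(np.all(x == 0))
    extreme_max = bool(np.all(x == design.m))
    if extreme_min or extreme_max:
        theta = -THETA_BOUND if extreme_min else THETA_BOUND
        converged, at_boundary = True, True
    else:
        theta, converged, at_boundary = _newton_argmax(
            lambda t: design.loglik_grad_hess(t, x), THETA_BOUND
        )
        at_boundary = at_boundary or abs(theta) >= THETA_BOUND
    info = float(np.sum(design.information(np.array([theta]))))
    return PersonEstimate(
        theta=float(theta),
        sem=_sem_from_info(info),
        method=Estimator.MLE,
        n_items=len(x),
        converged=converged,
        at_boundary=at_boundary,
    )


def map_from_design(design: BankDesign, x: np.ndarray) -> PersonEstimate:
    if len(x) == 0:
        return PersonEstimate(theta=0.0, sem=1.0, method=Estimator.MAP, n_items=0)

    def grad_hess(t: float) -> tuple[float, float]:
        g, h = design.loglik_grad_hess(t, x)
        return g - t, h - 1.0

    theta, converged, at_boundary = _newton_argmax(grad_hess, THETA_BOUND)
    info = float(np.sum(design.information(np.array([theta]))))
    return PersonEstimate(
        theta=float(theta),
        sem=_sem_from_info(info + 1.0),
        method=Estimator.MAP,
        n_items=len(x),
        converged=converged,
        at_boundary=at_boundary,
    )


def eap_nodes_weights(n_nodes: int = EAP_NODES) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and standard-normal weights (unnormalized)."""
    nodes = np.linspace(-THETA_BOUND, THETA_BOUND, n_nodes)
    weights = np.exp(-0.5 * nodes**2)
    return nodes, weights


def eap_from_design(
    design: BankDesign | None,
    x: np.ndarray,
    n_nodes: int = EAP_NODES,
) -> PersonEstimate:
    nodes, weights = eap_nodes_weights(n_nodes)
    if design is not None and len(x) > 0:
        log_post = design.log_likelihood(nodes, x) + np.log(weights)
    else:
        log_post = np.log(weights)
    log_post = log_post - log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    theta = float(np.sum(post * nodes))
    var = float(np.sum(post * (nodes - theta) ** 2))
    return PersonEstimate(
        theta=theta,
        sem=float(np.sqrt(max(var, _MIN_INFO))),
        method=Estimator.EAP,
        n_items=len(x),
        converged=True,
        at_boundary=False,
    )


def estimate_mle(responses: Sequence[Response]) -> PersonEstimate:
    """Maximum-likelihood person estimate.

    Raises
    ------
    ValueError
        If ``responses`` is empty (the likelihood is flat) or a category
        is out of range.
    """
    if not responses:
        raise ValueError("MLE requires at least one response")
    return mle_from_design(*_unpack(responses))


def estimate_map(responses: Sequence[Response]) -> PersonEstimate:
    """Posterior-mode estimate under a standard-normal prior.

    Defined for any pattern, including the empty one (prior mode 0).
    """
    if not responses:
        return PersonEstimate(theta=0.0, sem=1.0, method=Estimator.MAP, n_items=0)
    return map_from_design(*_unpack(responses))


def estimate_eap(
    responses: Sequence[Response], n_nodes: int = EAP_NODES
) -> PersonEstimate:
    """Posterior-mean estimate under a standard-normal prior.

    The posterior is evaluated on ``n_nodes`` equally spaced nodes over
    the trait range and renormalized; the SEM is the posterior SD.
    """
    if not responses:
        return eap_from_design(None, np.array([], dtype=np.int64), n_nodes)
    design, x = _unpack(responses)
    return eap_from_design(design, x, n_nodes)


_ESTIMATORS = {
    Estimator.MLE: estimate_mle,
    Estimator.MAP: estimate_map,
    Estimator.EAP: estimate_eap,
}

_DESIGN_ESTIMATORS = {
    Estimator.MLE: mle_from_design,
    Estimator.MAP: map_from_design,
    Estimator.EAP: eap_from_design,
}


def estimate(responses: Sequence[Response], method: Estimator | str) -> PersonEstimate:
    """Score a response pattern with the chosen estimator."""
    return _ESTIMATORS[Estimator(method)](responses)


def estimate_from_design(
    design: BankDesign, x: np.ndarray, method: Estimator | str
) -> PersonEstimate:
    """Design-based entry point used by the adaptive engine."""
    return _DESIGN_ESTIMATORS[Estimator(method)](design, x)
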