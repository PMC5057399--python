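"""Adaptive test administration (CAT).

A session starts with one randomly selected item (seed-controlled, or
pinned for clinical determinism), then repeatedly administers the
unadministered item with maximal Fisher information at the provisional
person measure, re-estimates after every response, and stops once at
least ``min_items`` (7) have been given and the two precision clauses
hold:

* person reliability ``1 - SEM^2`` has reached 0.90, and
* the mean of the last three absolute changes in the provisional
  measure (``resi``) has dropped below 0.05

(conjunction by default; :class:`StopRule` can combine them
disjunctively instead), or when the bank is exhausted. Two diagnostics
are carried along: ``resi`` as above, and ``corr``, the Pearson
correlation of the last five provisional measures against their step
numbers — a flat trend (small ``|corr|``) signals a settled estimate.

Person-fit statistics (infit/outfit mean-squares and per-item
standardized residuals ``z``; responses with ``|z| >= 2.0`` are flagged)
screen for careless, mistaken, or otherwise aberrant responding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimation import Estimator, PersonEstimate, estimate_from_design
from .irt import BankDesign, Response, bank_design
from .item_bank import ItemBank, ItemParameters
from .simulate import ResponseMatrix

#: |z| threshold above which a response is flagged as unexpected.
Z_FLAG = 2.0

#: Number of provisional-theta changes averaged into ``resi``.
RESI_WINDOW = 3

#: Number of trailing provisional thetas used for the ``corr`` trend.
CORR_WINDOW = 5


class StopReason(str, Enum):
    RELIABILITY = "reliability"
    CONVERGENCE = "convergence"
    BANK_EXHAUSTED = "bank_exhausted"


@dataclass(frozen=True)
class StopRule:
    """Compound CAT stop rule (defaults are the engine's study settings).

    With ``require_both`` (the default) the session ends only once the
    reliability target is met *and* the provisional measure has settled
    (``resi`` under its threshold); set it to ``False`` for the
    disjunctive reading, which ends at whichever clause fires first.
    A bank whose total information cannot reach the reliability target
    is simply exhausted under the conjunctive rule.
    """

    min_items: int = 7
    reliability_target: float = 0.90
    resi_threshold: float = 0.05
    require_both: bool = True

    def __post_init__(self) -> None:
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")
        if not 0 < self.reliability_target < 1:
            raise ValueError("reliability_target must be in (0, 1)")
        if not self.resi_threshold > 0:
            raise ValueError("resi_threshold must be positive")


def _trailing_resi(thetas: Sequence[float]) -> float:
    """Mean absolute change over the last ``RESI_WINDOW`` steps (nan if
    fewer than ``RESI_WINDOW + 1`` provisional estimates exist)."""
    if len(thetas) < RESI_WINDOW + 1:
        return float("nan")
    tail = np.asarray(thetas[-(RESI_WINDOW + 1):], dtype=float)
    return float(np.mean(np.abs(np.diff(tail))))


def _trailing_corr(thetas: Sequence[float]) -> float:
    """Pearson correlation of the last ``CORR_WINDOW`` provisional thetas
    with their step numbers; 0 for a perfectly flat trend, nan if fewer
    than ``CORR_WINDOW`` estimates exist."""
    if len(thetas) < CORR_WINDOW:
        return float("nan")
    tail = np.asarray(thetas[-CORR_WINDOW:], dtype=float)
    if np.ptp(tail) == 0.0:
        return 0.0
    steps = np.arange(CORR_WINDOW, dtype=float)
    return float(np.corrcoef(tail, steps)[0, 1])


@dataclass
class CatSession:
    """One person's adaptive trajectory."""

    bank_name: str
    method: Estimator
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta_trace: list[float] = field(default_factory=list)
    sem_trace: list[float] = field(default_factory=list)
    stop_reason: StopReason | None = None
    final: PersonEstimate | None = None

    @property
    def n_administered(self) -> int:
        return len(self.administered)

    @property
    def resi(self) -> float:
        return _trailing_resi(self.theta_trace)

    @property
    def corr(self) -> float:
        return _trailing_corr(self.theta_trace)

    @property
    def finished(self) -> bool:
        return self.stop_reason is not None

    def log_frame(self) -> pd.DataFrame:
        """Per-step session log (step, item, response, theta, sem, resi, corr)."""
        n = self.n_administered
        return pd.DataFrame(
            {
                "step": np.arange(1, n + 1),
                "item_id": self.administered,
                "response": self.responses,
                "theta": self.theta_trace,
                "sem": self.sem_trace,
                "resi": [_trailing_resi(self.theta_trace[: k + 1]) for k in range(n)],
                "corr": [_trailing_corr(self.theta_trace[: k + 1]) for k in range(n)],
            }
        )


def _select_index(
    design: BankDesign,
    provisional_theta: float,
    administered_mask: np.ndarray,
    rng: np.random.Generator,
) -> int:
    if administered_mask.all():
        raise ValueError("item bank exhausted: no items left to select")
    if not administered_mask.any():
        return int(rng.integers(len(design)))
    info = design.information(np.array([provisional_theta]))[0]
    info[administered_mask] = -np.inf
    return int(np.argmax(info))  # argmax takes the lowest bank position on ties


def select_next_item(
    provisional_theta: float,
    bank: ItemBank,
    administered: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> str:
    """Choose the next item to administer.

    The first item is drawn uniformly at random from the pool; every
    later item is the one with maximal Fisher information at the
    provisional measure, ties broken by bank order.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    design = bank_design(bank)
    ids = bank.item_ids
    unknown = set(administered) - set(ids)
    if unknown:
        raise KeyError(f"administered ids not in bank: {sorted(unknown)}")
    mask = np.array([item_id in set(administered) for item_id in ids])
    return ids[_select_index(design, provisional_theta, mask, rng)]


def should_stop(
    session: CatSession,
    rule: StopRule = StopRule(),
    n_bank_items: int | None = None,
) -> tuple[bool, StopReason | None]:
    """Evaluate the compound stop rule on a session in progress.

    Requires ``n >= min_items``; then combines the reliability clause
    and the ``resi`` clause conjunctively or disjunctively per
    ``rule.require_both``. A session that consumes the whole bank stops
    regardless. The reported reason is ``reliability`` whenever the
    reliability clause holds at the stop, else ``convergence``.
    """
    n = session.n_administered
    if n < 1:
        raise ValueError("should_stop requires at least one administered item")
    if n_bank_items is not None and n >= n_bank_items:
        return True, StopReason.BANK_EXHAUSTED
    if n < rule.min_items:
        return False, None
    sem = session.sem_trace[-1]
    rel_ok = 1.0 - sem**2 >= rule.reliability_target
    resi = session.resi
    resi_ok = bool(np.isfinite(resi) and resi < rule.resi_threshold)
    stop = (rel_ok and resi_ok) if rule.require_both else (rel_ok or resi_ok)
    if not stop:
        return False, None
    return True, StopReason.RELIABILITY if rel_ok else StopReason.CONVERGENCE


Responder = Callable[[int, ItemParameters], int]


def model_responder(
    true_theta: float, bank: ItemBank, rng: np.random.Generator
) -> Responder:
    """Responder that draws each answer from the model at ``true_theta``."""
    design = bank_design(bank)
    probs = design.probs(np.array([true_theta]))[0]  # (n_items, m_max + 1)

    def respond(index: int, item: ItemParameters) -> int:
        cdf = np.cumsum(probs[index, : item.max_score + 1])
        return int(np.searchsorted(cdf, rng.random(), side="right"))

    return respond


def matrix_responder(matrix: ResponseMatrix, person: int) -> Responder:
    """Responder replaying one person's row of a pre-simulated matrix."""
    row = matrix.responses[person]

    def respond(index: int, item: ItemParameters) -> int:
        return int(row[index])

    return respond


def run_cat(
    bank: ItemBank,
    method: Estimator | str,
    true_theta: float | None = None,
    responder: Responder | None = None,
    seed: int | np.random.Generator = 0,
    stop_rule: StopRule = StopRule(),
    first_item: str | None = None,
) -> CatSession:
    """Administer one full adaptive session and return its trajectory.

    Answers come either from ``responder`` (e.g. a pre-simulated response
    matrix, or an interactive prompt) or are drawn from the model at
    ``true_theta``. The provisional measure feeding item selection is the
    session estimator's current estimate; under MLE an extreme pattern
    contributes its boundary value (+/-4) until an interior maximum
    appears. ``first_item`` pins the opening item instead of drawing it
    at random.
    """
    method = Estimator(method)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if responder is None:
        if true_theta is None:
            raise ValueError("provide either true_theta or a responder")
        responder = model_responder(true_theta, bank, rng)
    design = bank_design(bank)
    ids = bank.item_ids
    session = CatSession(bank_name=bank.name, method=method)
    mask = np.zeros(len(bank), dtype=bool)
    indices: list[int] = []

    while True:
        if not indices and first_item is not None:
            idx = ids.index(first_item)
        else:
            theta = session.theta_trace[-1] if session.theta_trace else 0.0
            idx = _select_index(design, theta, mask, rng)
        item = bank[idx]
        x = responder(idx, item)
        if not 0 <= int(x) <= item.max_score:
            raise ValueError(
                f"responder returned {x!r} for item {item.item_id!r} "
                f"(valid categories 0..{item.max_score})"
            )
        indices.append(idx)
        mask[idx] = True
        session.administered.append(item.item_id)
        session.responses.append(int(x))
        est = estimate_from_design(
            design.subset(indices), np.array(session.responses), method
        )
        session.theta_trace.append(est.theta)
        session.sem_trace.append(est.sem)
        stop, reason = should_stop(session, stop_rule, n_bank_items=len(bank))
        if stop:
            session.stop_reason = reason
            session.final = est
            return session


@dataclass(frozen=True)
class PersonFit:
    """Residual-based person-fit summary for a scored response pattern."""

    infit_mnsq: float
    outfit_mnsq: float
    z_scores: np.ndarray  # per response; nan where the item was degenerate
    flagged: tuple[str, ...]  # item ids with |z| >= Z_FLAG


def person_fit(responses: Sequence[Response], theta: float) -> PersonFit:
    """Infit/outfit mean-squares and standardized residuals at ``theta``.

    ``z_i = (x_i - E_i) / sqrt(W_i)`` with ``E_i``/``W_i`` the model
    expected score and score variance. Outfit is the mean of ``z_i^2``,
    infit the information-weighted ratio ``sum (x_i - E_i)^2 / sum W_i``.
    Items whose score variance vanishes at ``theta`` (extreme measures)
    are excluded with a warning.
    """
    if not responses:
        raise ValueError("person_fit requires at least one response")
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    design = BankDesign.from_items([item for item, _ in responses])
    x = np.array([x for _, x in responses], dtype=float)
    e, w = design.score_moments(np.array([theta]))
    e, w = e[0], w[0]
    usable = w > 1e-10
    if not usable.all():
        excluded = [responses[i][0].item_id for i in np.flatnonzero(~usable)]
        warnings.warn(
            f"excluding degenerate items from person fit at theta={theta:g}: "
            f"{excluded}",
            stacklevel=2,
        )
    if not usable.any():
        raise ValueError("no item has positive score variance at this theta")
    z = np.full(len(x), np.nan)
    z[usable] = (x[usable] - e[usable]) / np.sqrt(w[usable])
    outfit = float(np.mean(z[usable] ** 2))
    infit = float(np.sum((x[usable] - e[usable]) ** 2) / np.sum(w[usable]))
    flagged = tuple(
        responses[i][0].item_id
        for i in np.flatnonzero(usable & (np.abs(np.where(usable, z, 0.0)) >= Z_FLAG))
    )
    return PersonFit(infit_mnsq=infit, outfit_mnsq=outfit, z_scores=z, flagged=flagged)
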