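"""CAT versus full-test (NAT) comparison.

Non-adaptive testing (NAT) scores every item of the instrument; the
adaptive engine answers a person-specific subset of the same simulated
response matrix. The comparison reports, per (scale, estimator) cell:

* the Pearson correlation between paired CAT and NAT measures;
* the *different-number ratio* — the percentage of persons whose CAT and
  NAT measures differ significantly under a per-person two-sample z
  test, ``z = (theta_CAT - theta_NAT) / sqrt(SEM_CAT^2 + SEM_NAT^2)``,
  ``|z| > 1.96`` at the 5% level (a ratio below 5% declares CAT and NAT
  equivalent);
* efficiency — the percentage of item administrations saved by CAT,
  ``100 (L - mean items) / L`` for a full length ``L``;
* Cronbach's alpha of the raw response matrix (internal consistency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cat import CatSession, StopRule, matrix_responder, run_cat
from .estimation import Estimator, PersonEstimate, estimate_from_design
from .irt import bank_design
from .item_bank import ItemBank
from .simulate import ResponseMatrix

#: Two-sided 5% critical value of the standard normal.
Z_CRIT_5PCT = 1.959963984540054


@dataclass(frozen=True)
class ComparisonReport:
    """One (scale, estimator) cell of the CAT-vs-NAT comparison.

    ``pearson_r`` correlates CAT finals with full-bank estimates of the
    matrix; ``pearson_r_true`` correlates them with the simulated
    generating (NAT) measures when those are known — the recovery
    correlation a simulation design reports, and the only one defined
    when the full-bank estimate is information-starved.
    """

    scale: str
    method: Estimator
    pearson_r: float
    diff_ratio_pct: float
    mean_items_cat: float
    efficiency_pct: float
    cronbach_alpha: float
    pearson_r_true: float = float("nan")


def nat_estimate(
    matrix: ResponseMatrix, bank: ItemBank, method: Estimator | str
) -> list[PersonEstimate]:
    """Score every person on the complete instrument."""
    if not matrix.is_complete():
        raise ValueError("NAT scoring requires a complete response matrix")
    if matrix.item_ids != bank.item_ids:
        raise ValueError(
            f"matrix items do not match bank {bank.name!r}"
        )
    method = Estimator(method)
    design = bank_design(bank)
    return [
        estimate_from_design(design, row, method) for row in matrix.responses
    ]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length measure vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def diff_ratio(
    cat: Sequence[PersonEstimate],
    nat: Sequence[PersonEstimate],
    alpha_level: float = 0.05,
) -> float:
    """Percentage of persons whose paired CAT/NAT measures differ
    significantly at ``alpha_level`` (per-person z test on the paired
    difference, pooled SEMs)."""
    if len(cat) != len(nat) or not cat:
        raise ValueError("diff_ratio needs nonempty paired estimate lists")
    z_crit = float(stats.norm.ppf(1.0 - alpha_level / 2.0))
    z = np.array(
        [
            (c.theta - n.theta) / np.sqrt(c.sem**2 + n.sem**2)
            for c, n in zip(cat, nat)
        ]
    )
    return float(100.0 * np.mean(np.abs(z) > z_crit))


def efficiency(sessions: Sequence[CatSession], full_len: int) -> float:
    """Percentage of item length saved by CAT relative to the full test."""
    if not sessions:
        raise ValueError("efficiency needs at least one session")
    if full_len <= 0:
        raise ValueError("full_len must be positive")
    mean_items = float(np.mean([s.n_administered for s in sessions]))
    return 100.0 * (full_len - mean_items) / full_len


def cronbach_alpha(matrix: ResponseMatrix | np.ndarray) -> float:
    """Cronbach's alpha of a complete persons x items score matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(total score))``
    with ``n - 1`` sample variances.
    """
    data = matrix.responses if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("cronbach_alpha needs at least 2 persons and 2 items")
    if np.any(data < 0):
        raise ValueError("cronbach_alpha requires a complete matrix")
    k = data.shape[1]
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("cronbach_alpha undefined: total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def run_cat_sessions(
    bank: ItemBank,
    method: Estimator | str,
    seed: int,
    stop_rule: StopRule = StopRule(),
    *,
    true_thetas: Sequence[float] | None = None,
    matrix: ResponseMatrix | None = None,
    redraw: bool = True,
) -> list[CatSession]:
    """Run one CAT session per person.

    With ``redraw`` (the default study design) every administered item
    is answered by a fresh draw from the model at the person's true
    measure, so CAT and NAT carry independent response-sampling noise —
    the comparison then measures two genuinely separate test sittings.
    With ``redraw=False`` sessions replay the pre-simulated ``matrix``
    instead (CAT answers a subset of exactly the responses NAT scores),
    which isolates item-selection effects from response noise.
    """
    rng = np.random.default_rng(seed)
    if redraw:
        thetas = true_thetas
        if thetas is None and matrix is not None:
            thetas = matrix.true_thetas
        if thetas is None:
            raise ValueError("redraw sessions need true_thetas (or a matrix carrying them)")
        return [
            run_cat(bank, method, true_theta=float(theta), seed=rng, stop_rule=stop_rule)
            for theta in thetas
        ]
    if matrix is None:
        raise ValueError("replay sessions need the pre-simulated matrix")
    return [
        run_cat(
            bank,
            method,
            responder=matrix_responder(matrix, person),
            seed=rng,
            stop_rule=stop_rule,
        )
        for person in range(matrix.n_persons)
    ]


def compare_cat_nat(
    matrix: ResponseMatrix,
    bank: ItemBank,
    method: Estimator | str,
    seed: int,
    stop_rule: StopRule = StopRule(),
    sessions: Sequence[CatSession] | None = None,
    nat: Sequence[PersonEstimate] | None = None,
    redraw: bool = True,
) -> ComparisonReport:
    """Full CAT-vs-NAT comparison for one (scale, estimator) cell.

    Precomputed ``sessions``/``nat`` estimates may be passed to avoid
    rescoring when several statistics share one simulation.
    """
    method = Estimator(method)
    if nat is None:
        nat = nat_estimate(matrix, bank, method)
    if sessions is None:
        sessions = run_cat_sessions(
            bank, method, seed, stop_rule, matrix=matrix, redraw=redraw
        )
    cat_finals = [s.final for s in sessions]
    cat_thetas = [e.theta for e in cat_finals]
    r_true = (
        pearson_r(cat_thetas, matrix.true_thetas)
        if matrix.true_thetas is not None
        else float("nan")
    )
    return ComparisonReport(
        scale=bank.name,
        method=method,
        pearson_r=pearson_r(cat_thetas, [e.theta for e in nat]),
        diff_ratio_pct=diff_ratio(cat_finals, nat),
        mean_items_cat=float(np.mean([s.n_administered for s in sessions])),
        efficiency_pct=efficiency(sessions, len(bank)),
        cronbach_alpha=cronbach_alpha(matrix),
        pearson_r_true=r_true,
    )


def report_frame(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    """Tabulate comparison cells (one row per scale x estimator)."""
    return pd.DataFrame(
        [
            {
                "scale": r.scale,
                "method": r.method.value,
                "pearson_r": r.pearson_r,
                "pearson_r_true": r.pearson_r_true,
                "diff_ratio_pct": r.diff_ratio_pct,
                "mean_items_cat": r.mean_items_cat,
                "efficiency_pct": r.efficiency_pct,
                "cronbach_alpha": r.cronbach_alpha,
            }
            for r in reports
        ]
    )
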