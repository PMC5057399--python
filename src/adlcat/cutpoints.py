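"""Norm-referenced cutpoints for person strata.

Without a gold-standard diagnosis there is no empirical ROC curve to
cut, so strata boundaries are derived from the norm itself:

1. scale reliability (Cronbach's alpha) fixes how many person strata
   can be distinguished with 95% confidence, via the separation index
   ``G = sqrt(rel / (1 - rel))`` and ``H = floor((4 G + 1) / 3)``
   (0.67 -> 2, 0.80 -> 3, 0.90 -> 4, 0.94 -> 5, ...);
2. one-dimensional k-means clusters the person measures into that many
   ascending strata (solved exactly, hence deterministically);
3. for each adjacent pair of clusters, a normal distribution is fitted
   to each cluster (its mean and member SD) and a brute-force grid
   search places the cut where specificity plus sensitivity is maximal
   — specificity is the lower cluster's mass below the cut,
   sensitivity the upper cluster's mass above it;
4. cuts are reported on the logit scale and as T scores
   (``T = 50 + 10 theta``; population mean 50, SD 10).

By convention the four default strata are "Not Active", "Fairly
Active", "Active", and "Very Active", and the stratum count is capped
at four even when reliability would support five.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Default stratum labels, lowest functioning first.
DEFAULT_LABELS = ("Not Active", "Fairly Active", "Active", "Very Active")

#: Default cap on the number of strata.
DEFAULT_MAX_STRATA = 4

#: Default grid step (logits) for the brute-force cut search.
GRID_STEP = 0.01


@dataclass(frozen=True)
class Cluster:
    """One ascending stratum of person measures."""

    mean: float
    sd: float
    size: int


@dataclass(frozen=True)
class CutPoint:
    """Boundary between two adjacent strata."""

    theta: float
    t_score: float
    specificity: float
    sensitivity: float


@dataclass(frozen=True)
class StratumResult:
    """Full stratification of one set of person measures."""

    labels: tuple[str, ...]
    clusters: tuple[Cluster, ...]
    cuts: tuple[CutPoint, ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(c.size for c in self.clusters)

    @property
    def cut_theta(self) -> tuple[float, ...]:
        return tuple(c.theta for c in self.cuts)

    @property
    def cut_t(self) -> tuple[float, ...]:
        return tuple(c.t_score for c in self.cuts)


def strata_count(reliability: float) -> int:
    """Number of person strata distinguishable at 95% confidence.

    Uses the separation index ``G = sqrt(rel / (1 - rel))`` and
    ``H = floor((4 G + 1) / 3)``, with a floor of one stratum.
    """
    if not 0.0 <= reliability < 1.0:
        raise ValueError(f"reliability must be in [0, 1), got {reliability}")
    g = math.sqrt(reliability / (1.0 - reliability))
    return max(1, math.floor((4.0 * g + 1.0) / 3.0))


def t_score(theta: float | np.ndarray) -> float | np.ndarray:
    """Rescale a logit measure to the T metric (mean 50, SD 10)."""
    scaled = 50.0 + 10.0 * np.asarray(theta, dtype=float)
    return float(scaled) if np.ndim(theta) == 0 else scaled


def kmeans_1d(
    measures: Sequence[float], k: int, seed: int | None = None
) -> tuple[Cluster, ...]:
    """Exact k-means on a line, returned as ascending clusters.

    In one dimension the optimal k-means partition is contiguous on the
    sorted data, so the global optimum is found deterministically by
    dynamic programming over split points (no random initialization;
    ``seed`` is accepted for interface symmetry but unused). Each
    cluster's SD comes from its own members; a singleton cluster falls
    back to the pooled SD.
    """
    x = np.sort(np.asarray(measures, dtype=float))
    n = len(x)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def segment_cost(i: np.ndarray, j: int) -> np.ndarray:
        """Within-segment sum of squares for x[i..j] inclusive, vector in i."""
        length = j - i + 1
        total = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - total**2 / length

    # dp[c, j]: optimal cost of splitting x[0..j] into c+1 clusters
    dp = np.empty((k, n))
    split = np.zeros((k, n), dtype=int)
    dp[0] = np.array([segment_cost(np.array([0]), j)[0] for j in range(n)])
    for c in range(1, k):
        dp[c] = np.inf
        for j in range(c, n):
            i = np.arange(c, j + 1)  # first index of the last cluster
            candidates = dp[c - 1][i - 1] + segment_cost(i, j)
            arg = int(np.argmin(candidates))
            dp[c, j] = candidates[arg]
            split[c, j] = c + arg
    # backtrack cluster boundaries
    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = split[c, j]
        bounds.append(i)
        j = i - 1
    bounds = [0] + bounds[::-1] + [n]
    pooled_sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    clusters = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        members = x[a:b]
        sd = float(np.std(members, ddof=1)) if len(members) > 1 else pooled_sd
        clusters.append(Cluster(mean=float(members.mean()), sd=sd, size=len(members)))
    return tuple(clusters)


def best_cut(
    mu_lo: float,
    sd_lo: float,
    mu_hi: float,
    sd_hi: float,
    grid_step: float = GRID_STEP,
) -> tuple[float, float, float]:
    """Cut between two normal clusters maximizing specificity + sensitivity.

    Brute-force grid search of ``c`` over ``[mu_lo, mu_hi]``;
    ``Sp(c) = Phi((c - mu_lo) / sd_lo)`` (lower cluster correctly below
    the cut) and ``Se(c) = 1 - Phi((c - mu_hi) / sd_hi)`` (upper cluster
    correctly above). Returns ``(cut, sensitivity, specificity)``. The
    argmax coincides with the point where the two normal densities are
    equal, up to the grid resolution.
    """
    if not mu_lo < mu_hi:
        raise ValueError(f"need mu_lo < mu_hi, got {mu_lo} >= {mu_hi}")
    if not (sd_lo > 0 and sd_hi > 0):
        raise ValueError("cluster SDs must be positive")
    grid = np.arange(mu_lo, mu_hi + grid_step / 2.0, grid_step)
    sp = stats.norm.cdf((grid - mu_lo) / sd_lo)
    se = 1.0 - stats.norm.cdf((grid - mu_hi) / sd_hi)
    i = int(np.argmax(sp + se))
    return float(grid[i]), float(se[i]), float(sp[i])


def derive_cutpoints(
    measures: Sequence[float],
    reliability: float | None = None,
    n_strata: int | None = None,
    max_strata: int = DEFAULT_MAX_STRATA,
    labels: Sequence[str] | None = None,
    grid_step: float = GRID_STEP,
) -> StratumResult:
    """Run the full norm-referenced cutpoint procedure.

    The stratum count comes from ``reliability`` via
    :func:`strata_count` (capped at ``max_strata``) unless ``n_strata``
    overrides it directly — the study fixes four strata for every scale.
    """
    if n_strata is None:
        if reliability is None:
            raise ValueError("provide either reliability or n_strata")
        n_strata = min(strata_count(reliability), max_strata)
    measures = np.asarray(measures, dtype=float)
    if len(measures) < 2 * n_strata:
        raise ValueError(
            f"need at least {2 * n_strata} measures for {n_strata} strata"
        )
    clusters = kmeans_1d(measures, n_strata)
    cuts = []
    for lo, hi in zip(clusters[:-1], clusters[1:]):
        cut, se, sp = best_cut(lo.mean, lo.sd, hi.mean, hi.sd, grid_step)
        cuts.append(
            CutPoint(
                theta=cut, t_score=float(t_score(cut)), specificity=sp, sensitivity=se
            )
        )
    if labels is None:
        labels = (
            DEFAULT_LABELS
            if n_strata == len(DEFAULT_LABELS)
            else tuple(f"Stratum {j + 1}" for j in range(n_strata))
        )
    return StratumResult(labels=tuple(labels), clusters=clusters, cuts=tuple(cuts))
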