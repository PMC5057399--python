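"""Seeded simulation of person measures and full response matrices.

The study design draws 1000 person measures from the standard normal
population and generates one complete response matrix per scale by
inverse-CDF sampling from the model category probabilities, yielding a
1000 x 23 dichotomous CADL matrix and 1000 x 34 polytomous ADL matrices
(male and female parameterizations). One RNG stream is consumed in
persons-major order (all items of person 1, then person 2, ...), so a
matrix is bit-reproducible from its seed.

Category coding ascends with ability: 0 is the lowest-functioning
category, ``m`` the highest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .irt import bank_design
from .item_bank import ItemBank

#: Marker for unadministered (missing) cells in stored matrices.
MISSING = -1


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items integer category responses for one scale.

    ``responses`` uses ``-1`` for unadministered cells (complete matrices
    from :func:`simulate_matrix` have none). ``true_thetas`` is available
    in simulation designs only.
    """

    bank_name: str
    item_ids: tuple[str, ...]
    responses: np.ndarray  # (n_persons, n_items) int64
    true_thetas: np.ndarray | None = None

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=np.int64)
        object.__setattr__(self, "responses", resp)
        if resp.ndim != 2 or resp.shape[1] != len(self.item_ids):
            raise ValueError(
                f"responses shape {resp.shape} does not match "
                f"{len(self.item_ids)} item ids"
            )
        if self.true_thetas is not None:
            thetas = np.asarray(self.true_thetas, dtype=float)
            if len(thetas) != resp.shape[0]:
                raise ValueError("true_thetas length must equal the person count")
            object.__setattr__(self, "true_thetas", thetas)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def is_complete(self) -> bool:
        return bool(np.all(self.responses != MISSING))


def sample_thetas(n: int, seed: int) -> np.ndarray:
    """Draw ``n`` true person measures from N(0, 1), reproducibly."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return np.random.default_rng(seed).standard_normal(n)


def simulate_matrix(
    thetas: Sequence[float], bank: ItemBank, seed: int
) -> ResponseMatrix:
    """Generate a complete response matrix from the model.

    Each cell is drawn by inverse-CDF on one uniform draw against the
    item's category probabilities at that person's true measure. The
    uniform stream is persons-major, so the matrix is deterministic per
    seed, and per-person rows do not change when other rows are added.
    """
    thetas = np.asarray(thetas, dtype=float)
    design = bank_design(bank)
    rng = np.random.default_rng(seed)
    u = rng.random((len(thetas), len(bank)))
    probs = design.probs(thetas)  # (n_persons, n_items, m_max + 1)
    cdf = np.cumsum(probs, axis=2)
    responses = np.sum(u[:, :, None] > cdf[:, :, :-1], axis=2)
    responses = np.minimum(responses, design.m[None, :])
    return ResponseMatrix(
        bank_name=bank.name,
        item_ids=bank.item_ids,
        responses=responses.astype(np.int64),
        true_thetas=thetas,
    )


def write_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix to CSV (header = item ids, one person per
    row, optional ``true_theta`` column, ``-1`` for missing)."""
    df = pd.DataFrame(matrix.responses, columns=list(matrix.item_ids))
    if matrix.true_thetas is not None:
        df.insert(0, "true_theta", matrix.true_thetas)
    df.to_csv(path, index=False)


def load_matrix(path: str | Path, bank_name: str = "") -> ResponseMatrix:
    """Load a response matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path)
    thetas = None
    if "true_theta" in df.columns:
        thetas = df.pop("true_theta").to_numpy(dtype=float)
    return ResponseMatrix(
        bank_name=bank_name or Path(path).stem,
        item_ids=tuple(df.columns),
        responses=df.to_numpy(dtype=np.int64),
        true_thetas=thetas,
    )
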