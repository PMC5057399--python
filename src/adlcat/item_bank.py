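"""Item banks for ADL adaptive testing.

Two instruments are shipped as packaged fixtures, both calibrated on a
common logit metric in the source literature:

* ``CADL`` — the 23-item comprehensive ADL scale (Barthel Index plus
  Frenchay Activities Index items), dichotomous Rasch model with item
  difficulties ``delta``.
* ``ADL-male`` / ``ADL-female`` — the 34-item ADL scale under the
  generalized partial credit model (GPCM), with sex-specific
  discrimination and first-step difficulty for items 6-11.

Banks are plain CSV (``item_id, model, discrimination, step_1..step_3``,
empty cells for absent steps), so user-supplied banks load the same way.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence


class ModelFamily(str, Enum):
    """IRT model family of a single item."""

    RASCH_DICHOTOMOUS = "rasch_dichotomous"
    GPCM = "gpcm"


_FIXTURE_FILES = {
    "CADL": "cadl.csv",
    "ADL-male": "adl_male.csv",
    "ADL-female": "adl_female.csv",
}

#: Number of step difficulties the fixtures may carry per item.
MAX_STEPS = 3


class BankValidationError(ValueError):
    """Raised when an item bank violates a structural invariant."""


class BankParseError(ValueError):
    """Raised when a delimited bank file cannot be parsed."""


@dataclass(frozen=True)
class ItemParameters:
    """Calibrated parameters of one item.

    Parameters
    ----------
    item_id
        Short unique label, e.g. ``"BI 2: bathing"``.
    model
        Model family. Rasch dichotomous items are the 1-step,
        unit-discrimination special case of the GPCM.
    discrimination
        Slope ``a`` on the logit scale (``D`` in the ADL bank). Fixed to
        1.0 for Rasch items.
    step_difficulties
        Ordered step (threshold) difficulties ``b_1..b_m`` in logits.
        ``m`` equals the number of score categories minus one; the single
        step of a dichotomous item is its difficulty ``delta``.
    """

    item_id: str
    model: ModelFamily
    discrimination: float
    step_difficulties: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.item_id:
            raise BankValidationError("item_id must be non-empty")
        if not self.discrimination > 0:
            raise BankValidationError(
                f"item {self.item_id!r}: discrimination must be > 0, "
                f"got {self.discrimination}"
            )
        if len(self.step_difficulties) < 1:
            raise BankValidationError(
                f"item {self.item_id!r}: at least one step difficulty required"
            )
        if self.model is ModelFamily.RASCH_DICHOTOMOUS:
            if len(self.step_difficulties) != 1:
                raise BankValidationError(
                    f"item {self.item_id!r}: dichotomous Rasch items take "
                    f"exactly one step difficulty"
                )
            if self.discrimination != 1.0:
                raise BankValidationError(
                    f"item {self.item_id!r}: dichotomous Rasch discrimination "
                    f"is fixed at 1.0"
                )
        object.__setattr__(
            self, "step_difficulties", tuple(float(b) for b in self.step_difficulties)
        )

    @property
    def max_score(self) -> int:
        """Highest score category ``m`` (categories run 0..m)."""
        return len(self.step_difficulties)


@dataclass(frozen=True)
class ItemBank:
    """Named, ordered collection of items defining one scale."""

    name: str
    items: tuple[ItemParameters, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise BankValidationError(f"bank {self.name!r} has no items")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"bank {self.name!r}: duplicate item_ids {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, index: int) -> ItemParameters:
        return self.items[index]

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no item {item_id!r} in bank {self.name!r}")


def _parse_row(row: dict[str, str], row_number: int) -> ItemParameters:
    try:
        item_id = (row["item_id"] or "").strip()
        model = ModelFamily((row["model"] or "").strip())
        discrimination = float(row["discrimination"])
        steps = []
        for k in range(1, MAX_STEPS + 1):
            cell = (row.get(f"step_{k}") or "").strip()
            if cell == "":
                break
            steps.append(float(cell))
    except (KeyError, ValueError) as exc:
        raise BankParseError(f"row {row_number}: malformed item row ({exc})") from exc
    return ItemParameters(
        item_id=item_id,
        model=model,
        discrimination=discrimination,
        step_difficulties=tuple(steps),
    )


def load_bank(path: str | Path, name: str | None = None) -> ItemBank:
    """Load an item bank from a CSV file.

    The file must carry a header row with columns ``item_id, model,
    discrimination, step_1, step_2, step_3``; trailing step cells may be
    empty. Row order is preserved.

    Raises
    ------
    BankParseError
        If a row is malformed (the error names the offending row).
    BankValidationError
        If the parsed bank violates an invariant (non-positive
        discrimination, duplicate ids, empty file).
    """
    path = Path(path)
    items: list[ItemParameters] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "item_id" not in reader.fieldnames:
            raise BankParseError(f"{path}: missing header row")
        for row_number, row in enumerate(reader, start=2):
            items.append(_parse_row(row, row_number))
    if not items:
        raise BankParseError(f"{path}: file contains no items")
    return ItemBank(name=name or path.stem, items=tuple(items))


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write ``bank`` to CSV in the same dialect :func:`load_bank` reads.

    Round-trips parameter values exactly (``repr`` of the stored floats).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["item_id", "model", "discrimination"]
            + [f"step_{k}" for k in range(1, MAX_STEPS + 1)]
        )
        for it in bank.items:
            steps = [repr(b) for b in it.step_difficulties]
            steps += [""] * (MAX_STEPS - len(steps))
            writer.writerow([it.item_id, it.model.value, repr(it.discrimination), *steps])


def fixture_bank(name: str) -> ItemBank:
    """Return one of the packaged banks: ``CADL``, ``ADL-male``, ``ADL-female``."""
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture bank {name!r}; available: {sorted(_FIXTURE_FILES)}"
        ) from None
    resource = importlib.resources.files("adlcat.data").joinpath(filename)
    with importlib.resources.as_file(resource) as path:
        return load_bank(path, name=name)


def fixture_names() -> Sequence[str]:
    return tuple(_FIXTURE_FILES)
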