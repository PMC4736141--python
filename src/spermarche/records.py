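"""Per-animal records and cohort CSV input/output.

A cohort is a flat list of :class:`AnimalRecord`, one row per animal (for
on-farm calliper measurements) or per excised organ pair (castration or
necropsy material).  Testicular size is carried as the left and right
lengths in cm together with their arithmetic mean, which is the response
of the growth model and the predictor of the sperm-presence model.  Body
condition score (BCS, 1-5 in half steps) and the binary sperm-presence
outcome are optional: BCS is only scored on live animals and sperm
presence can only be verified on excised organs.

The on-disk format is a plain CSV with the header::

    animal_id,source,age_months,bcs,left_length_cm,right_length_cm,mean_length_cm,sperm_present

Empty fields encode missing values; ``sperm_present`` is written ``0``/``1``.
Floats are serialized with :func:`repr` so a write/read round trip is exact.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Source",
    "AnimalRecord",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
]

_MEAN_TOL = 1e-9


class Source(str, enum.Enum):
    """How the length measurement was obtained."""

    IN_VIVO = "in_vivo"  # calliper on the live animal; includes scrotal layers
    CASTRATION = "castration"  # excised organ pair from routine castration
    NECROPSY = "necropsy"  # excised organ pair collected post mortem

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


EX_VIVO_SOURCES = (Source.CASTRATION, Source.NECROPSY)

CSV_COLUMNS = [
    "animal_id",
    "source",
    "age_months",
    "bcs",
    "left_length_cm",
    "right_length_cm",
    "mean_length_cm",
    "sperm_present",
]


@dataclass(frozen=True)
class AnimalRecord:
    """One animal (or organ pair) with its measurements.

    Invariants enforced on construction: positive age and lengths,
    ``mean_length_cm`` equal to the arithmetic mean of the two sides
    (within 1e-9), and BCS within [1, 5] when present.
    """

    animal_id: str
    source: Source
    age_months: float
    left_length_cm: float
    right_length_cm: float
    mean_length_cm: float
    bcs: float | None = None
    sperm_present: bool | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))
        if not self.age_months > 0:
            raise ValueError(
                f"record {self.animal_id!r}: age_months must be positive, "
                f"got {self.age_months}"
            )
        for side in ("left_length_cm", "right_length_cm", "mean_length_cm"):
            if not getattr(self, side) > 0:
                raise ValueError(
                    f"record {self.animal_id!r}: {side} must be positive, "
                    f"got {getattr(self, side)}"
                )
        expected = 0.5 * (self.left_length_cm + self.right_length_cm)
        if abs(self.mean_length_cm - expected) > _MEAN_TOL:
            raise ValueError(
                f"record {self.animal_id!r}: mean_length_cm "
                f"{self.mean_length_cm} is not the mean of left/right "
                f"({expected})"
            )
        if self.bcs is not None and not (1.0 <= self.bcs <= 5.0):
            raise ValueError(
                f"record {self.animal_id!r}: bcs must lie in [1, 5], "
                f"got {self.bcs}"
            )

    @classmethod
    def from_lengths(
        cls,
        animal_id: str,
        source: Source | str,
        age_months: float,
        left_length_cm: float,
        right_length_cm: float,
        bcs: float | None = None,
        sperm_present: bool | None = None,
    ) -> "AnimalRecord":
        """Build a record computing the mean length from the two sides."""
        return cls(
            animal_id=animal_id,
            source=Source(source),
            age_months=age_months,
            left_length_cm=left_length_cm,
            right_length_cm=right_length_cm,
            mean_length_cm=0.5 * (left_length_cm + right_length_cm),
            bcs=bcs,
            sperm_present=sperm_present,
        )

    def with_sperm(self, present: bool) -> "AnimalRecord":
        return replace(self, sperm_present=present)


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_cohort_csv(records: Iterable[AnimalRecord], path: str | Path) -> None:
    """Write a cohort to CSV in the canonical column order."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.animal_id,
                    rec.source.value,
                    _fmt(rec.age_months),
                    _fmt(rec.bcs),
                    _fmt(rec.left_length_cm),
                    _fmt(rec.right_length_cm),
                    _fmt(rec.mean_length_cm),
                    "" if rec.sperm_present is None else int(rec.sperm_present),
                ]
            )


def _parse_float(field: str, value: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"row {row}: malformed {field} value {value!r}") from None


def read_cohort_csv(path: str | Path) -> list[AnimalRecord]:
    """Read and validate a cohort CSV.

    Errors carry the 1-based data row number.  Missing ``bcs`` and
    ``sperm_present`` fields are tolerated; the stored mean length is
    checked against the recomputed left/right mean.
    """
    path = Path(path)
    records: list[AnimalRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != CSV_COLUMNS:
            raise ValueError(
                f"{path}: expected header {','.join(CSV_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=1):
            try:
                source = Source(row["source"])
            except ValueError:
                raise ValueError(
                    f"row {i}: unknown source value {row['source']!r}"
                ) from None
            sperm_raw = (row["sperm_present"] or "").strip()
            if sperm_raw == "":
                sperm: bool | None = None
            elif sperm_raw in {"0", "1"}:
                sperm = bool(int(sperm_raw))
            else:
                raise ValueError(
                    f"row {i}: sperm_present must be 0, 1 or empty, "
                    f"got {sperm_raw!r}"
                )
            try:
                rec = AnimalRecord(
                    animal_id=row["animal_id"],
                    source=source,
                    age_months=_parse_float("age_months", row["age_months"], i),
                    left_length_cm=_parse_float(
                        "left_length_cm", row["left_length_cm"], i
                    ),
                    right_length_cm=_parse_float(
                        "right_length_cm", row["right_length_cm"], i
                    ),
                    mean_length_cm=_parse_float(
                        "mean_length_cm", row["mean_length_cm"], i
                    ),
                    bcs=(
                        None
                        if (row["bcs"] or "").strip() == ""
                        else _parse_float("bcs", row["bcs"], i)
                    ),
                    sperm_present=sperm,
                )
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from None
            records.append(rec)
    return records


def cohort_summary(records: Sequence[AnimalRecord]) -> dict:
    """Descriptive metadata: n per source, age/BCS/length ranges and medians."""
    import numpy as np

    ages = np.array([r.age_months for r in records], dtype=float)
    lengths = np.array([r.mean_length_cm for r in records], dtype=float)
    bcs = np.array([r.bcs for r in records if r.bcs is not None], dtype=float)
    out = {
        "n": len(records),
        "n_per_source": {
            s.value: sum(1 for r in records if r.source is s) for s in Source
        },
        "age_months": {
            "min": float(ages.min()),
            "max": float(ages.max()),
            "median": float(np.median(ages)),
        },
        "mean_length_cm": {
            "min": float(lengths.min()),
            "max": float(lengths.max()),
            "median": float(np.median(lengths)),
        },
    }
    if bcs.size:
        out["bcs"] = {
            "min": float(bcs.min()),
            "max": float(bcs.max()),
            "median": float(np.median(bcs)),
        }
    n_sperm = [r.sperm_present for r in records if r.sperm_present is not None]
    out["n_with_sperm_outcome"] = len(n_sperm)
    out["n_sperm_positive"] = int(sum(n_sperm))
    return out
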