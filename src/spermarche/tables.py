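"""Length x age contingency tables with sperm-presence percentages.

Cohorts are binned on mean testicular length (<3, 3–3.9, >4 cm) and age
(12–23, 24–35, then 36–48 months for the on-farm scheme or an open-ended
>36 for the excised-organ scheme).  All bins use the half-open [lo, hi)
convention, so a length of exactly 4.0 cm falls in ">4" and 3.95 cm in
"3–3.9" — the published bin labels leave 3.9–4.0 ambiguous and this
package resolves it as [3, 4) versus [4, inf).

Percentages are rounded half-up to whole percent (1/6 -> 17).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .records import AnimalRecord, Source

__all__ = [
    "BinScheme",
    "ContingencyTable",
    "EXPERIMENT1_SCHEME",
    "EXPERIMENT2_SCHEME",
    "assign_bins",
    "cross_tabulate",
    "presence_percent",
]


@dataclass(frozen=True)
class BinScheme:
    """Edges and labels for the length and age grids.

    ``min_age_months`` (when set) rejects animals younger than the grid —
    the on-farm table starts at 12 months.  The last age bin is always
    open-ended on the right.
    """

    length_edges: tuple[float, ...] = (3.0, 4.0)
    length_labels: tuple[str, ...] = ("<3", "3–3.9", ">4")
    age_edges_months: tuple[float, ...] = (24.0, 36.0)
    age_labels: tuple[str, ...] = ("12–23", "24–35", "36–48")
    min_age_months: float | None = 12.0

    def __post_init__(self) -> None:
        for edges, labels in (
            (self.length_edges, self.length_labels),
            (self.age_edges_months, self.age_labels),
        ):
            if list(edges) != sorted(set(edges)):
                raise ValueError(f"edges must be strictly increasing, got {edges}")
            if len(labels) != len(edges) + 1:
                raise ValueError(
                    f"need exactly {len(edges) + 1} labels for edges {edges}, got {labels}"
                )


EXPERIMENT1_SCHEME = BinScheme()
EXPERIMENT2_SCHEME = BinScheme(
    age_labels=("12–23", "24–35", ">36"), min_age_months=None
)


def _bin_label(value: float, edges: tuple[float, ...], labels: tuple[str, ...]) -> str:
    for edge, label in zip(edges, labels):
        if value < edge:
            return label
    return labels[-1]


def assign_bins(
    length_cm: float, age_months: float, scheme: BinScheme = EXPERIMENT1_SCHEME
) -> tuple[str, str]:
    """Map a (length, age) pair to its (length bin, age bin) labels."""
    if length_cm <= 0 or age_months <= 0:
        raise ValueError(
            f"length and age must be positive, got ({length_cm}, {age_months})"
        )
    if scheme.min_age_months is not None and age_months < scheme.min_age_months:
        raise ValueError(
            f"age {age_months} months is below the scheme's grid "
            f"(starts at {scheme.min_age_months})"
        )
    return (
        _bin_label(length_cm, scheme.length_edges, scheme.length_labels),
        _bin_label(age_months, scheme.age_edges_months, scheme.age_labels),
    )


def presence_percent(positives: int, total: int) -> int:
    """Sperm-presence percentage, rounded half-up to a whole percent."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positives <= total:
        raise ValueError(f"need 0 <= positives <= total, got {positives}/{total}")
    pct = (Decimal(100 * positives) / Decimal(total)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP
    )
    return int(pct)


@dataclass(frozen=True)
class ContingencyTable:
    """Binned counts with margins.

    ``cells`` maps ``(length_bin, age_bin)`` — or, when sperm outcomes
    are present, ``(length_bin, age_bin, source)`` — to a count or a
    ``(positives, total)`` pair.  Margins are stored explicitly and are
    consistent with the cells by construction.
    """

    scheme: BinScheme
    has_sperm: bool
    cells: dict
    row_totals: dict[str, int]
    col_totals: dict[str, int]
    grand_total: int

    def render_text(self) -> str:
        """Aligned-text rendering; empty cells print as an en dash."""
        lines = []
        header = ["Mean length (cm)"] + [f"{a} months" for a in self.scheme.age_labels]
        if not self.has_sperm:
            header.append("Total")
        lines.append("\t".join(header))
        for lb in self.scheme.length_labels:
            row = [lb]
            for ab in self.scheme.age_labels:
                if self.has_sperm:
                    parts = []
                    for src in Source:
                        key = (lb, ab, src)
                        if key in self.cells:
                            pos, tot = self.cells[key]
                            parts.append(
                                f"{pos}/{tot} ({presence_percent(pos, tot)}) {src.value}"
                            )
                    row.append("; ".join(parts) if parts else "–")
                else:
                    count = self.cells.get((lb, ab), 0)
                    row.append(str(count) if count else "–")
            if not self.has_sperm:
                row.append(str(self.row_totals[lb]))
            lines.append("\t".join(row))
        if not self.has_sperm:
            lines.append(
                "\t".join(
                    ["Total"]
                    + [str(self.col_totals[a]) for a in self.scheme.age_labels]
                    + [str(self.grand_total)]
                )
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def keyfmt(key):
            return "|".join(k.value if isinstance(k, Source) else str(k) for k in key)

        return {
            "has_sperm": self.has_sperm,
            # tuples become lists so the dict round-trips through JSON
            "cells": {
                keyfmt(k): list(v) if isinstance(v, tuple) else v
                for k, v in self.cells.items()
            },
            "row_totals": dict(self.row_totals),
            "col_totals": dict(self.col_totals),
            "grand_total": self.grand_total,
        }


def cross_tabulate(
    records: Sequence[AnimalRecord], scheme: BinScheme = EXPERIMENT1_SCHEME
) -> ContingencyTable:
    """Bin a cohort and count per cell.

    If any record carries a sperm outcome the table is stratified by
    source and each cell holds ``(positives, total)``; otherwise cells
    are plain counts.  Every record lands in exactly one cell, so margins
    always sum to n.
    """
    if not records:
        raise ValueError("cohort is empty")
    has_sperm = any(r.sperm_present is not None for r in records)
    cells: dict = {}
    row_totals = {lb: 0 for lb in scheme.length_labels}
    col_totals = {ab: 0 for ab in scheme.age_labels}
    for rec in records:
        lb, ab = assign_bins(rec.mean_length_cm, rec.age_months, scheme)
        row_totals[lb] += 1
        col_totals[ab] += 1
        if has_sperm:
            if rec.sperm_present is None:
                raise ValueError(
                    f"record {rec.animal_id!r} lacks a sperm outcome in a "
                    "sperm-presence tabulation"
                )
            pos, tot = cells.get((lb, ab, rec.source), (0, 0))
            cells[(lb, ab, rec.source)] = (pos + int(rec.sperm_present), tot + 1)
        else:
            cells[(lb, ab)] = cells.get((lb, ab), 0) + 1
    return ContingencyTable(
        scheme=scheme,
        has_sperm=has_sperm,
        cells=cells,
        row_totals=row_totals,
        col_totals=col_totals,
        grand_total=len(records),
    )
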