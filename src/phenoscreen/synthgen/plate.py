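"""Plate geometry, well naming and layout assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..catalogue import PANELS

ROW_LETTERS = "ABCDEFGHIJKLMNOP"


class CapacityError(ValueError):
    """More wells requested than the plate can hold."""


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and imaging layout of one plate."""

    rows: int = 16
    cols: int = 24
    exclude_edge: bool = True
    fields_per_well: int = 9
    panel: str = "panelA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols != 384:
            raise ValueError("plate must be 384-well (rows*cols == 384)")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")

    @property
    def usable_wells(self) -> list[tuple[int, int]]:
        """(row, col) pairs available for seeding, 0-based, row-major."""
        if self.exclude_edge:
            return [
                (r, c)
                for r in range(1, self.rows - 1)
                for c in range(1, self.cols - 1)
            ]
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]

    @property
    def n_usable(self) -> int:
        return len(self.usable_wells)


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> "A01"-style well name."""
    return f"{ROW_LETTERS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    return ROW_LETTERS.index(name[0]), int(name[1:]) - 1


@dataclass
class PlateLayout:
    """Condition/compound assignment for every usable well of one plate."""

    spec: PlateSpec
    wells: pd.DataFrame  # plate_id, well, row, col, condition, compound, spiked
    plate_id: str = "P1"

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: PlateSpec | None = None) -> "PlateLayout":
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        df["compound"] = df["compound"].fillna("")
        spec = spec or PlateSpec()
        return cls(spec=spec, wells=df, plate_id=str(df["plate_id"].iloc[0]))


def make_layout(
    spec: PlateSpec,
    conditions: list[tuple[str, int | str]],
    compounds: list[str] | None = None,
    n_spiked_per_compound: int = 0,
    spike_from: str | None = None,
    seed: int | None = None,
    plate_id: str = "P1",
) -> PlateLayout:
    """Assign conditions to every usable well, then spike compound wells.

    ``conditions`` is a list of ``(label, n_wells)`` with ``"fill"`` meaning
    "split the remaining wells as evenly as possible".  Spiked wells are drawn
    uniformly at random, without replacement, from wells of the ``spike_from``
    condition (default: the last condition listed), mimicking a screen where a
    handful of compound wells hide inside an otherwise untreated plate.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    usable = spec.usable_wells
    n_usable = len(usable)

    fixed = [(lbl, n) for lbl, n in conditions if n != "fill"]
    fillers = [lbl for lbl, n in conditions if n == "fill"]
    n_fixed = sum(int(n) for _, n in fixed)
    if n_fixed > n_usable:
        raise CapacityError(f"requested {n_fixed} wells but only {n_usable} usable")
    remaining = n_usable - n_fixed
    counts: dict[str, int] = {lbl: int(n) for lbl, n in fixed}
    if fillers:
        base, extra = divmod(remaining, len(fillers))
        for i, lbl in enumerate(fillers):
            counts[lbl] = counts.get(lbl, 0) + base + (1 if i < extra else 0)
    elif remaining:
        raise CapacityError(f"{remaining} usable wells left unassigned (no 'fill' condition)")

    labels: list[str] = []
    for lbl, _ in conditions:
        labels.extend([lbl] * counts[lbl])
    order = rng.permutation(n_usable)
    assigned = np.empty(n_usable, dtype=object)
    assigned[order] = labels

    rows_ = [r for r, _ in usable]
    cols_ = [c for _, c in usable]
    df = pd.DataFrame(
        {
            "plate_id": plate_id,
            "well": [well_name(r, c) for r, c in usable],
            "row": rows_,
            "col": cols_,
            "condition": assigned,
            "compound": "",
            "spiked": 0,
        }
    )

    compounds = compounds or []
    if compounds and n_spiked_per_compound > 0:
        src = spike_from if spike_from is not None else conditions[-1][0]
        pool = df.index[df["condition"] == src].to_numpy()
        need = n_spiked_per_compound * len(compounds)
        if need > len(pool):
            raise CapacityError(
                f"cannot spike {need} wells from {len(pool)} '{src}' wells"
            )
        picked = rng.choice(pool, size=need, replace=False)
        for i, cmpd in enumerate(compounds):
            idx = picked[i * n_spiked_per_compound : (i + 1) * n_spiked_per_compound]
            df.loc[idx, "compound"] = cmpd
            df.loc[idx, "spiked"] = 1
    return PlateLayout(spec=spec, wells=df, plate_id=plate_id)
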