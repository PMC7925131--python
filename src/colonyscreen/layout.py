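"""Plate layouts for colony co-culture screens.

A plate is a rectangular grid of spotted colonies at a fixed
center-to-center pitch (9 mm for the screens this package emulates).
Each grid position plays one of four roles:

``sample``
    a knockdown strain co-cultured 1:1 with the RFP parent,
``control_1to1``
    a 1:1 parent-GFP : parent-RFP co-culture used to normalize fitness,
``titration``
    a calibration colony grown from a known volumetric GFP fraction
    (the default titration row runs 0, 0.1, ..., 1.0),
``blank``
    an unspotted position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

ROLES = ("sample", "control_1to1", "titration", "blank")

DEFAULT_PITCH_MM = 9.0
DEFAULT_TITRATION_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class Position:
    """One colony position on a plate."""

    row: int
    col: int
    center_x: float  # mm, from the plate's left edge
    center_y: float  # mm, from the plate's top edge
    role: str
    known_fraction: float | None = None  # GFP fraction; titration only

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "titration":
            if self.known_fraction is None or not 0.0 <= self.known_fraction <= 1.0:
                raise ValueError(
                    f"titration position ({self.row},{self.col}) needs a known "
                    f"fraction in [0, 1], got {self.known_fraction!r}"
                )


@dataclass(frozen=True)
class PlateLayout:
    """Geometry and role of every colony position on one plate."""

    n_rows: int
    n_cols: int
    pitch: float  # mm between adjacent colony centers
    positions: tuple[Position, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for p in self.positions:
            if not (0 <= p.row < self.n_rows and 0 <= p.col < self.n_cols):
                raise ValueError(f"position ({p.row},{p.col}) outside the grid")
            if (p.row, p.col) in seen:
                raise ValueError(f"duplicate assignment of position ({p.row},{p.col})")
            seen.add((p.row, p.col))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def titration_positions(self) -> tuple[Position, ...]:
        return tuple(p for p in self.positions if p.role == "titration")

    @property
    def control_positions(self) -> tuple[Position, ...]:
        return tuple(p for p in self.positions if p.role == "control_1to1")

    @property
    def sample_positions(self) -> tuple[Position, ...]:
        return tuple(p for p in self.positions if p.role == "sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": [p.row for p in self.positions],
                "col": [p.col for p in self.positions],
                "center_x_mm": [p.center_x for p in self.positions],
                "center_y_mm": [p.center_y for p in self.positions],
                "role": [p.role for p in self.positions],
                "known_fraction": [p.known_fraction for p in self.positions],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pitch: float) -> "PlateLayout":
        positions = tuple(
            Position(
                int(r.row),
                int(r.col),
                float(r.center_x_mm),
                float(r.center_y_mm),
                str(r.role),
                None if pd.isna(r.known_fraction) else float(r.known_fraction),
            )
            for r in df.itertuples(index=False)
        )
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        return cls(n_rows=n_rows, n_cols=n_cols, pitch=pitch, positions=positions)

    @classmethod
    def from_csv(cls, path, pitch: float = DEFAULT_PITCH_MM) -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path), pitch=pitch)


def make_plate_layout(
    n_rows: int = 8,
    n_cols: int = 12,
    pitch: float = DEFAULT_PITCH_MM,
    titration_spec: Sequence[float] | None = DEFAULT_TITRATION_FRACTIONS,
    control_positions: Iterable[tuple[int, int]] | None = None,
    blank_positions: Iterable[tuple[int, int]] | None = None,
) -> PlateLayout:
    """Build a plate layout with a titration row, controls and samples.

    Titration colonies fill the top row from column 0 (left to right, in
    the order given; the default covers 0 to 1 in 0.1 steps).  Control
    co-cultures default to the remaining first-row positions.  Every
    unassigned position becomes a sample.  Colony centers sit at
    ``pitch/2 + index*pitch`` from the plate edge so the pitch-sized grid
    cells tile the plate exactly.

    Raises
    ------
    ValueError
        if the grid cannot hold all requested roles, a position is
        assigned twice, or a titration fraction falls outside [0, 1].
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must have at least one row and one column")
    if pitch <= 0:
        raise ValueError("pitch must be positive")

    titration = list(titration_spec) if titration_spec else []
    for f in titration:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"titration fraction {f} outside [0, 1]")
    if len(titration) > n_cols:
        raise ValueError(
            f"titration row needs {len(titration)} columns but the plate has {n_cols}"
        )

    def center(row: int, col: int) -> tuple[float, float]:
        return (pitch / 2 + col * pitch, pitch / 2 + row * pitch)

    assigned: dict[tuple[int, int], Position] = {}

    for i, frac in enumerate(titration):
        cx, cy = center(0, i)
        assigned[(0, i)] = Position(0, i, cx, cy, "titration", float(frac))

    if control_positions is None:
        if titration:
            control_positions = [
                (0, c) for c in range(len(titration), n_cols)
            ]
        else:
            control_positions = []
    for row, col in control_positions:
        if (row, col) in assigned:
            raise ValueError(f"duplicate assignment of position ({row},{col})")
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(f"control position ({row},{col}) outside the grid")
        cx, cy = center(row, col)
        assigned[(row, col)] = Position(row, col, cx, cy, "control_1to1")

    for row, col in blank_positions or []:
        if (row, col) in assigned:
            raise ValueError(f"duplicate assignment of position ({row},{col})")
        cx, cy = center(row, col)
        assigned[(row, col)] = Position(row, col, cx, cy, "blank")

    n_assigned = len(assigned)
    if n_assigned > n_rows * n_cols:
        raise ValueError(
            f"{n_assigned} roles requested but the plate holds {n_rows * n_cols}"
        )

    positions = []
    for row in range(n_rows):
        for col in range(n_cols):
            if (row, col) in assigned:
                positions.append(assigned[(row, col)])
            else:
                cx, cy = center(row, col)
                positions.append(Position(row, col, cx, cy, "sample"))

    return PlateLayout(
        n_rows=n_rows, n_cols=n_cols, pitch=pitch, positions=tuple(positions)
    )
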