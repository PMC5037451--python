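"""96-well plate layout: well addressing, control wells, excluded edges.

The experimental plate reserves the edge rows/columns (A, H, 1, 12) as
unused to avoid edge effects, and designates eight interior wells as
unstretched controls (the injury device omits the posts under them).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

ROWS = tuple("ABCDEFGH")
COLUMNS = tuple(range(1, 13))

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")

DEFAULT_CONTROL_WELLS = frozenset(
    {"C4", "D4", "E4", "F4", "C9", "D9", "E9", "F9"}
)


@dataclass(frozen=True, order=True)
class Well:
    """A well position on the 8x12 grid, e.g. ``Well('B', 2)``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"invalid row {self.row!r}")
        if self.column not in COLUMNS:
            raise ValueError(f"invalid column {self.column}")

    @classmethod
    def parse(cls, name: str | "Well") -> "Well":
        if isinstance(name, Well):
            return name
        m = _WELL_RE.match(str(name).strip())
        if not m:
            raise ValueError(f"cannot parse well name {name!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    @property
    def name(self) -> str:
        return f"{self.row}{self.column}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _parse_set(wells: Iterable[str | Well]) -> frozenset[Well]:
    return frozenset(Well.parse(w) for w in wells)


@dataclass(frozen=True)
class PlateLayout:
    """Which wells of a 96-well plate are used, controls, or excluded.

    Defaults match the study design: edge rows A and H and edge columns 1
    and 12 excluded, controls at C4, D4, E4, F4, C9, D9, E9, F9 (wells
    whose posts are removed so they see zero strain).
    """

    control_wells: frozenset[Well] = field(default_factory=lambda: _parse_set(DEFAULT_CONTROL_WELLS))
    excluded_wells: frozenset[Well] = field(
        default_factory=lambda: frozenset(
            Well(r, c)
            for r in ROWS
            for c in COLUMNS
            if r in ("A", "H") or c in (1, 12)
        )
    )

    def __post_init__(self) -> None:
        if self.control_wells & self.excluded_wells:
            raise ValueError("control_wells and excluded_wells must be disjoint")

    @classmethod
    def default(cls) -> "PlateLayout":
        return cls()

    @classmethod
    def from_names(
        cls,
        control_wells: Iterable[str | Well],
        excluded_wells: Iterable[str | Well],
    ) -> "PlateLayout":
        return cls(_parse_set(control_wells), _parse_set(excluded_wells))

    @property
    def all_wells(self) -> tuple[Well, ...]:
        return tuple(Well(r, c) for r in ROWS for c in COLUMNS)

    @property
    def active_wells(self) -> tuple[Well, ...]:
        """Wells used in the experiment (controls included), row-major order."""
        return tuple(w for w in self.all_wells if w not in self.excluded_wells)

    @property
    def injured_wells(self) -> tuple[Well, ...]:
        """Active wells that actually receive the stretch insult."""
        return tuple(
            w for w in self.active_wells if w not in self.control_wells
        )

    def is_control(self, well: str | Well) -> bool:
        return Well.parse(well) in self.control_wells

    def is_excluded(self, well: str | Well) -> bool:
        return Well.parse(well) in self.excluded_wells
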