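"""384-well plate geometry and sample-name conventions.

A compartmentalised sequencing run distributes template DNA over a
16 x 24 well plate; every well becomes one sample column in the joint
VCF.  The layout maps sample names to (row, column) coordinates so that
row/column clustering statistics can be computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PlateLayout:
    """Mapping between well indices, plate coordinates and sample names.

    The default is a 16-row x 24-column plate with samples named
    ``S001`` .. ``S384`` in row-major order (well_index = row * 24 + col).
    """

    n_rows: int = 16
    n_cols: int = 24
    sample_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sample_names:
            names = tuple(f"S{i + 1:03d}" for i in range(self.n_wells))
            object.__setattr__(self, "sample_names", names)
        if len(self.sample_names) != self.n_wells:
            raise ValueError(
                f"expected {self.n_wells} sample names, got {len(self.sample_names)}"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} plate")
        return row * self.n_cols + col

    def row_col(self, well_index: int) -> tuple[int, int]:
        if not 0 <= well_index < self.n_wells:
            raise ValueError(f"well index {well_index} outside plate")
        return divmod(well_index, self.n_cols)

    def sample_to_well(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in plate layout") from None


DEFAULT_LAYOUT = PlateLayout()
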