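"""Core domain types shared across the package.

A *pressure sample* is one standardized plantar pressure map: a 64x64
grid of non-negative intensities normalized to [0, 1], together with the
metadata needed for quality control — which subject and foot it belongs
to, how it was acquired, its QC label, and (for derived samples) which
samples it was derived from.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

GRID_SIZE = 64

#: QC label taxonomy. 0 is a valid (inlier) map; 1-4 are outlier classes.
LABEL_VALID = 0
LABEL_GENERAL_ERROR = 1        # cropped / incomplete acquisition
LABEL_DOUBLE_FOOT = 2          # both feet captured in one frame
LABEL_INVERTED = 3             # map stored upside-down
LABEL_SIDE_SWAP = 4            # left/right annotation swapped
ALL_LABELS = (LABEL_VALID, LABEL_GENERAL_ERROR, LABEL_DOUBLE_FOOT,
              LABEL_INVERTED, LABEL_SIDE_SWAP)

LABEL_NAMES = {
    LABEL_VALID: "valid",
    LABEL_GENERAL_ERROR: "general_acquisition_error",
    LABEL_DOUBLE_FOOT: "double_foot",
    LABEL_INVERTED: "inverted_orientation",
    LABEL_SIDE_SWAP: "incorrect_side_annotation",
}


class Side(str, enum.Enum):
    LEFT = "L"
    RIGHT = "R"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Condition(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"


class Provenance(str, enum.Enum):
    REAL = "real"
    SYNTHETIC = "synthetic"


@dataclass
class PressureSample:
    """One standardized plantar pressure map plus its QC metadata.

    Grid convention: row 0 is distal (toes), row 63 proximal (heel);
    columns increase left-to-right in the image plane.
    """

    sample_id: str
    grid: np.ndarray
    subject_id: str
    side: Side
    condition: Condition = Condition.STATIC
    label: int = LABEL_VALID
    provenance: Provenance = Provenance.REAL
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.side = Side(self.side)
        self.condition = Condition(self.condition)
        self.provenance = Provenance(self.provenance)
        self.validate()

    def validate(self) -> None:
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(
                f"sample {self.sample_id}: grid shape {self.grid.shape}, "
                f"expected ({GRID_SIZE}, {GRID_SIZE})")
        if self.grid.min() < 0 or self.grid.max() > 1 + 1e-6:
            raise ValueError(f"sample {self.sample_id}: intensities outside [0, 1]")
        if self.label not in ALL_LABELS:
            raise ValueError(f"sample {self.sample_id}: unknown label {self.label}")
        if self.provenance is Provenance.SYNTHETIC and not self.source_ids:
            raise ValueError(
                f"sample {self.sample_id}: synthetic sample without source_ids")

    @property
    def is_outlier(self) -> bool:
        return self.label != LABEL_VALID

    def replace(self, **kwargs) -> "PressureSample":
        """Return a copy with selected fields replaced (grid is copied)."""
        data = dict(
            sample_id=self.sample_id,
            grid=self.grid.copy(),
            subject_id=self.subject_id,
            side=self.side,
            condition=self.condition,
            label=self.label,
            provenance=self.provenance,
            source_ids=list(self.source_ids),
        )
        data.update(kwargs)
        return PressureSample(**data)
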