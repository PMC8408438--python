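"""2D hand space and phase-encoded stimulation designs.

The hand is modelled as a 2D Cartesian stimulus space: the x-axis is the
between-digit dimension (thumb D1 ... little finger D5, then the palm) and
the y-axis is the within-digit dimension (distal phalanx P1, proximal
phalanx P2, palm).  The space spans +/-12 arbitrary hand-space units on
both axes and is divided into equal-width segments that correspond to the
stimulated locations.

Phase-encoded stimulation steps through the locations of one dimension in
order (forward) or in reverse (backward), holding each location for a fixed
number of seconds, for several cycles per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HandSpace",
    "StimulusDesign",
    "build_hand_space",
    "build_design",
    "design_to_regressor_stack",
    "design_to_json",
    "design_from_json",
    "DIGIT_LABELS",
    "PHALANX_LABELS",
]

#: Canonical left-to-right labels for the between-digit axis (6 segments).
DIGIT_LABELS = ("D1", "D2", "D3", "D4", "D5", "Palm")

#: Canonical bottom-to-top labels for the within-digit axis (3 segments).
PHALANX_LABELS = ("P1", "P2", "Palm")

BETWEEN_DIGIT = "between_digit"
WITHIN_DIGIT = "within_digit"
FORWARD = "forward"
BACKWARD = "backward"


def _segment_labels(n: int, canonical: Sequence[str]) -> tuple[str, ...]:
    if n == len(canonical):
        return tuple(canonical)
    return tuple(f"S{i + 1}" for i in range(n))


@dataclass(frozen=True)
class HandSpace:
    """The 2D hand space with digit/phalanx segmentation.

    Orientation convention: D1 sits at ``x_min`` and the palm at ``x_max``;
    P1 (distal) at ``y_min`` and the palm at ``y_max``.  Segments are
    half-open intervals of equal width; the right edge of the space belongs
    to the last segment so that every coordinate in range has exactly one
    label.
    """

    x_min: float = -12.0
    x_max: float = 12.0
    y_min: float = -12.0
    y_max: float = 12.0
    n_digit_segments: int = 6
    n_phalanx_segments: int = 3
    grid_resolution: int = 41

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("degenerate hand-space range")
        if self.n_digit_segments < 1 or self.n_phalanx_segments < 1:
            raise ValueError("segment counts must be >= 1")
        if self.grid_resolution < 3:
            raise ValueError("grid_resolution must be >= 3")

    # -- segment geometry ---------------------------------------------------

    @property
    def digit_labels(self) -> tuple[str, ...]:
        return _segment_labels(self.n_digit_segments, DIGIT_LABELS)

    @property
    def phalanx_labels(self) -> tuple[str, ...]:
        return _segment_labels(self.n_phalanx_segments, PHALANX_LABELS)

    @property
    def digit_width(self) -> float:
        return (self.x_max - self.x_min) / self.n_digit_segments

    @property
    def phalanx_width(self) -> float:
        return (self.y_max - self.y_min) / self.n_phalanx_segments

    def digit_edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_digit_segments + 1)

    def phalanx_edges(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.n_phalanx_segments + 1)

    def segment_index_of(self, x: float | np.ndarray) -> np.ndarray | int:
        """Index of the digit segment containing x (right edge -> last)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x_min) or np.any(x > self.x_max):
            raise ValueError("x outside hand space")
        idx = np.floor((x - self.x_min) / self.digit_width).astype(int)
        idx = np.clip(idx, 0, self.n_digit_segments - 1)
        return idx if idx.ndim else int(idx)

    def phalanx_index_of(self, y: float | np.ndarray) -> np.ndarray | int:
        y = np.asarray(y, dtype=float)
        if np.any(y < self.y_min) or np.any(y > self.y_max):
            raise ValueError("y outside hand space")
        idx = np.floor((y - self.y_min) / self.phalanx_width).astype(int)
        idx = np.clip(idx, 0, self.n_phalanx_segments - 1)
        return idx if idx.ndim else int(idx)

    def segment_of(self, x: float) -> str:
        return self.digit_labels[self.segment_index_of(x)]

    def phalanx_of(self, y: float) -> str:
        return self.phalanx_labels[self.phalanx_index_of(y)]

    def segment_center(self, index: int) -> float:
        edges = self.digit_edges()
        return 0.5 * (edges[index] + edges[index + 1])

    def phalanx_center(self, index: int) -> float:
        edges = self.phalanx_edges()
        return 0.5 * (edges[index] + edges[index + 1])

    # -- evaluation grid ----------------------------------------------------

    @cached_property
    def xs(self) -> np.ndarray:
        """Grid sample positions along x (endpoint-inclusive)."""
        return np.linspace(self.x_min, self.x_max, self.grid_resolution)

    @cached_property
    def ys(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.grid_resolution)

    @cached_property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrid arrays of shape (res, res), indexed [iy, ix]."""
        return np.meshgrid(self.xs, self.ys)

    def location_masks(self, dimension: str) -> np.ndarray:
        """Boolean masks (n_locations, res, res), one per stimulated location.

        Between-digit locations are vertical bands (one digit segment, full
        y-extent); within-digit locations are horizontal bands (one phalanx
        row across all digits), because the paradigm stimulates two
        phalanges of one digit together, or one phalanx row of all five
        digits together.
        """
        X, Y = self.grid
        if dimension == BETWEEN_DIGIT:
            seg = self.segment_index_of(X)
            n = self.n_digit_segments
        elif dimension == WITHIN_DIGIT:
            seg = self.phalanx_index_of(Y)
            n = self.n_phalanx_segments
        else:
            raise ValueError(f"unknown dimension {dimension!r}")
        return np.stack([seg == k for k in range(n)])

    def to_dict(self) -> dict:
        return {
            "x_range": [self.x_min, self.x_max],
            "y_range": [self.y_min, self.y_max],
            "n_digit_segments": self.n_digit_segments,
            "n_phalanx_segments": self.n_phalanx_segments,
            "grid_resolution": self.grid_resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HandSpace":
        return cls(
            x_min=d["x_range"][0],
            x_max=d["x_range"][1],
            y_min=d["y_range"][0],
            y_max=d["y_range"][1],
            n_digit_segments=d["n_digit_segments"],
            n_phalanx_segments=d["n_phalanx_segments"],
            grid_resolution=d["grid_resolution"],
        )


def build_hand_space(
    x_range: tuple[float, float] = (-12.0, 12.0),
    y_range: tuple[float, float] = (-12.0, 12.0),
    n_digit_segments: int = 6,
    n_phalanx_segments: int = 3,
    grid_resolution: int = 41,
) -> HandSpace:
    """Construct a :class:`HandSpace` with equally spaced segment boundaries."""
    return HandSpace(
        x_min=float(x_range[0]),
        x_max=float(x_range[1]),
        y_min=float(y_range[0]),
        y_max=float(y_range[1]),
        n_digit_segments=int(n_digit_segments),
        n_phalanx_segments=int(n_phalanx_segments),
        grid_resolution=int(grid_resolution),
    )


@dataclass(frozen=True, eq=False)
class StimulusDesign:
    """One phase-encoded run: a periodic sequence of location apertures.

    ``location_sequence[t]`` is the index of the single active location at
    time-bin t (TR resolution).  The aperture of a location is the binary
    mask of grid points inside that location's band of the hand space.
    """

    space: HandSpace
    dimension: str
    direction: str
    tr: float = 2.0
    seconds_per_location: float = 8.0
    n_cycles: int = 8
    location_sequence: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.dimension not in (BETWEEN_DIGIT, WITHIN_DIGIT):
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.direction not in (FORWARD, BACKWARD):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, StimulusDesign):
            return NotImplemented
        return (self.space == other.space
                and self.dimension == other.dimension
                and self.direction == other.direction
                and self.tr == other.tr
                and self.seconds_per_location == other.seconds_per_location
                and self.n_cycles == other.n_cycles
                and np.array_equal(self.location_sequence, other.location_sequence))

    @property
    def n_locations(self) -> int:
        if self.dimension == BETWEEN_DIGIT:
            return self.space.n_digit_segments
        return self.space.n_phalanx_segments

    @property
    def labels(self) -> tuple[str, ...]:
        """Location labels in forward stimulation order."""
        if self.dimension == BETWEEN_DIGIT:
            return self.space.digit_labels
        return self.space.phalanx_labels

    @property
    def bins_per_location(self) -> int:
        return int(round(self.seconds_per_location / self.tr))

    @property
    def cycle_bins(self) -> int:
        return self.n_locations * self.bins_per_location

    @property
    def cycle_seconds(self) -> float:
        return self.cycle_bins * self.tr

    @property
    def n_timebins(self) -> int:
        return self.n_cycles * self.cycle_bins

    @cached_property
    def masks(self) -> np.ndarray:
        """(n_locations, res, res) boolean aperture per location."""
        return self.space.location_masks(self.dimension)

    @cached_property
    def apertures(self) -> np.ndarray:
        """(n_timebins, res, res) boolean aperture per time-bin."""
        return self.masks[self.location_sequence]

    def reversed(self) -> "StimulusDesign":
        """The per-cycle time-reversal of this design (forward <-> backward)."""
        seq = self.location_sequence.reshape(self.n_cycles, self.cycle_bins)
        seq = seq[:, ::-1].reshape(-1).copy()
        other = BACKWARD if self.direction == FORWARD else FORWARD
        return replace(self, direction=other, location_sequence=seq)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "direction": self.direction,
            "tr": self.tr,
            "seconds_per_location": self.seconds_per_location,
            "n_cycles": self.n_cycles,
            "space": self.space.to_dict(),
        }


def build_design(
    space: HandSpace,
    dimension: str = BETWEEN_DIGIT,
    direction: str = FORWARD,
    tr: float = 2.0,
    seconds_per_location: float = 8.0,
    n_cycles: int = 8,
) -> StimulusDesign:
    """Build one phase-encoded run over the given hand space.

    Forward order steps D1 -> D2 -> ... -> Palm (or P1 -> P2 -> Palm);
    backward order is the reverse.  Each location is held for
    ``seconds_per_location`` seconds, which must be a multiple of the TR.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    bins = seconds_per_location / tr
    if abs(bins - round(bins)) > 1e-9 or round(bins) < 1:
        raise ValueError("seconds_per_location must be a positive multiple of tr")
    bins = int(round(bins))
    if dimension == BETWEEN_DIGIT:
        n_loc = space.n_digit_segments
    elif dimension == WITHIN_DIGIT:
        n_loc = space.n_phalanx_segments
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    order = np.arange(n_loc)
    if direction == BACKWARD:
        order = order[::-1]
    cycle = np.repeat(order, bins)
    seq = np.tile(cycle, n_cycles)
    return StimulusDesign(
        space=space,
        dimension=dimension,
        direction=direction,
        tr=float(tr),
        seconds_per_location=float(seconds_per_location),
        n_cycles=int(n_cycles),
        location_sequence=seq,
    )


def design_to_regressor_stack(design: StimulusDesign, space: HandSpace) -> np.ndarray:
    """Flattened binary aperture matrix, one row per time-bin.

    Row t is the active aperture at time-bin t flattened row-major over the
    (y, x) grid; its row sum equals the active location's grid-point count.
    """
    if design.space != space:
        raise ValueError("design was built on a different hand space")
    ap = design.apertures
    stack = ap.reshape(ap.shape[0], -1).astype(float)
    if np.any(stack.sum(axis=1) == 0):
        raise ValueError("empty aperture in design")
    return stack


def design_to_json(design: StimulusDesign, path: str | Path | None = None) -> str:
    """Serialize the design spec (not the aperture tensor) to JSON."""
    text = json.dumps(design.to_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def design_from_json(source: str | Path) -> StimulusDesign:
    """Rebuild a design from a JSON spec string or file path."""
    s = str(source)
    if s.lstrip().startswith("{"):
        d = json.loads(s)
    else:
        d = json.loads(Path(source).read_text())
    space = HandSpace.from_dict(d["space"])
    return build_design(
        space,
        dimension=d["dimension"],
        direction=d["direction"],
        tr=d["tr"],
        seconds_per_location=d["seconds_per_location"],
        n_cycles=d["n_cycles"],
    )
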