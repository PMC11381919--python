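"""Electrode-array geometry.

A multiwell MEA plate carries a small regular grid of extracellular
electrodes per well (16 electrodes at ~300 µm pitch is the classic
cardiac configuration). Positions are expressed in µm with the origin at
the first electrode; electrodes are ordered row-major, matching how
per-electrode tables and spatial maps are exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ElectrodeLayout", "make_layout"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Regular rows x cols electrode grid.

    Attributes
    ----------
    rows, cols : int
        Grid dimensions.
    pitch : float
        Interelectrode distance in µm.
    coordinates : np.ndarray, shape (rows*cols, 2)
        (x, y) positions in µm, row-major (x varies fastest).
    electrode_ids : tuple of str
        Unique labels, ordered like ``coordinates``.
    """

    rows: int
    cols: int
    pitch: float
    coordinates: np.ndarray = field(repr=False)
    electrode_ids: tuple[str, ...]

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    @property
    def max_pairwise_distance(self) -> float:
        """Largest electrode-to-electrode distance (µm): the grid diagonal."""
        return float(self.pitch * np.hypot(self.rows - 1, self.cols - 1))

    def coordinates_mm(self) -> np.ndarray:
        return self.coordinates / 1000.0

    def to_dict(self) -> dict:
        return {"rows": self.rows, "cols": self.cols, "pitch_um": self.pitch}


def make_layout(rows: int, cols: int, pitch: float = 300.0) -> ElectrodeLayout:
    """Build a regular electrode grid.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions, each >= 1.
    pitch : float
        Interelectrode spacing in µm (> 0). Default 300 µm.
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError(f"grid dimensions must be >= 1, got {rows}x{cols}")
    if pitch <= 0:
        raise InvalidArgumentError(f"pitch must be > 0, got {pitch}")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel() * pitch, rr.ravel() * pitch]).astype(float)
    ids = tuple(f"E{i:02d}" for i in range(rows * cols))
    coords.setflags(write=False)
    return ElectrodeLayout(rows=rows, cols=cols, pitch=float(pitch),
                           coordinates=coords, electrode_ids=ids)
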