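"""Discrete containers: traction grids, displacement fields, traction fields.

Unit convention: every container carries a ``length_unit`` tag, either
``"um"`` (micrometers) or ``"pix"`` (camera pixels).  Conversion between the
two requires an explicit ``pixel_size`` (um per pixel).  Containers and
operators refuse algebra across mismatched units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LENGTH_UNITS = ("um", "pix")


def _check_unit(unit: str) -> str:
    if unit not in LENGTH_UNITS:
        raise ValueError(f"length_unit must be one of {LENGTH_UNITS}, got {unit!r}")
    return unit


class UnitMismatchError(ValueError):
    """Raised when objects with different length units are combined."""


@dataclass(frozen=True)
class TractionGrid:
    """Regular grid of traction nodes.

    Nodes are ordered row-major with x fastest: node k = iy * nx + ix is at
    ``origin + (ix, iy) * mesh_constant``.  The traction vector layout is
    ``f[2k] = f_x``, ``f[2k+1] = f_y``.
    """

    shape: tuple[int, int]  # (nx, ny)
    mesh_constant: float
    origin: tuple[float, float] = (0.0, 0.0)
    length_unit: str = "um"

    def __post_init__(self) -> None:
        nx, ny = self.shape
        if nx < 2 or ny < 2:
            raise ValueError("grid must have at least 2 nodes per axis")
        if not self.mesh_constant > 0:
            raise ValueError("mesh_constant must be > 0")
        _check_unit(self.length_unit)

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def node_positions(self) -> np.ndarray:
        """(n, 2) array of node coordinates."""
        nx, ny = self.shape
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))  # iy slow, ix fast
        pos = np.column_stack(
            [
                self.origin[0] + ix.ravel() * self.mesh_constant,
                self.origin[1] + iy.ravel() * self.mesh_constant,
            ]
        )
        return pos

    @property
    def extent(self) -> tuple[float, float]:
        """Spanned extent (max - min coordinate) per axis."""
        nx, ny = self.shape
        return ((nx - 1) * self.mesh_constant, (ny - 1) * self.mesh_constant)

    def in_units(self, unit: str, pixel_size: float | None = None) -> "TractionGrid":
        s = _unit_scale(self.length_unit, unit, pixel_size)
        if s == 1.0:
            return self
        return TractionGrid(
            shape=self.shape,
            mesh_constant=self.mesh_constant * s,
            origin=(self.origin[0] * s, self.origin[1] * s),
            length_unit=unit,
        )


def _unit_scale(src: str, dst: str, pixel_size: float | None) -> float:
    _check_unit(src)
    _check_unit(dst)
    if src == dst:
        return 1.0
    if pixel_size is None or not pixel_size > 0:
        raise ValueError("pixel_size (um per pixel, > 0) is required for unit conversion")
    return pixel_size if (src, dst) == ("pix", "um") else 1.0 / pixel_size


@dataclass
class DisplacementField:
    """m sampled displacement vectors.

    ``positions`` is (m, 2); ``vectors`` is the stacked 2m component vector
    with layout ``u[2k] = u_x``, ``u[2k+1] = u_y`` at sample k.
    """

    positions: np.ndarray
    vectors: np.ndarray
    length_unit: str = "um"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float).ravel()
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (m, 2)")
        if self.vectors.size != 2 * self.positions.shape[0]:
            raise ValueError("vectors length must equal 2 * number of samples")
        if not np.all(np.isfinite(self.positions)) or not np.all(np.isfinite(self.vectors)):
            raise ValueError("positions and vectors must be finite")
        _check_unit(self.length_unit)

    @property
    def m_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def vector_matrix(self) -> np.ndarray:
        """(m, 2) view of the displacement components."""
        return self.vectors.reshape(-1, 2)

    def in_units(self, unit: str, pixel_size: float | None = None) -> "DisplacementField":
        s = _unit_scale(self.length_unit, unit, pixel_size)
        if s == 1.0:
            return self
        return DisplacementField(
            positions=self.positions * s,
            vectors=self.vectors * s,
            length_unit=unit,
            meta=dict(self.meta),
        )


@dataclass
class TractionField:
    """Traction vectors (Pa) on the nodes of a TractionGrid."""

    grid: TractionGrid
    vectors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float).ravel()
        if self.vectors.size != 2 * self.grid.n_nodes:
            raise ValueError("vectors length must equal 2 * n_nodes")

    @property
    def vector_matrix(self) -> np.ndarray:
        return self.vectors.reshape(-1, 2)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vector_matrix, axis=1)
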