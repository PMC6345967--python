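"""Tabular text formats for displacement and traction fields.

Displacements: 4 numeric columns (x, y, ux, uy), whitespace- or
comma-delimited, with '#' comment lines.  A header comment of the form
``# key = value`` carries units and provenance and round-trips through
read/write.  Tractions: same layout with (x, y, tx, ty) and traction in Pa.
"""

from __future__ import annotations

import numpy as np

from .grids import DisplacementField, TractionGrid
from .grids import TractionField

__all__ = ["read_displacements", "write_displacements", "write_traction",
           "read_traction"]

_FLOAT_FMT = "%.12g"


def _parse_table(path: str):
    meta: dict = {}
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            # sniff the dialect per line: commas win if present
            parts = [p for p in (line.split(",") if "," in line else line.split())
                     if p != ""]
            if n_cols is None:
                n_cols = len(parts)
            if len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"({len(parts)} fields, expected {n_cols})")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if not all(np.isfinite(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty input (no data rows)")
    return np.asarray(rows, dtype=float), meta


def read_displacements(path: str, length_unit: str | None = None) -> DisplacementField:
    """Read a 4-column (x, y, ux, uy) displacement table.

    The length unit comes from a ``# length_unit = ...`` header comment
    unless overridden by the ``length_unit`` argument; default "um".
    """
    data, meta = _parse_table(path)
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (x, y, ux, uy), "
                         f"got {data.shape[1]}")
    unit = length_unit or meta.get("length_unit", "um")
    return DisplacementField(positions=data[:, :2], vectors=data[:, 2:].ravel(),
                             length_unit=unit, meta=meta)


def _write_table(path: str, header: dict, columns: np.ndarray, names: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {names}\n")
        for k, v in header.items():
            fh.write(f"# {k} = {v}\n")
        np.savetxt(fh, columns, fmt=_FLOAT_FMT)


def write_displacements(field: DisplacementField, path: str) -> None:
    header = {"length_unit": field.length_unit}
    for k, v in field.meta.items():
        header.setdefault(str(k), v)
    table = np.column_stack([field.positions, field.vector_matrix])
    _write_table(path, header, table, "x y ux uy")


def write_traction(field: TractionField, path: str, **provenance) -> None:
    """Write (x, y, tx, ty) in Pa with a provenance header.

    Keyword arguments (method, lambda values, alpha/beta, seeds, ...) are
    recorded as header comments together with the field's own metadata.
    """
    header = {"length_unit": field.grid.length_unit, "traction_unit": "Pa"}
    for k, v in {**field.meta, **provenance}.items():
        header[str(k)] = v
    table = np.column_stack([field.grid.node_positions, field.vector_matrix])
    _write_table(path, header, table, "x y tx ty")


def read_traction(path: str, mesh_constant: float | None = None) -> TractionField:
    """Read a traction table written by :func:`write_traction`."""
    data, meta = _parse_table(path)
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (x, y, tx, ty)")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    mesh = mesh_constant or float(meta.get("mesh_constant", xs[1] - xs[0]))
    grid = TractionGrid(shape=(xs.size, ys.size), mesh_constant=mesh,
                        origin=(float(xs.min()), float(ys.min())),
                        length_unit=meta.get("length_unit", "um"))
    order = np.lexsort((data[:, 0], data[:, 1]))  # y slow, x fast
    return TractionField(grid=grid, vectors=data[order, 2:].ravel(), meta=meta)
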