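"""Gridded height maps of enamel wear facets: reading, validation, leveling.

A facet scan is represented as a :class:`HeightMap`: surface heights in µm
on a regular x/y lattice with a per-point validity mask.  Non-measured
points are excluded from every statistic rather than interpolated, so that
no texture is fabricated.

Supported plain-text dialects
-----------------------------
ascii-grid
    Header lines ``ncols N``, ``nrows M``, ``spacing_um DX DY`` followed by
    M whitespace-separated rows; ``NA`` marks a non-measured point.
csv-matrix
    Optional first line ``# spacing_um=DX,DY`` (spacing defaults to 1 µm),
    then a comma-separated numeric matrix; ``NA`` allowed.
xyz-points
    Three whitespace-separated columns ``x y z`` in µm, one point per line,
    ``#`` comments; points must lie on a regular lattice and missing lattice
    cells become masked points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DegeneracyError, FormatError, ValidationError

__all__ = [
    "HeightMap",
    "PARAM_ORDER",
    "PARAM_UNITS",
    "read_height_map",
    "write_height_map",
    "level_surface",
    "write_parameter_table",
    "read_parameter_table",
]

#: Fixed column order of the 30 areal texture parameters in written tables.
PARAM_ORDER: Tuple[str, ...] = (
    "S10z", "S5p", "S5v", "Sa", "Sal", "Sda", "Sdq", "Sdr", "Sdv", "Sha",
    "Shv", "Sku", "Smc", "Smr", "Sp", "Spc", "Spd", "Sq", "Ssk", "Std",
    "Str", "Sv", "Sxp", "Sz", "Vm", "Vmc", "Vmp", "Vv", "Vvc", "Vvv",
)

PARAM_UNITS = {
    "Sa": "µm", "Sq": "µm", "Sp": "µm", "Sv": "µm", "Sz": "µm",
    "Smc": "µm", "Sxp": "µm", "S10z": "µm", "S5p": "µm", "S5v": "µm",
    "Ssk": "-", "Sku": "-", "Str": "-", "Sdq": "-",
    "Sdr": "%", "Smr": "%", "Sal": "µm", "Std": "°",
    "Vm": "µm³/µm²", "Vmc": "µm³/µm²", "Vmp": "µm³/µm²",
    "Vv": "µm³/µm²", "Vvc": "µm³/µm²", "Vvv": "µm³/µm²",
    "Spd": "1/µm²", "Spc": "1/µm", "Sda": "µm²", "Sha": "µm²",
    "Sdv": "µm³", "Shv": "µm³",
}


@dataclass
class HeightMap:
    """A regular grid of surface heights in µm with a validity mask.

    The grid origin is the top-left sample; x increases with column index,
    y with row index.  Heights at masked-out cells are stored as NaN and
    never enter any computation.

    Parameters
    ----------
    heights
        2D array of heights in µm (rows × columns).
    spacing_x, spacing_y
        Lateral sample spacing in µm; strictly positive.
    mask
        Boolean validity flag per point (True = measured).  Defaults to
        all-valid.
    specimen_id, group_label
        Opaque specimen label and habitat name (may be empty).
    """

    heights: np.ndarray
    spacing_x: float
    spacing_y: float
    mask: np.ndarray = None  # type: ignore[assignment]
    specimen_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValidationError("heights must be a 2D array")
        if self.heights.shape[0] < 2 or self.heights.shape[1] < 2:
            raise ValidationError("height map must be at least 2×2")
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValidationError(
                f"spacing must be strictly positive, got "
                f"({self.spacing_x}, {self.spacing_y})"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.heights)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.heights.shape:
                raise ValidationError("mask shape must match heights shape")
            self.mask = self.mask & np.isfinite(self.heights)
        if self.mask.sum() < 4:
            raise ValidationError("height map needs at least 2×2 valid points")
        # NaN out invalid cells so stray arithmetic cannot pick them up.
        self.heights = np.where(self.mask, self.heights, np.nan)

    # -- convenience accessors -------------------------------------------

    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def is_complete(self) -> bool:
        """True when every grid point is a measured point."""
        return bool(self.mask.all())

    @property
    def valid_heights(self) -> np.ndarray:
        """1D array of heights at valid points."""
        return self.heights[self.mask]

    @property
    def projected_area(self) -> float:
        """Projected (x–y plane) area of the valid points in µm²."""
        return self.n_valid * self.spacing_x * self.spacing_y

    def with_heights(self, heights: np.ndarray) -> "HeightMap":
        return replace(self, heights=heights, mask=self.mask.copy())


# ---------------------------------------------------------------------------
# readers / writers

_FORMATS = ("ascii-grid", "csv-matrix", "xyz-points")


def read_height_map(path, fmt: str, **meta) -> HeightMap:
    """Read a height map from ``path`` under the named dialect.

    Parameters
    ----------
    path
        File to read.
    fmt
        One of ``"ascii-grid"``, ``"csv-matrix"``, ``"xyz-points"``.
    **meta
        Optional ``specimen_id`` / ``group_label`` to attach.
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    text = path.read_text()
    if fmt == "ascii-grid":
        return _parse_ascii_grid(text, **meta)
    if fmt == "csv-matrix":
        return _parse_csv_matrix(text, **meta)
    return _parse_xyz(text, **meta)


def _parse_cell(token: str, lineno: int) -> float:
    token = token.strip()
    if token.upper() in ("NA", "NAN", ""):
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"line {lineno}: cannot parse value {token!r}") from None


def _parse_ascii_grid(text: str, **meta) -> HeightMap:
    lines = text.splitlines()
    header = {}
    i = 0
    for key, nvals in (("ncols", 1), ("nrows", 1), ("spacing_um", 2)):
        if i >= len(lines):
            raise FormatError(f"line {i + 1}: missing header line {key!r}")
        parts = lines[i].split()
        if not parts or parts[0] != key or len(parts) != nvals + 1:
            raise FormatError(f"line {i + 1}: expected header {key!r}, got {lines[i]!r}")
        try:
            header[key] = [float(v) for v in parts[1:]]
        except ValueError:
            raise FormatError(f"line {i + 1}: non-numeric header value in {lines[i]!r}") from None
        i += 1
    ncols, nrows = int(header["ncols"][0]), int(header["nrows"][0])
    dx, dy = header["spacing_um"]
    if dx <= 0 or dy <= 0:
        raise ValidationError(f"non-positive spacing ({dx}, {dy})")
    rows = []
    for r in range(nrows):
        lineno = i + r + 1
        if i + r >= len(lines):
            raise FormatError(f"line {lineno}: expected {nrows} data rows, file ended")
        tokens = lines[i + r].split()
        if len(tokens) != ncols:
            raise FormatError(
                f"line {lineno}: expected {ncols} values, got {len(tokens)}"
            )
        rows.append([_parse_cell(t, lineno) for t in tokens])
    z = np.array(rows, dtype=float)
    return HeightMap(z, dx, dy, **meta)


def _parse_csv_matrix(text: str, **meta) -> HeightMap:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    dx = dy = 1.0
    start = 0
    if lines and lines[0].lstrip().startswith("#"):
        hdr = lines[0].lstrip("# ").strip()
        if hdr.startswith("spacing_um="):
            try:
                dx, dy = (float(v) for v in hdr.split("=", 1)[1].split(","))
            except ValueError:
                raise FormatError(f"line 1: malformed spacing header {lines[0]!r}") from None
            start = 1
        else:
            raise FormatError(f"line 1: unrecognized header {lines[0]!r}")
    if dx <= 0 or dy <= 0:
        raise ValidationError(f"non-positive spacing ({dx}, {dy})")
    rows = []
    width = None
    for r, ln in enumerate(lines[start:]):
        lineno = start + r + 1
        tokens = ln.split(",")
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise FormatError(
                f"line {lineno}: ragged row ({len(tokens)} values, expected {width})"
            )
        rows.append([_parse_cell(t, lineno) for t in tokens])
    if not rows:
        raise FormatError("line 1: no data rows")
    return HeightMap(np.array(rows, dtype=float), dx, dy, **meta)


def _lattice_coords(vals: np.ndarray, axis: str) -> Tuple[np.ndarray, float]:
    """Distinct sorted coordinates and their common spacing."""
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise ValidationError(f"xyz points span fewer than 2 distinct {axis} values")
    steps = np.diff(uniq)
    spacing = float(np.median(steps))
    if spacing <= 0:
        raise ValidationError(f"non-positive {axis} spacing")
    # every coordinate must sit on the lattice implied by (min, spacing)
    idx = (uniq - uniq[0]) / spacing
    if np.max(np.abs(idx - np.round(idx))) > 1e-6:
        raise ValidationError(
            f"xyz points are not on a regular {axis} lattice "
            f"(coordinate residual exceeds 1e-6·spacing)"
        )
    return uniq, spacing


def _parse_xyz(text: str, **meta) -> HeightMap:
    xs: List[float] = []
    ys: List[float] = []
    zs: List[float] = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        stripped = ln.split("#", 1)[0].strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if len(tokens) != 3:
            raise FormatError(f"line {lineno}: expected 3 columns x y z, got {len(tokens)}")
        try:
            x, y, z = (float(t) for t in tokens)
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric value in {stripped!r}") from None
        xs.append(x)
        ys.append(y)
        zs.append(z)
    if not xs:
        raise FormatError("no data points in xyz file")
    xa, ya, za = np.array(xs), np.array(ys), np.array(zs)
    ux, dx = _lattice_coords(xa, "x")
    uy, dy = _lattice_coords(ya, "y")
    grid = np.full((uy.size, ux.size), np.nan)
    ci = np.round((xa - ux[0]) / dx).astype(int)
    ri = np.round((ya - uy[0]) / dy).astype(int)
    grid[ri, ci] = za
    return HeightMap(grid, dx, dy, **meta)


def write_height_map(s: HeightMap, path, fmt: str = "ascii-grid") -> None:
    """Write ``s`` to ``path``; masked points are written as ``NA``."""
    path = Path(path)
    ny, nx = s.shape
    if fmt == "ascii-grid":
        out = [f"ncols {nx}", f"nrows {ny}", f"spacing_um {s.spacing_x:.12g} {s.spacing_y:.12g}"]
        for r in range(ny):
            out.append(" ".join(
                f"{s.heights[r, c]:.12g}" if s.mask[r, c] else "NA" for c in range(nx)
            ))
    elif fmt == "csv-matrix":
        out = [f"# spacing_um={s.spacing_x:.12g},{s.spacing_y:.12g}"]
        for r in range(ny):
            out.append(",".join(
                f"{s.heights[r, c]:.12g}" if s.mask[r, c] else "NA" for c in range(nx)
            ))
    elif fmt == "xyz-points":
        out = ["# x y z (um)"]
        for r in range(ny):
            for c in range(nx):
                if s.mask[r, c]:
                    out.append(
                        f"{c * s.spacing_x:.12g} {r * s.spacing_y:.12g} {s.heights[r, c]:.12g}"
                    )
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# leveling


def level_surface(s: HeightMap) -> HeightMap:
    """Subtract the least-squares plane fitted over valid points.

    The residual surface has zero mean over valid points.  Raises
    :class:`DegeneracyError` when the valid points are collinear (no unique
    plane).
    """
    ny, nx = s.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    m = s.mask
    x = xx[m] * s.spacing_x
    y = yy[m] * s.spacing_y
    z = s.heights[m]
    design = np.column_stack([np.ones_like(x), x, y])
    # collinearity check: the centered (x, y) scatter must have rank 2
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    if np.linalg.matrix_rank(pts, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise DegeneracyError("valid points are collinear; cannot fit a plane")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    plane = coef[0] + coef[1] * xx * s.spacing_x + coef[2] * yy * s.spacing_y
    resid = s.heights - plane
    resid = resid - np.nanmean(resid[m])  # exact zero mean
    return s.with_heights(np.where(m, resid, np.nan))


# ---------------------------------------------------------------------------
# parameter tables


def write_parameter_table(rows: Sequence[Tuple[str, str, "object"]], path) -> None:
    """Write one CSV row per specimen with the 30 parameters in fixed order.

    ``rows`` holds ``(specimen_id, group_label, parameter_set)`` triples,
    where ``parameter_set`` is any mapping-like object with the 30 parameter
    names (a :class:`~microwear.parameters.ParameterSet` or a dict).  Values
    round-trip losslessly at 12 significant digits.
    """
    records = []
    for specimen_id, group_label, ps in rows:
        vals = ps.values if hasattr(ps, "values") and not isinstance(ps, dict) else ps
        missing = set(PARAM_ORDER) - set(vals)
        extra = set(vals) - set(PARAM_ORDER)
        if missing or extra:
            raise ValidationError(
                f"specimen {specimen_id!r}: parameter names do not match the "
                f"fixed set (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        rec = {"specimen_id": specimen_id, "group_label": group_label}
        rec.update({k: vals[k] for k in PARAM_ORDER})
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=["specimen_id", "group_label", *PARAM_ORDER])
    df.to_csv(path, index=False, float_format="%.12g")


def read_parameter_table(path) -> pd.DataFrame:
    """Read a parameter table CSV into a DataFrame.

    Returns columns ``specimen_id``, ``group_label`` and the 30 parameters
    in the fixed order.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "group_label": str})
    missing = [c for c in ("specimen_id", "group_label", *PARAM_ORDER) if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table is missing columns {missing}")
    return df[["specimen_id", "group_label", *PARAM_ORDER]]
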