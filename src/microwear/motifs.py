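"""Watershed motif segmentation with Wolf pruning for feature parameters.

Hills are the catchment basins of the inverted surface (one local maximum
each), dales the catchment basins of the surface itself.  Motifs whose
extremum-to-saddle height difference falls below a fraction of Sz are
merged into the neighbor across the saddle (Wolf pruning); this is
realized through the standard h-extrema construction: markers are the
regional extrema whose dynamic exceeds the pruning height, and a
marker-controlled watershed assigns every grid point to one surviving
motif.  Flooding resolves plateau ties in deterministic raster order, so
motif counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima, h_minima
from skimage.segmentation import watershed

from .exceptions import ValidationError
from .surface import HeightMap

__all__ = ["Motif", "MotifSet", "segment_motifs", "feature_params"]


@dataclass
class Motif:
    """One hill or dale motif.

    ``height`` is the signed extremum height relative to the mean plane
    (µm); ``area`` the projected motif area (µm²); ``volume`` the volume
    (µm³) enclosed between the motif surface and its saddle-closure level;
    ``curvature`` the negated mean Laplacian −½(z_xx + z_yy) at the
    extremum (1/µm), positive for peaks on a dome.
    """

    kind: str  # "hill" or "dale"
    height: float
    area: float
    volume: float
    curvature: float


@dataclass
class MotifSet:
    """Hill and dale motifs of one surface; each family partitions the grid."""

    hills: List[Motif] = field(default_factory=list)
    dales: List[Motif] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.hills and not self.dales


def _curvature_at(z: np.ndarray, r: int, c: int, dx: float, dy: float) -> float:
    """−½(z_xx + z_yy) by central differences; extrema on the border use
    the nearest interior stencil."""
    ny, nx = z.shape
    r = min(max(r, 1), ny - 2)
    c = min(max(c, 1), nx - 2)
    zxx = (z[r, c + 1] - 2.0 * z[r, c] + z[r, c - 1]) / dx**2
    zyy = (z[r + 1, c] - 2.0 * z[r, c] + z[r - 1, c]) / dy**2
    return -0.5 * (zxx + zyy)


def _segment_family(
    z: np.ndarray, h: float, dx: float, dy: float, kind: str
) -> List[Motif]:
    """Segment one motif family on ``z``; ``kind`` selects hills or dales.

    For dales the watershed floods ``z`` from its pruned regional minima;
    hills are the dales of ``−z``.
    """
    surf = -z if kind == "hill" else z
    # markers: regional minima of `surf` with dynamic ≥ h (Wolf pruning)
    seeds = h_minima(surf, h) if h > 0 else (surf == ndimage.minimum_filter(surf, 3))
    markers, n_marks = ndimage.label(seeds)
    if n_marks == 0:
        return []
    labels = watershed(surf, markers=markers, connectivity=1)

    cell = dx * dy
    idx = np.arange(1, n_marks + 1)
    areas = ndimage.sum_labels(np.ones_like(surf), labels, idx) * cell
    # extremum per region (minimum of `surf`) and its location
    ext_pos = ndimage.minimum_position(surf, labels, idx)
    ext_surf = ndimage.minimum(surf, labels, idx)

    # saddle-closure level per region: the level at which the motif first
    # connects to a neighbor.  On `surf` the pass between two catchments is
    # the lowest max(surf_a, surf_b) over adjacent cross-boundary pairs,
    # and a region closes at the lowest pass on its boundary.
    closure = np.full(n_marks + 1, np.inf)
    for axis in (0, 1):
        a = labels.take(range(labels.shape[axis] - 1), axis=axis)
        b = labels.take(range(1, labels.shape[axis]), axis=axis)
        za = surf.take(range(surf.shape[axis] - 1), axis=axis)
        zb = surf.take(range(1, surf.shape[axis]), axis=axis)
        diff = a != b
        if not diff.any():
            continue
        pass_h = np.maximum(za[diff], zb[diff])
        np.minimum.at(closure, a[diff], pass_h)
        np.minimum.at(closure, b[diff], pass_h)
    # single motif covering the grid: close at its own maximum level
    lone = ~np.isfinite(closure[1:])
    if lone.any():
        closure[1:][lone] = ndimage.maximum(surf, labels, idx[lone])

    motifs: List[Motif] = []
    for k in range(n_marks):
        lab = k + 1
        region = labels == lab
        depth = np.maximum(0.0, closure[lab] - surf[region])
        volume = float(depth.sum() * cell)
        r, c = ext_pos[k]
        curv = _curvature_at(z, int(r), int(c), dx, dy)
        height = -ext_surf[k] if kind == "hill" else ext_surf[k]
        motifs.append(
            Motif(kind=kind, height=float(height), area=float(areas[k]),
                  volume=volume, curvature=float(curv))
        )
    return motifs


def segment_motifs(s: HeightMap, prune_fraction: float = 0.05) -> MotifSet:
    """Watershed hills and dales with Wolf pruning at ``prune_fraction``·Sz.

    Motifs shallower than the pruning height (extremum-to-saddle difference
    below 5 % of Sz by default) are merged into their neighbors.  A flat
    surface has no peaks or pits and yields an empty :class:`MotifSet`.
    Extremum heights are reported relative to the mean plane.
    """
    if not s.is_complete:
        raise ValidationError(
            "motif segmentation requires a fully valid grid; crop the "
            "surface to an unmasked rectangle instead of interpolating"
        )
    if not 0.0 <= prune_fraction < 1.0:
        raise ValidationError(f"prune_fraction must lie in [0, 1), got {prune_fraction}")
    z = s.heights - s.heights.mean()
    sz = float(z.max() - z.min())
    if sz == 0.0:
        return MotifSet()
    h = prune_fraction * sz
    hills = _segment_family(z, h, s.spacing_x, s.spacing_y, "hill")
    dales = _segment_family(z, h, s.spacing_x, s.spacing_y, "dale")
    return MotifSet(hills=hills, dales=dales)


def feature_params(m: MotifSet, area: float) -> Dict[str, float]:
    """Feature parameters from a motif set and the total projected area (µm²).

    Spd is the hill (peak) density, Spc the mean hill extremum curvature,
    S5p/S5v the mean extremum height of the five highest hills / deepest
    dales (all of them if fewer than five), S10z their sum, and
    Sha/Sda/Shv/Sdv the mean hill/dale areas and volumes.  An empty motif
    set (flat surface) reports all nine as 0.
    """
    if area <= 0:
        raise ValidationError(f"total projected area must be positive, got {area}")
    if m.is_empty:
        return {k: 0.0 for k in
                ("Spd", "Spc", "S10z", "S5p", "S5v", "Sda", "Sha", "Sdv", "Shv")}
    hill_h = sorted((h.height for h in m.hills), reverse=True)
    dale_h = sorted((abs(d.height) for d in m.dales), reverse=True)
    s5p = float(np.mean(hill_h[:5])) if hill_h else 0.0
    s5v = float(np.mean(dale_h[:5])) if dale_h else 0.0
    out = {
        "Spd": len(m.hills) / area,
        "Spc": float(np.mean([h.curvature for h in m.hills])) if m.hills else 0.0,
        "S5p": s5p,
        "S5v": s5v,
        "S10z": s5p + s5v,
        "Sha": float(np.mean([h.area for h in m.hills])) if m.hills else 0.0,
        "Sda": float(np.mean([d.area for d in m.dales])) if m.dales else 0.0,
        "Shv": float(np.mean([h.volume for h in m.hills])) if m.hills else 0.0,
        "Sdv": float(np.mean([d.volume for d in m.dales])) if m.dales else 0.0,
    }
    return out
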