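"""ISO 25178 areal surface texture parameters from gridded height maps.

The 30 parameters fall into five families:

* height parameters (Sa, Sq, Ssk, Sku, Sp, Sv, Sz) — moments and extremes
  of the height distribution;
* functional parameters (Smc, Smr, Sxp) and volume parameters
  (Vm, Vmc, Vmp, Vv, Vvc, Vvv) — read off the Abbott–Firestone
  material-ratio curve, i.e. the inverse cumulative height distribution
  ζ(p);
* spatial parameters (Sal, Str, Std) — from the areal autocorrelation
  function;
* hybrid parameters (Sdq, Sdr) — surface-gradient statistics;
* feature parameters (Spd, Spc, S10z, S5p, S5v, Sda, Sha, Sdv, Shv) —
  from watershed motif segmentation with Wolf pruning (see
  :mod:`microwear.motifs`).

All heights are in µm; area-weighted means reduce to simple means on the
uniform grid.  Statistics are restricted to valid (unmasked) points; the
spatial, hybrid and feature families require a fully valid grid because
they depend on neighborhood structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegeneracyError, ValidationError
from .motifs import MotifSet, feature_params, segment_motifs
from .surface import PARAM_ORDER, PARAM_UNITS, HeightMap, level_surface

__all__ = [
    "ParameterSet",
    "AbbottCurve",
    "height_params",
    "abbott_curve",
    "functional_params",
    "spatial_params",
    "hybrid_params",
    "volume_params",
    "compute_all",
]

#: Parameters that need every grid point to be a measured point.
FULL_GRID_PARAMS = (
    "Sal", "Str", "Std", "Sdq", "Sdr",
    "Spd", "Spc", "S10z", "S5p", "S5v", "Sda", "Sha", "Sdv", "Shv",
)


@dataclass
class ParameterSet:
    """The 30 named areal texture parameter values for one surface.

    Values are floats in the units of :data:`microwear.surface.PARAM_UNITS`;
    NaN marks a parameter that is undefined for the surface (Ssk/Sku on a
    perfectly flat surface) or not computable (neighborhood parameters on a
    masked grid).
    """

    values: Dict[str, float]
    notes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_ORDER)
        if unknown:
            raise ValidationError(f"unknown parameter names {sorted(unknown)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values.get(k, np.nan) for k in PARAM_ORDER})

    @property
    def units(self) -> Dict[str, str]:
        return {k: PARAM_UNITS[k] for k in self.values}


@dataclass
class AbbottCurve:
    """Areal material-ratio curve: height ζ(p) vs material ratio p.

    ``p`` is an even grid over [0, 100] % and ``zeta`` the corresponding
    section heights in µm; ζ is non-increasing, ζ(0) is the maximum height
    (Sp reference) and ζ(100) the minimum (−Sv).
    """

    p: np.ndarray
    zeta: np.ndarray

    def __call__(self, p: float) -> float:
        """Evaluate ζ at material ratio ``p`` (linear interpolation)."""
        return float(np.interp(p, self.p, self.zeta))


# ---------------------------------------------------------------------------
# height parameters


def height_params(s: HeightMap) -> Dict[str, float]:
    """Moments and extremes of the height distribution over valid points.

    Expects a leveled surface (mean height ≈ 0).  On a perfectly flat
    surface Sq = 0 and the normalized moments Ssk, Sku are undefined; they
    are reported as NaN rather than 0/0.
    """
    z = s.valid_heights
    sa = float(np.mean(np.abs(z)))
    sq = float(np.sqrt(np.mean(z**2)))
    sp = float(np.max(z))
    sv = float(-np.min(z))
    if sq > 0:
        ssk = float(np.mean(z**3) / sq**3)
        sku = float(np.mean(z**4) / sq**4)
    else:
        ssk = np.nan
        sku = np.nan
    return {"Sa": sa, "Sq": sq, "Ssk": ssk, "Sku": sku,
            "Sp": sp, "Sv": sv, "Sz": sp + sv}


# ---------------------------------------------------------------------------
# Abbott–Firestone curve and the functional / volume families


def abbott_curve(s: HeightMap, n_ratios: Optional[int] = None) -> AbbottCurve:
    """Material-ratio curve ζ(p): the (1 − p/100)-quantile of the heights.

    Quantiles use linear interpolation between order statistics, so ζ is
    piecewise linear with knots at material ratios k/(N−1)·100 for N valid
    points.  By default the even p-grid is chosen as the smallest grid with
    at least 1001 points whose step divides the knot spacing; every knot
    then falls on a grid point and trapezoidal integration of the curve is
    exact.
    """
    z = s.valid_heights
    n = z.size
    if n < 4:
        raise ValidationError("Abbott curve needs at least 4 valid points")
    if n_ratios is None:
        k = int(np.ceil(1000 / (n - 1)))
        n_ratios = k * (n - 1) + 1
    if n_ratios < 101:
        raise ValidationError("n_ratios must be at least 101")
    p = np.linspace(0.0, 100.0, n_ratios)
    zeta = np.quantile(z, 1.0 - p / 100.0, method="linear")
    return AbbottCurve(p=p, zeta=zeta)


def functional_params(
    c: AbbottCurve,
    p_smc: float = 10.0,
    smr_offset: float = 1.0,
    p_sxp: float = 2.5,
    q_sxp: float = 50.0,
) -> Dict[str, float]:
    """Functional parameters Smc, Smr, Sxp from the material-ratio curve.

    * ``Smc`` — inverse areal material ratio: the section height (µm) at
      material ratio ``p_smc`` (default 10 %).
    * ``Smr`` — areal material ratio (%) at the section height
      ζ(0) − ``smr_offset`` (default 1 µm below the highest peak); 100 % if
      the surface spans less than the offset.
    * ``Sxp`` — peak extreme height: ζ(``p_sxp``) − ζ(``q_sxp``)
      (defaults 2.5 % and 50 %).
    """
    for name, v in (("p_smc", p_smc), ("p_sxp", p_sxp), ("q_sxp", q_sxp)):
        if not 0.0 < v < 100.0:
            raise ValidationError(f"{name} must lie in (0, 100), got {v}")
    smc = c(p_smc)
    sxp = c(p_sxp) - c(q_sxp)
    target = c.zeta[0] - smr_offset
    if target < c.zeta[-1]:
        smr = 100.0
    else:
        # first (smallest-p) crossing of the non-increasing curve
        below = np.nonzero(c.zeta <= target)[0]
        i = below[0]
        if i == 0:
            smr = float(c.p[0])
        else:
            z0, z1 = c.zeta[i - 1], c.zeta[i]
            if z0 == z1:
                smr = float(c.p[i - 1])
            else:
                frac = (z0 - target) / (z0 - z1)
                smr = float(c.p[i - 1] + frac * (c.p[i] - c.p[i - 1]))
    return {"Smc": smc, "Smr": smr, "Sxp": sxp}


def _material_void_volumes(c: AbbottCurve, x: float) -> tuple[float, float]:
    """Vm(x), Vv(x) in µm³/µm² by trapezoidal integration of ζ.

    The evaluation ratio ``x`` is inserted into the integration grid with
    its interpolated ζ value, which keeps the trapezoid rule exact for the
    piecewise-linear curve whenever the p-grid contains the quantile knots.
    """
    zx = c(x)
    left = c.p <= x
    pm = np.append(c.p[left], x)
    zm = np.append(c.zeta[left], zx)
    vm = np.trapezoid(zm - zx, pm) / 100.0
    right = c.p >= x
    pv = np.concatenate([[x], c.p[right]])
    zv = np.concatenate([[zx], c.zeta[right]])
    vv = np.trapezoid(zx - zv, pv) / 100.0
    return float(vm), float(vv)


def volume_params(c: AbbottCurve, p: float = 10.0, q: float = 80.0) -> Dict[str, float]:
    """Material and void volume parameters at material ratios p and q.

    With Vm(x) = (1/100)·∫₀ˣ [ζ(r) − ζ(x)] dr and
    Vv(x) = (1/100)·∫ₓ¹⁰⁰ [ζ(x) − ζ(r)] dr (both in µm³ per µm² of
    projected area):

    * ``Vmp`` = Vm(p) — peak material volume; ``Vm`` reported ≡ Vmp.
    * ``Vmc`` = Vm(q) − Vm(p) — core material volume.
    * ``Vvv`` = Vv(q) — dale void volume.
    * ``Vvc`` = Vv(p) − Vv(q) — core void volume; ``Vv`` reported = Vv(p).
    """
    if not (0.0 < p < 100.0 and 0.0 < q < 100.0):
        raise ValidationError(f"material ratios must lie in (0, 100), got p={p}, q={q}")
    if p >= q:
        raise ValidationError(f"need p < q, got p={p}, q={q}")
    vm_p, vv_p = _material_void_volumes(c, p)
    vm_q, vv_q = _material_void_volumes(c, q)
    return {
        "Vm": vm_p,
        "Vmp": vm_p,
        "Vmc": vm_q - vm_p,
        "Vv": vv_p,
        "Vvc": vv_p - vv_q,
        "Vvv": vv_q,
    }


# ---------------------------------------------------------------------------
# spatial parameters


def spatial_params(
    s: HeightMap, threshold: float = 0.2, angle_step: float = 1.0
) -> Dict[str, float]:
    """Autocorrelation length Sal, texture aspect ratio Str, direction Std.

    The normalized areal autocorrelation function (ACF) is computed through
    the power spectrum.  Along each direction θ ∈ [0°, 180°) the decay
    length is the smallest sampled lag at which the ACF falls below
    ``threshold`` (capped at half the field).  Then

    * ``Sal`` = minimum decay length over directions (µm),
    * ``Str`` = minimum / maximum decay length ∈ [0, 1],
    * ``Std`` = direction of slowest decay, i.e. the dominant ridge
      orientation, in degrees counter-clockwise from the x-axis (a grating
      with ridges parallel to the y-axis has Std = 90°).

    Requires a fully valid grid: the FFT-based ACF cannot skip masked
    points without fabricating texture.
    """
    if not s.is_complete:
        raise ValidationError(
            "spatial parameters require a fully valid grid; crop the surface "
            "to an unmasked rectangle instead of interpolating"
        )
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    z = s.heights - s.heights.mean()
    if np.all(z == 0):
        # flat surface: no decorrelation anywhere
        rmax = 0.5 * min(s.shape[1] * s.spacing_x, s.shape[0] * s.spacing_y)
        return {"Sal": rmax, "Str": 1.0, "Std": 0.0}
    ny, nx = z.shape
    spec = np.abs(np.fft.fft2(z)) ** 2
    acf = np.real(np.fft.ifft2(spec))
    acf = np.fft.fftshift(acf / acf[0, 0])
    cy, cx = ny // 2, nx // 2

    step = min(s.spacing_x, s.spacing_y)
    angles = np.arange(0.0, 180.0, angle_step)
    theta = np.deg2rad(angles)
    # radii sampled per ray, bounded so every sample stays inside the array
    kmax_x = (nx - 1 - cx) * s.spacing_x
    kmax_y = (ny - 1 - cy) * s.spacing_y
    rmax = min(kmax_x, kmax_y)
    nk = int(np.floor(rmax / step))
    radii = step * np.arange(1, nk + 1)
    cols = cx + np.outer(np.cos(theta), radii) / s.spacing_x
    rows = cy + np.outer(np.sin(theta), radii) / s.spacing_y
    vals = ndimage.map_coordinates(acf, [rows.ravel(), cols.ravel()], order=1)
    vals = vals.reshape(len(angles), nk)

    below = vals < threshold
    first = np.argmax(below, axis=1)
    decay = np.where(below.any(axis=1), radii[first], rmax)
    sal = float(decay.min())
    smax = float(decay.max())
    # dominant ridge orientation: the angular maximum of the ACF, taken as
    # the ray with the largest integrated ACF (robust when several rays
    # never cross the threshold)
    std = float(angles[int(np.argmax(vals.mean(axis=1)))] % 180.0)
    return {"Sal": sal, "Str": sal / smax, "Std": std}


# ---------------------------------------------------------------------------
# hybrid parameters


def hybrid_params(s: HeightMap) -> Dict[str, float]:
    """Root-mean-square gradient Sdq and developed interfacial area ratio Sdr.

    Sdq uses central differences (one-sided at borders).  Sdr triangulates
    each grid cell into two triangles along the same diagonal everywhere
    and reports 100·(developed area / projected area − 1) in %.
    """
    if not s.is_complete:
        raise ValidationError("hybrid parameters require a fully valid grid")
    z = s.heights
    gy, gx = np.gradient(z, s.spacing_y, s.spacing_x)
    sdq = float(np.sqrt(np.mean(gx**2 + gy**2)))

    dx, dy = s.spacing_x, s.spacing_y
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]
    # split along the (0,0)–(1,1) diagonal: triangles (00,01,11) and (00,10,11)
    a1 = 0.5 * np.sqrt((dy * (z01 - z00)) ** 2 + (dx * (z01 - z11)) ** 2 + (dx * dy) ** 2)
    a2 = 0.5 * np.sqrt((dy * (z10 - z11)) ** 2 + (dx * (z10 - z00)) ** 2 + (dx * dy) ** 2)
    developed = float(np.sum(a1 + a2))
    projected = dx * dy * z00.size
    sdr = 100.0 * (developed / projected - 1.0)
    return {"Sdq": sdq, "Sdr": sdr}


# ---------------------------------------------------------------------------
# full parameter set


def compute_all(
    s: HeightMap,
    level: bool = True,
    *,
    p_smc: float = 10.0,
    smr_offset: float = 1.0,
    p_sxp: float = 2.5,
    q_sxp: float = 50.0,
    volume_p: float = 10.0,
    volume_q: float = 80.0,
    acf_threshold: float = 0.2,
    prune_fraction: float = 0.05,
    on_incomplete: str = "nan",
) -> ParameterSet:
    """Compute all 30 areal texture parameters of a height map.

    Plane leveling is applied first unless ``level=False``.  The height,
    functional and volume families use valid points only; the spatial,
    hybrid and feature families need a fully valid grid — with
    ``on_incomplete="nan"`` (default) those parameters are reported as NaN
    on masked grids so that downstream group statistics can treat them as
    missing, with ``"raise"`` a :class:`ValidationError` propagates, naming
    the first failing parameter family.
    """
    if on_incomplete not in ("nan", "raise"):
        raise ValidationError("on_incomplete must be 'nan' or 'raise'")
    if level:
        s = level_surface(s)
    vals: Dict[str, float] = {}
    notes: Dict[str, str] = {}
    vals.update(height_params(s))
    curve = abbott_curve(s)
    vals.update(functional_params(curve, p_smc, smr_offset, p_sxp, q_sxp))
    vals.update(volume_params(curve, volume_p, volume_q))
    if s.is_complete:
        vals.update(spatial_params(s, threshold=acf_threshold))
        vals.update(hybrid_params(s))
        motifs = segment_motifs(s, prune_fraction=prune_fraction)
        if motifs.is_empty and vals["Sz"] > 0:
            notes["features"] = "no motifs survived pruning"
        feats = feature_params(motifs, s.projected_area)
        vals.update(feats)
    else:
        if on_incomplete == "raise":
            raise ValidationError(
                "Sal: spatial, hybrid and feature parameters need a fully "
                "valid grid but the height map has masked points"
            )
        for name in FULL_GRID_PARAMS:
            vals[name] = np.nan
        notes["masked"] = (
            "spatial/hybrid/feature parameters skipped: grid has masked points"
        )
    return ParameterSet(values=vals, notes=notes)
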