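"""Synthetic wear-facet surfaces with controlled roughness statistics.

Three generators cover the testing and simulation needs of the pipeline:

* :func:`make_fixture` — deterministic analytic surfaces (flat, tilted
  plane, sinusoid, bimodal, raster ramp, Gaussian bump, egg crate) whose
  texture parameters have closed forms;
* :func:`gaussian_field` — stationary Gaussian random fields by spectral
  synthesis with a Gaussian autocorrelation model, rescaled to an exact
  target Sq, with an optional monotone exponential transform to induce
  positive skew;
* :func:`sample_habitat` — groups of random surfaces whose per-specimen
  roughness targets are drawn around a habitat's mean Sa, emulating the
  between-specimen spread observed on real facets.

The habitat presets encode the study conditions of the four Malagasy
sampling areas: mean Sa 0.269 µm (village, n=19), 0.238 µm (manioc
fields, n=3), 0.248 µm (spiny forest, n=3) and 0.173 µm (rainforest,
n=12), with the observed between-specimen standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np

from .exceptions import ValidationError
from .surface import HeightMap

__all__ = [
    "SurfaceSpec",
    "HabitatPreset",
    "HABITAT_PRESETS",
    "make_fixture",
    "gaussian_field",
    "sample_habitat",
]

#: Ratio Sq/Sa of a zero-mean Gaussian height distribution.
GAUSSIAN_SQ_OVER_SA = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class SurfaceSpec:
    """Recipe for one random rough surface.

    Defaults emulate a plausible confocal facet scan: 256×256 samples at
    0.35 µm spacing (≈ 90×90 µm field) with a 2.8 µm correlation length.
    """

    nx: int = 256
    ny: int = 256
    spacing: float = 0.35
    target_sq: float = 0.3
    correlation_length: float = 2.8
    skew_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValidationError("random fields need at least 16×16 samples")
        if self.target_sq <= 0:
            raise ValidationError(f"target_sq must be positive, got {self.target_sq}")
        if self.spacing <= 0:
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.correlation_length < self.spacing:
            raise ValidationError(
                "correlation_length must be at least one sample spacing"
            )
        if self.correlation_length >= min(self.nx, self.ny) * self.spacing / 4.0:
            raise ValidationError(
                "correlation_length too large for the field: fewer than ~4 "
                "independent patches per side"
            )


@dataclass(frozen=True)
class HabitatPreset:
    """Per-habitat roughness target: mean Sa, between-specimen spread, n."""

    name: str
    mean_sa: float
    sd_sa: float
    n: int


#: The four sampling areas with their observed group statistics.
HABITAT_PRESETS: Dict[str, HabitatPreset] = {
    "village": HabitatPreset("village", 0.269, 0.060, 19),
    "manioc_fields": HabitatPreset("manioc_fields", 0.238, 0.109, 3),
    "spiny_forest": HabitatPreset("spiny_forest", 0.248, 0.107, 3),
    "rainforest": HabitatPreset("rainforest", 0.173, 0.072, 12),
}


# ---------------------------------------------------------------------------
# analytic fixtures


def make_fixture(
    kind: str, nx: int = 64, ny: int = 64, spacing: float = 1.0, **params
) -> HeightMap:
    """Deterministic analytic surface with closed-form texture parameters.

    Kinds and their parameters (all heights in µm):

    * ``flat`` — all zeros.
    * ``tilted`` — plane ``slope_x``·x + ``slope_y``·y (defaults 0.1, 0).
    * ``sinusoid`` — A·sin(2πx/λ) with ``amplitude`` A and ``wavelength``
      λ in samples; λ must be a multiple of 4 and divide nx so that the
      surface spans integer periods with extrema on grid nodes.
    * ``bimodal`` — left half +h, right half −h (``h``, nx even).
    * ``ramp`` — raster ramp: all nx·ny heights distinct and evenly spaced
      over [−h, +h], so the height distribution is exactly uniform and the
      material-ratio curve exactly linear.
    * ``gaussian_bump`` — H·exp(−r²/2σ²) centered on the grid
      (``height`` H, ``sigma`` in µm).
    * ``egg_crate`` — A·sin(2πx/λ)·sin(2πy/λ) with ``periods`` full
      periods per axis (λ = nx·spacing/periods); 2·periods² maxima and as
      many minima.
    """
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    xx, yy = np.meshgrid(x, y)
    if kind == "flat":
        z = np.zeros((ny, nx))
    elif kind == "tilted":
        z = params.get("slope_x", 0.1) * xx + params.get("slope_y", 0.0) * yy
    elif kind == "sinusoid":
        A = params.get("amplitude", 1.0)
        lam = int(params.get("wavelength", 16))
        if lam % 4 != 0 or nx % lam != 0:
            raise ValidationError(
                f"sinusoid wavelength must be a multiple of 4 samples and "
                f"divide nx={nx}, got {lam} (closed forms require integer "
                f"periods with extrema on grid nodes)"
            )
        z = A * np.sin(2.0 * np.pi * np.arange(nx) / lam)[None, :] * np.ones((ny, 1))
    elif kind == "bimodal":
        h = params.get("h", 0.5)
        if nx % 2 != 0:
            raise ValidationError("bimodal fixture needs an even number of columns")
        z = np.full((ny, nx), -h)
        z[:, : nx // 2] = h
    elif kind == "ramp":
        h = params.get("h", 1.0)
        z = np.linspace(-h, h, nx * ny).reshape(ny, nx)
    elif kind == "gaussian_bump":
        H = params.get("height", 1.0)
        sigma = params.get("sigma", 3.0 * spacing)
        cx, cy = x[nx // 2], y[ny // 2]
        z = H * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))
    elif kind == "egg_crate":
        A = params.get("amplitude", 1.0)
        per = int(params.get("periods", 2))
        if per < 1 or nx % (4 * per) != 0 or ny % (4 * per) != 0:
            raise ValidationError(
                f"egg_crate needs nx and ny divisible by 4·periods so extrema "
                f"fall on grid nodes, got periods={per}, grid {nx}×{ny}"
            )
        lamx = nx * spacing / per
        lamy = ny * spacing / per
        z = A * np.sin(2.0 * np.pi * xx / lamx) * np.sin(2.0 * np.pi * yy / lamy)
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    return HeightMap(z, spacing, spacing, specimen_id=f"fixture-{kind}")


# ---------------------------------------------------------------------------
# random rough surfaces


def gaussian_field(spec: SurfaceSpec) -> HeightMap:
    """Stationary random surface with Gaussian autocorrelation exp(−r²/L²).

    Spectral synthesis: white Gaussian noise is filtered in the frequency
    domain with the amplitude transfer function of the Gaussian ACF model
    with correlation length L, re-centered and rescaled so the realized Sq
    equals ``spec.target_sq`` exactly.  A positive ``skew_strength`` s
    applies the monotone transform (exp(s·z/Sq) − 1)/s before the final
    re-centering and rescaling, inducing positive skewness while leaving
    the target Sq exact.  Identical spec (including seed) gives a
    bit-identical surface.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.ny, spec.nx))
    kx = 2.0 * np.pi * np.fft.fftfreq(spec.nx, d=spec.spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(spec.ny, d=spec.spacing)
    k2 = kx[None, :] ** 2 + ky[:, None] ** 2
    L = spec.correlation_length
    transfer = np.exp(-k2 * L**2 / 8.0)  # sqrt of the Gaussian-ACF spectrum
    z = np.real(np.fft.ifft2(np.fft.fft2(noise) * transfer))
    z -= z.mean()
    z *= spec.target_sq / np.sqrt(np.mean(z**2))
    if spec.skew_strength != 0.0:
        s = spec.skew_strength
        u = z / spec.target_sq
        z = (np.exp(s * u) - 1.0) / s
        z -= z.mean()
        z *= spec.target_sq / np.sqrt(np.mean(z**2))
    return HeightMap(z, spec.spacing, spec.spacing)


def sample_habitat(
    preset: HabitatPreset,
    seed: int,
    template: Optional[SurfaceSpec] = None,
    n: Optional[int] = None,
) -> List[HeightMap]:
    """Generate one group of surfaces for a habitat preset.

    Per-specimen target Sa values are drawn from a normal distribution
    with the preset's mean and spread (clipped below at 0.02 µm, a floor
    far in the tail for all presets) and converted to target Sq through
    the Gaussian-field ratio Sq/Sa = √(π/2).  ``template`` fixes grid and
    correlation structure; per-surface seeds derive deterministically from
    ``seed``.
    """
    size = preset.n if n is None else int(n)
    if size < 1:
        raise ValidationError(f"group size must be at least 1, got {size}")
    if template is None:
        template = SurfaceSpec()
    rng = np.random.default_rng(seed)
    surfaces = []
    for i in range(size):
        sa = max(0.02, rng.normal(preset.mean_sa, preset.sd_sa))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            template, target_sq=sa * GAUSSIAN_SQ_OVER_SA, seed=child_seed
        )
        s = gaussian_field(spec)
        s.specimen_id = f"{preset.name}-{i:02d}"
        s.group_label = preset.name
        surfaces.append(s)
    return surfaces
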