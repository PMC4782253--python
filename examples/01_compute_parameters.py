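"""Compute the 30 areal texture parameters of a single surface.

Builds two surfaces — an analytic sinusoidal grating with known closed
forms, and a random rough surface emulating a worn facet — and prints a
selection of their parameters with units.
"""

from microwear import (
    PARAM_UNITS,
    SurfaceSpec,
    compute_all,
    gaussian_field,
    make_fixture,
)

# a 1 µm amplitude grating: Sa → 2/π ≈ 0.6366 µm, Sq → 1/√2 ≈ 0.7071 µm,
# ridges parallel to y so the texture direction Std is 90°
grating = make_fixture("sinusoid", nx=256, ny=64, amplitude=1.0, wavelength=128)
ps = compute_all(grating, level=False)
print("sinusoidal grating (A = 1 µm):")
for name in ("Sa", "Sq", "Sku", "Sp", "Sz", "Str", "Std"):
    print(f"  {name:4s} = {ps[name]:8.4f} {PARAM_UNITS[name]}")

# a synthetic facet: Gaussian roughness with Sq = 0.35 µm and a 2.8 µm
# correlation length on a 90×90 µm field
facet = gaussian_field(SurfaceSpec(target_sq=0.35, seed=1))
ps = compute_all(facet)
print("\nsynthetic facet (target Sq = 0.35 µm):")
for name in ("Sa", "Sq", "Ssk", "Sal", "Sdr", "Vmc", "Vvc", "Spd"):
    print(f"  {name:4s} = {ps[name]:10.5f} {PARAM_UNITS[name]}")
print("\nSa is the mean roughness; Sal the distance over which the texture")
print("decorrelates; Vmc/Vvc the core material/void volumes per unit area.")
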