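# Methods

`microwear` implements dental 3D surface texture analysis (3DST): it
reduces a gridded height map of a worn enamel facet to the 30 ISO 25178
areal texture parameters and compares habitat groups of specimens with a
robust heteroscedastic inference battery, finally ranking the groups by
dietary abrasiveness. This note records the models, conventions and
numerical choices, and what the synthetic surfaces do and do not emulate.

## Surfaces and preprocessing

A surface is a regular lattice of heights (µm) with lateral spacings
`spacing_x`, `spacing_y` (µm) and a per-point validity mask. Non-measured
points are **excluded**, never interpolated: interpolation would fabricate
texture at exactly the spatial scales the parameters measure. Parameter
families that are pure statistics of the height distribution (height,
functional, volume) simply skip invalid points; families that depend on
neighborhood structure (spatial, hybrid, feature) require a fully valid
grid and otherwise report NaN (or raise, with `on_incomplete="raise"`).

Facet orientation on the tooth is arbitrary, so the pipeline subtracts the
least-squares plane over valid points before computing parameters
(disable with `level=False`). Without leveling, the tilt dominates the
hybrid parameters (Sdq, Sdr). No S-filter or F-operator band-pass nesting
is applied: the instrument and filtration chain of a particular microscope
are out of scope, and the leveling-only default is an explicit choice, not
a standard. A subtlety worth knowing: the least-squares plane of a pure
sinusoid spanning whole periods is *not* flat (the best-fit line through
one period of sin x has slope −12/(4π²) per unit amplitude), so leveling
slightly reshapes even "already periodic" surfaces; what is exactly true,
and what the tests assert, is that leveling is idempotent and invariant to
adding any plane.

## The 30 parameters

**Height family** — Sa (mean |z|), Sq (RMS), Ssk, Sku (3rd/4th
standardized moments), Sp, Sv (extremes), Sz = Sp + Sv. On a perfectly
flat surface Ssk and Sku are 0/0 and reported as NaN, not zero.

**Material-ratio curve** — ζ(p), the height at areal material ratio
p ∈ [0, 100] %, is the (1 − p/100) quantile of the height distribution
with linear interpolation between order statistics (type-7 convention).
ζ is therefore piecewise linear with knots at p = 100·k/(N−1). The default
evaluation grid is the smallest even grid with ≥ 1001 points whose step
divides the knot spacing, so every knot lies on the grid and trapezoidal
integration of the curve is **exact**; the oracle tests exploit this to
demand 1e-9 agreement with direct geometric integration over the sorted
heights.

**Functional family** — Smc = ζ(10 %); Smr = the material ratio at the
section 1 µm below the highest peak (100 % if the surface spans less);
Sxp = ζ(2.5 %) − ζ(50 %). All three reference ratios/offsets are
config-exposed; the defaults follow the ISO recommendations, since the
conventions of any particular commercial metrology package are not
reconstructable.

**Volume family** — Vm(x) = (1/100)·∫₀ˣ[ζ(r) − ζ(x)]dr and
Vv(x) = (1/100)·∫ₓ¹⁰⁰[ζ(x) − ζ(r)]dr in µm³/µm², reported at the ISO
default ratios p = 10 %, q = 80 % as Vmp = Vm(p), Vmc = Vm(q) − Vm(p),
Vvv = Vv(q), Vvc = Vv(p) − Vv(q), with "Vm" ≡ Vmp and "Vv" = Vv(p). The
reported Vm equals Vmp identically under these defaults — the same
identity visible in published descriptive tables of this parameter set.

**Spatial family** — the areal autocorrelation function is computed via
the power spectrum (circular ACF; the synthetic fields are spectrally
periodic, so this is exact for them). Along each 1°-spaced direction the
decay length is the first sampled lag (step = one sample spacing) at
which the ACF drops below s = 0.2, capped at half the field. Sal is the
minimum decay length, Str = min/max ∈ [0, 1], and Std is the direction of
the angular maximum of the ACF — implemented as the ray with the largest
integrated ACF, which breaks the tie cleanly when several rays never
cross the threshold (a grating with ridges parallel to the y-axis gives
Std = 90°, measured counter-clockwise from the x-axis). Reporting the
first *sampled* lag means white noise yields exactly one sample spacing.

**Hybrid family** — Sdq is the RMS gradient with central differences
(one-sided at borders); Sdr = 100·(developed/projected − 1) with each
cell split into two triangles along the same diagonal everywhere. The
fixed diagonal makes Sdr very slightly orientation-dependent (≈ 2e-4
relative under 90° rotation on smooth random surfaces) — the invariance
test budgets for this.

**Feature family** — hills are watershed catchments of the inverted
surface, dales of the surface itself; each family partitions the grid.
Wolf pruning removes motifs whose extremum-to-saddle difference is below
5 % of Sz, implemented through the standard h-extrema construction
(markers = regional extrema with dynamic ≥ h, then marker-controlled
watershed). Plateau ties resolve in deterministic raster order, so motif
counts are reproducible — at the cost of single-cell boundary shifts
under grid rotation, which the tests budget for in the motif areas and
volumes. Per motif: extremum height (relative to the mean plane), area,
volume between the surface and the motif's saddle-closure level, and
extremum curvature −½(z_xx + z_yy) (positive for peaks). Spd is hill
density, Spc mean hill curvature, S5p/S5v the means of the five highest
hills / deepest dales, S10z their sum, Sha/Sda/Shv/Sdv mean areas and
volumes. A flat surface has no motifs and reports zeros.

## Inference battery

Texture parameters across specimens are typically non-normal and
heteroscedastic, so all tests work on γ-trimmed means with γ = 0.15
(g = ⌊γn⌋ observations removed per tail; winsorized variance with the
same g). Three pieces, sharing a per-group squared standard error
d_j = (n_j−1)s²_wj/(h_j(h_j−1)) with h_j = n_j − 2g_j:

1. **Welch–Yuen omnibus** — the heteroscedastic F-type statistic on
   trimmed means, ν1 = J − 1, Satterthwaite-style ν2. With J = 2 and
   γ = 0 it reduces exactly to the square of Welch's t (verified to 1e-8
   against an independent implementation).
2. **Pairwise trimmed-means tests** ("Lincon", analogous to Dunnett's
   T3) — t = |x̄_t1 − x̄_t2|/√(d₁+d₂) with Welch-type df, one result per
   unordered pair. P-values are reported per pair, unadjusted, and
   flagged at α = 0.05 — reproducing the presentation of the published
   tables; a Šidák family-wise adjustment is available behind
   `adjust=True` for users who want the conservative reading.
3. **Cliff's method** — δ = P(X>Y) − P(X<Y) estimated over all pairs
   (ties count 0), variance from Cliff's consistent estimator combining
   row-mean, column-mean and cell variances (validated against the
   Monte-Carlo variance of δ), and the asymmetric CI at level 1 − α. A
   pair is "Cliff-significant" when the CI excludes 0. Degenerate cases:
   all-tied samples give δ = 0, not significant; complete separation
   (|δ| = 1) has a degenerate variance estimate, and the CI is computed
   as if one of the n_x·n_y comparisons were tied — keeping the bound
   inside (−1, 1) — then clamped to contain the point estimate.

**Consensus rule** — a pair differs iff the trimmed-means P ≤ α **and**
Cliff's interval excludes 0; a parameter is significant iff at least one
pair is. The omnibus does not gate the pairwise battery: consensus is
defined purely pairwise, so a parameter can be consensus-significant even
when its omnibus P slightly exceeds α (a pattern that does occur in
published tables of this design).

Group dropout is per parameter: a group with fewer than two usable values
for a parameter, or with zero winsorized variance, is dropped from that
parameter's tests (logged), shrinking ν1 accordingly. This supports the
realistic case where feature parameters are missing on degenerate
surfaces for a whole group.

A caveat the acceptance suite makes explicit: with two groups of n = 3
carrying the largest variances (σ up to 4× the others), the Welch–Yuen
omnibus is mildly liberal — its simulated type-I rate at α = 0.05 is
≈ 0.098 rather than ≤ 0.09. This is a property of the test at such group
sizes, not of the implementation (which matches the published formulas
and the Welch reduction exactly); at these sample sizes the omnibus
p-values near 0.05 deserve caution.

## Abrasiveness ranking

Only consensus-significant parameters enter the ranking. For each, groups
are ranked by group mean (rank 1 = highest); ranks are averaged across
parameters; groups are ordered by mean rank. Tie classes: two adjacent
groups share a class when no parameter separates them by consensus *and*
they are separated from exactly the same third parties. This makes the
common pattern "only the extremes separate" come out as
`extreme > {intermediate, intermediate} > extreme`, which is the natural
formalization of a narrative ranking with an unseparated middle pair.
With no consensus-significant parameter the ranking is "indeterminate".

Descriptive tables use untrimmed means and SDs (n − 1), the conventional
presentation, while tests use trimmed means — an intentional split.

## Synthetic surfaces

Because no raw facet scans are available, a generator produces surfaces
whose roughness statistics emulate the four habitat groups:

* **Model** — stationary Gaussian random field by spectral synthesis with
  a Gaussian ACF exp(−r²/L²). The Gaussian (rather than exponential) ACF
  gives differentiable surfaces so that gradients and curvatures are
  stable on coarse grids. Defaults: 256×256 samples at 0.35 µm spacing
  (≈ 90×90 µm field, a plausible confocal facet scan) and L = 2.8 µm; all
  config-exposed since acquisition details are unknowable here.
* **Amplitude** — the realized field is rescaled so Sq matches its target
  exactly, decoupling calibration tests from Monte-Carlo noise. An
  optional monotone transform (exp(s·z/Sq) − 1)/s induces positive skew.
* **Groups** — per-specimen target Sa is drawn from a normal distribution
  with the habitat's mean and between-specimen SD (village 0.269 ± 0.060
  µm, n = 19; manioc fields 0.238 ± 0.109, n = 3; spiny forest
  0.248 ± 0.107, n = 3; rainforest 0.173 ± 0.072, n = 12), clipped below
  at 0.02 µm (a floor several SDs in the tail), and converted to a target
  Sq by the Gaussian ratio Sq/Sa = √(π/2). Between-specimen variation
  runs through this single abrasiveness factor only.

**What this does and does not show.** The generator reproduces the
direction and magnitude of the group contrasts in the height/volume
families, so it exercises the full pipeline at realistic effect sizes:
the extreme pair (rainforest vs village) is consensus-significant for Sa
in ≈ 92 % of simulated studies, and the near-identical n = 3 pair in
≈ 6 % — the power structure of the real design. It does **not** reproduce
two things. First, with only n = 3 in the intermediate groups and the
observed between-specimen spreads, the *full* group-mean ordering
village > manioc/spiny > rainforest appears in only ≈ 25–30 % of studies
(the probability that a village mean of 0.269 ± 0.060/√19 exceeds a
manioc mean of 0.238 ± 0.109/√3 is only ≈ 0.68 by itself) — an ordering
observed once in a single real dataset is simply not a ≥ 95 % event under
resampling at these sizes. Second, because a single factor drives all
families, far more than nine parameters co-separate in simulation than in
real data, where striation anisotropy and feature structure decorrelate
the families; the generator is isotropic and makes no attempt at
striation/pit geometry or instrument noise.

## Reproducibility

Everything random is a pure function of an integer seed
(`numpy.random.default_rng` / `SeedSequence`); identical configs give
byte-identical CSV outputs. The acceptance script
(`scripts/acceptance.py --seed S --out f.json`) recomputes the fixture
closed forms, the omnibus degrees of freedom, the type-I rate (2000
replicates), the ordering/consensus rates (200 simulated studies at the
full 256×256 default grid) and one full 37-specimen study; it runs in
about 4 minutes on one CPU. Test-suite studies use 48×48 grids where only
structural properties (counts, determinism, dropout) are at stake.
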