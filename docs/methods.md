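# Methods

## Measurement model

A scene of `n = p·q` pixels, flattened row-major to `x`, is measured
through binary encoding patterns drawn from a cyclic S-matrix `S` of order
`n`. One bucket signal is the optical inner product

    y_u = Σ_v S[u, v] · x_v ,

and the full signal vector is `y = S x`. Because `S` is cyclic
(`S[i, j] = S[0, (i+j) mod n]`), the matrix-vector product is a 2D cyclic
correlation of the scene with the base pattern: shifting the measurement
row by 1 (or `q`) in linear index shifts the base pattern by one pixel
horizontally (or vertically), so adjacent signals come from almost
identical patterns and the signal vector is smooth when reshaped row-major
onto the `p × q` grid. That smoothness is the entire basis of the
compressed scheme.

### Twin-prime construction

For twin primes `p` and `q = p + 2`, the generating row is built from the
quadratic-residue indicator functions

    f(j) = +1 if j is a QR (mod p), 0 if j ≡ 0 (mod p), −1 otherwise
    g(j) = +1 if j is a QR (mod q), 0 if j ≡ 0 (mod q), −1 otherwise
    S[0, j] = 0  iff  (f(j) − g(j))·g(j) = 0,  else 1.

The residue test is exhaustive squaring over Z_p — the orders involved are
at most a few thousand, so nothing faster is warranted. `validate_smatrix`
machine-checks the defining invariants (cyclicity, row/column weight
`(n+1)/2`, Gram structure `S·Sᵀ = ((n+1)/4)(I + J)`); the construction is
accepted only because those checks pass for every supported order, not by
assumption. The inverse is applied in closed form,
`x̃ = 2/(n+1)·(2 Sᵀ ỹ − sum(ỹ))`, which costs one O(n²) product and avoids
explicit inversion; an exact integer-arithmetic variant
(`S @ (2Sᵀ − J) = ((n+1)/2)·I`) backs the rational identity checks in the
tests.

## Diagonal compressed scan

The measured rows are `u_k = (q+1)·k mod n`, `k = 0 … m−1` — the linear
index of a `(k, k)` diagonal position in the 2D-reshaped signal array.
For every twin-prime pair with `p > 3`, `gcd(q+1, pq) = 1`, so the rows
are distinct for any `m ≤ n`. The exception is `(p, q) = (3, 5)`:
`gcd(6, 15) = 3`, and the order-15 diagonal scan revisits rows after five
steps. The scan-row generator keeps the formula for any `m` (a physical
stripe with repeated patterns is well defined); distinctness is enforced
where it matters, at interpolation time.

`m = 91` at order 143 is the bench operating point carried as the package
default.

## Laplace interpolation

Unmeasured signals are filled by requiring the discrete harmonic condition

    y_u = ¼ (y_{u+1} + y_{u−1} + y_{u+q} + y_{u−q})

at every unmeasured index, with neighbor indices reduced modulo `n` on the
*linear* index — so `u+1` at a row end wraps into the next row and
`n−1` wraps to 0. This follows the modular index convention of the cyclic
measurement throughout; smoothness in linear index is exactly the
circular-shift similarity of adjacent measurement rows, including at the
wrap.

Unknowns may neighbor unknowns, so the conditions form a coupled sparse
linear system (one row per unmeasured site), solved directly with a sparse
LU factorization. The system matrix is an M-matrix on a connected modular
neighbor graph, hence uniquely solvable whenever at least one signal was
measured, and the solution obeys the discrete maximum principle
(interpolated values stay inside the measured range — asserted as a
property test). A Gauss–Seidel sweep (tolerance 1e−10) exists in the code
base solely as an independent test oracle for the direct solve; it is
never the production path.

## Radiometry

Intensity follows the total-radiance model `x̃ = C·ε·σ·T_s⁴ + Δ` with
emissivity ε = 0.98 (valid for both the calibration blackbody and human
skin in the LWIR band) and σ = 5.67×10⁻⁸ W m⁻² K⁻⁴. All internal
temperatures are kelvin; Celsius appears only at interfaces
(37.0 °C ↔ 310.15 K). Wavelength-band integration of Planck's law,
atmospheric transmission and reflected-temperature compensation are out of
scope: the model is deliberately the T⁴ one.

Calibration is a per-pixel ordinary least squares of intensity against
`ε·σ·T_s⁴` over a sweep of preset temperatures — by default 31.7 °C to
39.8 °C in 0.9 °C steps with five replicate frames per level (10 levels ×
5 × 143 pixels = 715 per-pixel samples per level). The fit is vectorized
as one shared design matrix against all pixels.

The temperature map subtracts the fitted offset before the fourth root:

    T_m = ((x̃ − Δ) / (C·ε·σ))^{1/4}.

This is the algebraic inverse of the calibration model; a variant that
omits Δ would bias every reading whenever Δ ≠ 0. Pixels with a
non-positive radicand (or non-positive fitted gain) are masked invalid
rather than raised.

An important consequence of linearity: when calibration frames are taken
*through* the compressed chain, the per-pixel fit absorbs the (linear)
interpolation-plus-reconstruction operator. The fitted `C, Δ` then differ
from the generator's ground truth, but the fit residual is zero and
temperatures recovered through the same chain are exact — which is exactly
how a real instrument self-calibrates. Ground-truth parameter recovery is
exact when frames come from the uncompressed chain or from the model
directly.

Temperature resolution has no standard formula; this package reports two
clearly-labeled definitions: the smallest preset step at which the
interquartile boxes of adjacent levels are disjoint, and the RMS error of
recovered samples about their preset levels.

## Synthetic scenes

The phantom generator reproduces the bench targets: uniform blackbody
fields, engraved dot-matrix letters (5×7 glyphs; "X" is 180°-symmetric as
the physical plate was), a slit of configurable sub-pixel width at 0°,
90°, ±45°, a pair of inner-canthi-like Gaussian hot spots (one per window
region, skin-level background), and arbitrary two-level masks.

Sub-pixel rasterization is by area-weighted coverage: exact interval
overlap for axis-aligned features, 16×16 supersampling per pixel for
rotated slits (the supersampling residual is far below the 0.5 profile
threshold the resolution metric uses). Mixing of feature and background is
done in radiance space, so a half-covered pixel carries the area-weighted
radiance, not the area-weighted temperature.

What the phantoms do **not** emulate: optical PSF and diffraction,
detector nonlinearity and drift, emissivity varying per pixel, motion, or
anatomically realistic faces. Passing tests therefore demonstrate the
correctness of the coding/reconstruction/calibration mathematics under the
stated acquisition model, not end-to-end hardware performance.

## Simulation of acquisition

The chopper/lock-in chain is modeled as a scalar gain plus i.i.d. Gaussian
noise added to the bucket signals — the lock-in output is a single scalar
per mask position, so waveform-level simulation would add nothing to the
quantities studied here. Each scan record carries its own seeded generator
state for exact replay; the pipeline derives per-stage substream seeds
from the run seed, so a run is byte-reproducible.

## Metrics

Sampling uniformity: for each unsampled linear index, the distance on the
`p × q` torus (row-major reshape, both axes wrap — matching the modular
neighbor structure) to the nearest sampled index. The metric is Chebyshev
by default with Euclidean and Manhattan selectable; the diagonal-vs-linear
ordering that motivates the diagonal scan holds under all three, and the
tests assert it under all three rather than privileging one.

Spatial resolution: the mean intensity profile along lines parallel to the
slit (columns at 0°, rows at 90°, grid diagonals at ±45°), min-max
normalized, counting pixels above 0.5. A half-pixel slit through the
noiseless uncompressed chain measures 1 pixel at all four orientations —
the resolution is set by the finite encoding-pixel size.

## Numerical and design choices

- Matrices are dense int64; exact checks use integer arithmetic, runtime
  math float64.
- The interpolation system is solved exactly; no tolerance enters the
  production path.
- Splitting a pattern into the 11×7 / 11×6 window parts applies
  configurable per-part flips (default: none); the ±45° physical rotation
  of windows and stripes is display/export metadata only, since scanning a
  45°-mounted stripe vertically is equivalent to the diagonal pattern
  shift in unrotated logical coordinates.
- Run-way L-markers and alignment pixels on the fabricated stripe are
  configurable metadata (default L size 3×3) excluded from the measurement
  matrix; they affect fabrication export only.
- Physical defaults: 250 µm encoding pixels, 4:1 magnification (1 mm
  object-plane sampling per pixel), 7.5 mm stripe separation (30 mm
  between the two object-plane regions).

## Known limitations

- At `m = 91`, image features oriented parallel to the sampling diagonal
  of the bucket array (the −45° direction in this package's conventions)
  interact worst with the unsampled lanes: a noiseless half-pixel slit at
  −45° through the compressed chain shows interpolation artifacts that
  cross the 0.5 profile threshold (profile count 2–3 instead of 1). The
  one-pixel resolution statement is a property of the encoding-pixel size
  and is measured on the uncompressed chain; compressed-chain anisotropy
  is a real cost of the compression.
- The interquartile-box resolution estimate needs enough replicates per
  level for stable quartiles; with the default five replicates per level
  it is a coarse statistic.
- The `(3, 5)` twin-prime pair supports at most five distinct diagonal
  scan rows (see above); it is useful for exhaustive unit tests, not as an
  operating point.
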