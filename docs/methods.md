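# Methods

## Acquisition model

The scanner is parallel-beam: at rotation angle φ_k = k·Δφ (k = 0 … K−1,
Δφ = π/K by default so the sample turns through a half revolution), sensor j
of width d integrates the absorption coefficient over the strip

    D_{k,j} = { (x, y) : −Jd/2 + j·d ≤ x cos φ_k + y sin φ_k < −Jd/2 + (j+1)·d },

so a sinogram entry is ξ_{k,j} = ∫_{D_{k,j}} f + ν_{k,j}.  Strips are
contiguous (pitch = width); the image is an N×N pixel grid (pixel size 1,
origin at the grid centre, x right, y up), and rotating the sample by φ is
realised as rotating the strip frame by −φ.  The object is assumed supported
in the disc Ω of radius N/2 (covered by the sensor span at every angle; a
narrower span triggers a warning).

**Discretization.** Pixel/strip intersection areas are estimated by
supersampling with n_subpixel² samples per pixel (default 4×4, configurable).
At any fixed angle the strips tile the plane, so the estimated weights
satisfy the partition of unity exactly for pixels inside the sensor span.
An exact polygon-clipping computation (shapely) is kept in the test suite as
an independent oracle; the supersampled weights agree with it to the sampling
tolerance (~1/(2·n_subpixel) per pixel in the worst case).  Per-angle weight
matrices are assembled sparsely on demand and memoized with a bounded cache;
the full K·J × N² operator is only materialised below a configurable entry
cap, as a test oracle and for the dense reduction path.

**Adjoint convention.** `adjoint_project` is the exact transpose of
`forward_project`, and unfiltered backprojection is defined as that
transpose.  In the continuous theory backprojection and the adjoint differ by
a constant (2π under common normalizations) plus discretization effects of
interpolation-based implementations; the exact-transpose convention removes
the discrepancy, so here the factor is exactly 1 and no rotation-based
backprojection is provided.  Reconstruction scale for unfiltered
backprojection remains arbitrary, which is why quality reports optionally
apply a least-squares scalar fit.

## Backprojection baselines

The ramp filter is applied per angle along the sensor axis as a circular
convolution: the frequency response is the DFT of the band-limited discrete
ramp sequence h[0] = 1/4, h[n] = −1/(πn)² for odd n, zero for even n, with
the DC bin forced to exactly zero.  The infinite sequence sums to zero;
circular truncation otherwise leaves a small positive DC residual, and
zeroing it makes a constant row filter to an exactly zero row.  Circular
wrap-around is harmless because the object's shadow stays inside the sensor
span.  No apodization window is applied.

## Linear measurement reduction (dense path)

For ξ = A f + ν with diagonal noise covariance and ideal transducer U
(identity by default), the minimax-MSE linear estimator and its error are

    R* = U (Σ_ν^{-1/2} A)⁻ Σ_ν^{-1/2},
    h(R*) = tr U (A* Σ_ν^{-1} A)⁻ U*,   Σ_{R*ξ} = U (A* Σ_ν^{-1} A)⁻ U*,

valid when the reducibility condition U(I − A⁻A) = 0 holds; its Frobenius
defect is reported so callers can see how much of U-space is unobservable.
Pseudoinverses are SVD-based with relative cutoff 1e−10.  The regularized
family is R_ω = U A\*(A A\* + ω Σ_ν)^{-1}; given a noise-energy budget ε the
multiplier is found by bracketed root-finding on log ω (the energy
‖R Σ_ν^{1/2}‖² is strictly decreasing in ω), and a budget at or above the
optimum's own noise energy (= h(R\*)) returns R\* unchanged.

**Non-negative fixed point.**  The estimate û is refined by stacking the real
measurement with a dummy observation of û itself — operator [A; U], noise
covariance diag(Σ_ν, Σ_{R\*ξ}) — reducing optimally, and projecting onto F₊
(Euclidean projection; a Mahalanobis variant converges faster but needs a
nontrivial projection and is out of scope).  Iteration starts from
max(R\*ξ, 0) and stops when successive iterates differ by less than `tol`
(default 1e−10) or after `max_iter`; non-convergence is reported with the
last iterate rather than raised.  A singular Σ_{R\*ξ} (rank-deficient A) is
handled by a pseudo inverse square root.  Everything here is dense and
capped at 2000 rows/columns; the local and iterative methods exist precisely
to avoid this path at sinogram scale.

## Local PSF-mask method

The unfiltered backprojection η of a sinogram is modeled as a
translation-invariant blur of the object, η = b ∗ f + μ, with b the
(2M+1)×(2M+1) window of the point response of acquisition followed by
backprojection, estimated by simulating a unit point at the central pixel
with the same sensors and angles.  The correction mask r solves the windowed
unbiasedness system (r ∗ b)(t) = δ_t for |t| ≤ M with out-of-window b taken
as zero.  The system is posed in the same (convolution) orientation in which
the mask is later applied — the two printed forms of the unbiasedness
condition in the source literature differ by a flip that only matters for
asymmetric PSFs.  If the system is numerically singular (condition number
above 1e12) the exact mode refuses and advises the regularized mode, which
minimizes the unbiasedness residual subject to the noise-amplification
budget σ_img²·Σr² ≤ ε via a ridge multiplier found by root-finding.  σ_img
defaults to the standard deviation of η outside Ω.  Masking is applied with
zero-padded boundaries (the object lives inside Ω, away from borders).

**Non-negativity refinement.** A pixel estimated negative is treated as an
exact additional measurement of zero brightness.  The best linear update of
each neighbour within the window is c_{k,l}·(0 − f̂) where
c_{k,l} = Σ r_{i−k,j−l} r_{i,j} / Σ r² is the mask autocorrelation
(c_{0,0} = 1, so the triggering pixel lands exactly at zero), and each
neighbour's variance shrinks by the factor 1 − c², never increasing.  The
default is a **single raster sweep** followed by clipping: the update is
optimal for the original estimate covariance, and reapplying it without
downdating that covariance over-corrects — when negative pixels are dense
(see the background limitation below) iterated sweeps are empirically an
expansive map whose negatives grow pass over pass rather than a contraction
to a fixed point.  A pass cap is exposed (`max_passes`) for sparse-negative
inputs, where repeated sweeps converge in one or two passes.

**Validity domain.** The point response of unfiltered backprojection has a
~1/r halo far outside any practical window; the windowed mask cannot cancel
it, and the row sum of the mask is forced to ≈ 1/Σb_window ≠ 0, so the
masked estimate carries a residual smooth background proportional to the
object's total absorbance.  The method therefore assumes a compact object
whose total mass is small against the windowed PSF mass.  Within that domain
it restores resolution that backprojection loses; outside it the background
dominates.  Larger windows fit more of the blur (the deconvolution residual
against the full point response decreases with M) at a higher noise
amplification and cost — M = 2 is the working default.

## Projected iterative reduction

All iterative solvers start from the zero image, act matrix-free through the
per-angle sparse strips, and project onto F₊ so returned images have
minimum ≥ 0 exactly.

* **Basic Kaczmarz** — one raveled measurement row per iteration (angle-major
  ordering; golden ordering permutes the angles), update
  f ← Π₊(f + λ (ξ_i − ⟨a_i, f⟩)/‖a_i‖² a_i).  The relaxation λ must satisfy
  0 < λ < 2: a single-row update scales the distance to the row's hyperplane
  by |1 − λ|, so λ ≥ 2 stops contracting and is flagged with a warning.
  Zero-norm rows are skipped.  N_iter counts row updates (default K·J, one
  use of every measurement).
* **Improved (per-angle simultaneous) Kaczmarz** — one angle per outer
  iteration: every sensor's correction is computed against the same current
  estimate and their sum applied at once (strips at one angle do not
  overlap), then projected.  Angles are visited in golden-ratio order:
  stride round(K/φ_golden) adjusted to the nearest integer coprime with K,
  a deterministic sequence that keeps consecutive angles maximally spread.
  N_iter counts angle visits (default K).  Defaults λ = 0.5, half the onset
  of instability.
* **Landweber / projected gradient descent** — f ← Π₊(f − λ A\*(A f − ξ)),
  stable for λ < 2/‖A‖² with ‖A‖ from deterministic power iteration on A\*A
  (all-ones start, relative tolerance 1e−6, 200-iteration cap); the default
  λ = 1/‖A‖² is half the maximum and makes the unprojected residual
  non-increasing.  Steps at or above the bound are rejected.
* **SART baseline** — per-angle corrections normalized by the angle's ray
  sums and pixel sums, clipped once per outer (angle) iteration.

Whitening is the caller's responsibility for non-white noise (`whiten`
rescales the sinogram and provides the row scales).  Iteration traces record
the full data residual ‖A f − ξ‖ and the pre-projection negative-pixel
count; because one residual evaluation costs a full forward projection, the
recording interval is configurable (`trace_every`) and defaults to every
angle-level iteration but once per J row updates for the basic solver.

## Synthetic benchmark

The benchmark emulates a laboratory micro-CT acquisition of a compact test
object: a 100×100 image scanned at 100 angles × 100 sensors, white Gaussian
noise with σ = 1% of the peak sinogram value, drawn from a counter-based
(Philox) generator so a seed reproduces the sinogram bit-for-bit.  The
default phantom is three nested/offset discs of brightness 1.0, 0.5 and 1.5
with radii of 1–2 pixels.  The composition is deliberately compact and
fine-scaled: it stays inside the local method's validity domain (small total
absorbance, see above) and probes resolution, which is what separates the
methods — large uniform blobs mostly probe the arbitrary overall scale of
backprojection.  Elements are rasterized with the same supersampling density
as the strip weights and masked to Ω; specifying an element that reaches
outside Ω is an error.

What the generator does **not** emulate: beam hardening, scatter, detector
sensitivity variation, positioning errors, fan/cone-beam geometry, or
correlated noise.  Passing tests therefore demonstrate algorithmic
correctness under the stated model, not robustness to the systematic errors
of real scanners (which published experience suggests can rival the noise in
magnitude).

Quality is summarized as RMSE over Ω (optionally after a least-squares
scalar fit, needed for the arbitrarily scaled backprojection), the fraction
of strictly negative pixels, and the max−min contrast.

## Numerical choices and degenerate inputs

* SVD pseudoinverse cutoff 1e−10 relative throughout the dense path.
* Root-finding for ε-budgets: Brent's method on log-multiplier, bracket
  expanded geometrically; relative tolerance 1e−8.
* Whitening and reduction reject non-positive noise variances explicitly.
* Zero-norm projection rows are skipped silently in iterative solvers.
* The refinement tolerance for "negative" is −1e−12 to avoid chasing
  rounding noise; final clipping guarantees exact non-negativity.
* Geometry hashes are used to memoize per-angle strip matrices (bounded LRU,
  256 angles); two equal geometries share the cache.

## Known limitations

* The local method's background term for massive objects (above): a global
  deconvolution, not a windowed one, would remove it but defeats the
  method's O(M⁶ + image) cost advantage.
* The dense reduction path is capped at small instances by design.
* The PSF is assumed translation-invariant; in truth the blur varies mildly
  with position (and the centre pixel of an even-sided image sits half a
  pixel off the rotation axis), which the window tolerates but does not
  model.
* Recurrent (covariance-propagating) reduction updates and Mahalanobis
  projections are not implemented.
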