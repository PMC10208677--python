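# Methods

## Scope and verification strategy

The package reconstructs the computational half of a light-paced
muscular-thin-film (MTF) experiment.  No raw videos of such an experiment
are bundled; instead every inverse pipeline is paired with a forward model
(`photopace.synthetic`) that generates movies, orientation samples and
stimulus trains from known parameters.  A pipeline is accepted when it
recovers the planted parameters at the assay's working tolerances.  Passing
these tests demonstrates correctness of the *computations* under the stated
generative assumptions; it does not validate the assumptions against real
microscope data (see Limitations).

## Cantilever mechanics

**Bending model.**  The film is treated as a circular arc of uniform
curvature κ, tangent to the substrate at its fixed base.  A camera above
sees the horizontal projection x(κ) = L·sin(κL)/(κL).  Uniform curvature is
the standard MTF assumption for a uniformly contracting monolayer; the
analysis is restricted to κL ∈ [0, π), where x(κ) is strictly decreasing
and the inversion single-valued.  The renderer refuses to draw over-curled
films rather than silently aliasing them.

**Inversion.**  x → κ solves sin θ/θ = x/L on (0, π) by Brent's method to
|Δθ| < 1e−12.  Conditioning degrades as θ → 0 because d(x/L)/dθ = O(θ);
below θ ≈ 1e−3 (x within a fraction of a nanometre of L — far below a
pixel) the round trip is limited by floating point, which is irrelevant at
any realistic image resolution.  Projections exceeding L by at most one
pixel are attributed to rasterization and clipped; larger excesses abort.

**Stoney relation.**  σ = C·E_s·h_s²·κ/(6·h_f·(1−ν_s)).  The correction
factor C multiplies the classical thin-film expression so a finite
film/substrate thickness-ratio correction can be supplied without code
changes; C = 1 by default.  ν_s = 0.5 (incompressible gel) is allowed — the
denominator uses (1 − ν_s) = 0.5, not (1 − ν_s²).

**Default mechanics.**  E_s = 15 kPa, h_s = 100 µm, h_f = 5 µm, ν_s = 0.5,
L = 3 mm, width 4 mm, all config-overridable.  These are representative of
micro-molded gelatin substrates carrying a cardiomyocyte monolayer and were
chosen so the 1–6.4 kPa stress range of the fixtures maps to κL ≈ 0.1–1.9,
comfortably inside the injective band while bending enough that a 1/500-L
pixel resolves the diastolic curvature.  Of the two cut sides (3 × 4 mm),
the 3 mm side is taken as the free length.

**Twitch detection.**  Peaks need prominence ≥ 20% of the trace's dynamic
range (robust to the ~2% mask noise of the fixtures).  Per beat the
baseline is the 5th percentile of the preceding inter-peak segment — robust
to drift and to incomplete relaxation.  Frequency is the reciprocal
*median* inter-peak interval: one missed or spurious beat moves the median
by at most one rank, where a spectral estimate would need a window/taper
choice and a mean would be biased.  Fewer than two peaks ⇒ frequency 0;
a flat trace is a quiescent film, not an error.

**Comparisons.**  Welch's t is the default (the assay's group sizes are
unequal, e.g. 40 vs 11 cantilevers); `variant="student"` gives the
pooled-variance test.  Zero-variance degenerate inputs follow the t = 0 /
p = 1 (equal) and |t| = ∞ / p = 0 (distinct) conventions, flagged.  Stars:
* p < 0.05, ** p < 0.01, *** p < 0.001, strict inequalities.

## Synthetic cantilever movies

The stress pulse is a half-cosine rise over `upstroke_fraction` of the beat
period (default 0.2) followed by a half-cosine decay over twice that, then
flat diastole.  Compact support makes the planted diastolic, systolic and
twitch values exact — recovery error is then attributable entirely to
rasterization and inversion, which the tests bound at < 2% RMS for
pixel ≤ L/500.  Movies are binary silhouettes (the analysis never uses
grayscale structure of the film interior); Gaussian intensity noise is
added and re-binarized at 0.5, matching a thresholding camera pipeline.
Fixtures use 30 s at 100 fps, noise SD 2% of the mask amplitude.

## Optical mapping

**Generative model.**  Activation fields are distance-from-source divided
by speed: a whole image edge (planar wave) or an interior pixel (radial
wave, i.e. two counter-propagating fronts along the long axis).  The
fluorescence transient is a linear rise (20 ms) to F0 + ΔF followed by
exponential decay (τ = 200 ms), repeated at the 1 Hz pacing period, plus
i.i.d. Gaussian noise.  Real calcium transients have more structure
(sigmoidal foot, Ca-dependent decay); none of it matters to the activation
*time*, which is all the inverse pipeline uses.  Standard fixtures: 24 × 50
pixels at 100 µm/pixel, 400 fps, 3 beats, noise SD 5% of ΔF.

**Pipeline order** is filter → ΔF/F → segment → activation → velocity.
The 3×3 uniform filter uses reflected borders; ΔF/F takes the per-pixel
10th percentile as F0 (≥ 60% of each trace is quiescent at these duty
cycles, so the percentile sits on the baseline).  Beat windows come from
peaks of the field-mean trace, snapped to one stimulus period when the
pacing frequency is known.

**Activation marker.**  Default is the first 50% -of-amplitude upward
crossing with linear inter-frame interpolation (sub-frame resolution); the
maximum of the centered first difference is available as an alternative and
resolves only to ±1 frame on step-like upstrokes.  Pixels with in-window
amplitude below 20% of the frame-wide median amplitude are invalid.

**Velocity.**  v = g/|g|² with g = ∇T by central differences (one-sided at
valid-region borders): speed = 1/|∇T|, direction along propagation.  The
componentwise alternative (1/g_x, 1/g_y) was rejected — it diverges for
fronts aligned with an axis.  Gradient bounds suppress plateau and
stationary pixels: speeds outside [1 mm/s, 2 m/s] (g below half of 1/v_max
or above 1/v_min) are invalidated; both bounds are arguments.  The
per-movie figure is the median speed over pixels within each beat, averaged
across beats — the median resists the residual bias near a point source,
where discrete radial gradients underestimate |∇T|.

**Wavefront counting.**  Per-column minimum of T over valid rows, smoothed
with a 5-column moving average; strict local minima (merged within
2 columns) are origins.  A single boundary minimum ⇒ edge wave (1 front);
a single interior minimum ⇒ point-source double wave (2 fronts); more ⇒
multiple sources.

## Orientation statistics

Axial angles are handled by doubling: 2θ on the circle, halve at the end.
`fit_nucleus_orientations` uses second-order central moments per label
(x = columns, y = −rows, so angles are counter-clockwise from the
horizontal); near-circular nuclei (moment-eigenvalue gap < 1e−6 of the
trace) have no axis and are excluded with a warning.  The sampler draws 2θ
from a von Mises law; `concentration_for_sem` inverts R(κ) = I₁/I₀ so a
target circular s.e.m. can be planted (0.75° at n = 130 ⇒ κ ≈ 11.7).  The
circular s.e.m. is √(−2 ln r₂)/2/√n (the factor ½ undoes the doubling);
200-replicate recovery puts ±2 s.e.m. coverage at ~94%, consistent with the
nominal 95%.  The nematic order parameter S = 2⟨cos²Δθ⟩ − 1 (= r₂ when Δθ
is taken from the sample mean) is reported for comparison with the MTF
literature but drives no decision.

## Protocol accounting and power

Pulse width = duty/frequency exactly; onsets at k/frequency for complete
periods only.  The schedule validator enforces that recording blocks carry
no light (recording during illumination would be optically contaminated).
ROS values are background-corrected and divided by the Hoechst-positive
nucleus count; negative corrected values are flagged, not rejected.

The power driver simulates the 0.78 vs 0.31 Hz comparison at 40 vs 11
cantilevers with per-cantilever SD = s.e.m.·√N (0.70 / 0.33 Hz).  The Welch
noncentrality is 0.47/√(0.11² + 0.10²) ≈ 3.2 at ≈ 35 df, giving ~86% power
— adequate for a single experiment but notably short of 95%; the pooled
Student variant is markedly worse (~59%) because the larger group carries
the larger variance.

## Problem sizes and determinism

Standard fixtures are 3000-frame (30 s, 100 fps) cantilever movies at
~512 × 24 pixels and 1200-frame (3 s, 400 fps) calcium movies at 24 × 50 —
small enough that the full suite and the acceptance script run in minutes
on one core while keeping ≥ 9 beats per contractility fixture and ≥ 40
pixels along the propagation axis.  Every stochastic operation takes an
explicit seed (NumPy `default_rng`); the acceptance script derives
per-target child seeds from its single `--seed` via `SeedSequence`.

## Limitations

- Ground-truth stress and activation fields are prescribed, not emergent:
  there is no excitation–contraction coupling, membrane model, or
  photostimulus transduction physics.
- The renderer draws clean silhouettes; real movies add illumination
  gradients, debris, meniscus shadows and motion blur that the Otsu +
  largest-component front end may or may not survive.
- Curvature is assumed uniform along the film; regionally heterogeneous
  contraction violates the arc model and biases σ toward the tip-dominated
  value.
- The velocity estimator assumes a locally smooth activation surface;
  colliding wavefronts produce gradient discontinuities that are masked,
  not modeled.
- Nuclei segmentation from raw DAPI images is out of scope: the input
  contract is a labeled mask or an angle table.
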