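# Methods

## Signal model and what the simulator emulates

The observed single frame is modelled as the original scene modulated
multiplicatively by motion: a dark object of reflectance 0 on a white
background of reflectance 1, moved during one exposure of length `T` along

```
r(t) = (A·cos ωt,  A·sin ωt) − v_pix·t·(cos φ, sin φ),      v_pix = v · pixels_per_meter
```

i.e. a circular oscillation (amplitude `A`, angular frequency `ω`)
superimposed on a linear drift at velocity `v` along orientation `φ`.  The
renderer integrates occlusion over the exposure: each pixel's intensity is
one minus the fraction of time the object's disk covers it, discretised by a
Riemann sum with step `s` (nearest-integer sample placement, then disk
convolution; an optional gaussian PSF smooths the result).  A binary "swept
silhouette" rendering was rejected: it admits no internal intensity
structure, and without structure a self-similarity profile has no secondary
peak at any prominence — the time integral is what produces the artifact.

The trajectory's speed, `|r'(t)|² = A²ω² + v_pix² + 2Aω·v_pix·sin(ωt−φ)`,
has one minimum per oscillation cycle.  At each minimum the object dwells and
deposits extra exposure, so the frame contains a chain of darker *replicas*
spaced `Δ = v_pix·2π/ω` pixels apart along the motion axis.  These periodic
replicas are the movement artifact that the estimation stage detects; their
spacing grows linearly with velocity, which is what makes the estimated
magnitude velocity-sensitive.

**Coordinate convention** (shared by simulator and estimator, stamped into
every output): x = column index increasing rightward, y = row index
increasing downward, angles clockwise on screen, so φ = 90° points down-rows.
Under this convention the 45° scanline family collects pixels with constant
j−i and the 135° family pixels with constant i+j.

## Default study conditions and why

| parameter | default | unit | rationale |
|---|---|---|---|
| frame / crop side | 256 / 224 | px | fixed analysis surface |
| `pixels_per_meter` | 125 | px/m | v = 0.2 m/s ⇒ 25 px trail in a 256 px frame |
| `T`, `s` | 1.0, 1e-3 | s | 1000 trajectory samples per exposure |
| `A` | 2.0 | px | oscillation visible but subordinate to drift |
| `ω` | 7π | rad/s | 3.5 cycles/exposure ⇒ replica spacing Δ = 2/7 of the drift |
| object radius | 1.1 | px | see the resolvability window below |
| PSF | gaussian, σ = 0.45 | px | mild optical smoothing |

The replica chain is only informative inside a geometric window.  Writing
`D ≈ 2·radius + 2σ` for the effective replica diameter: replicas must be
*resolvable* along the motion axis (`Δ > D`, else consecutive replicas merge
into a featureless band) and *visible* to the neighbouring scanline families
(a family at angular offset ψ only sees replica pairs on a common scanline
while `Δ·sin ψ ≲ D`).  With the defaults, trails of 20–40 px give
Δ ≈ 5.7–11.4 px against D ≈ 3.1 px: resolvable at the short end and still
visible to the ±15–30° families at the long end.  A large object (radius
comparable to Δ) pushes the method out of its regime — exactly the
high-velocity/large-blur ambiguity the estimator is expected to show.  The
object is therefore deliberately compact; the method's own assumption is that
the artifact displacement exceeds the object's spatial extent.

## Estimation pipeline

**Centre crop.** The dark object's intensity-weighted centroid is translated
to the centre of a 224 px square window (white padding).  The object
threshold adapts to the frame's contrast range (midpoint between background
and darkest pixel) because exposure-averaged smears of fast objects never
reach black; a frame whose contrast range is below 0.02 raises
"no object detected".

**Directional matrices.** Horizontal scanlines are the image rows; vertical
ones the rows of the 90°-rotated image; the two diagonal families collect
constant-(j−i) and constant-(i+j) pixel runs, keep only diagonals at least
half the crop side long, centre-align them and pad with the row's own edge
value (padding with zeros would inject artificial steps into the edge
detector).  Each row is z-scored with the population standard deviation; rows
with spread below 1e-12 are emitted as zeros and flagged invalid.

**MAPE.** The self-similarity profile is the zero-padded autocorrelation
normalised by the zero-lag energy, so r[0] = 1, |r| ≤ 1 and r[l] = r[−l]
exactly.  (Normalising instead by the lag-dependent overlap energy would
break the symmetry that the complement set relies on.)  Peaks are accepted at
prominence ≥ `min_prominence`·r[0] (default 0.1); the second peak is the most
prominent nonzero lag, ties resolved toward the smaller |lag| and then the
positive sign — the complement set restores the mirrored candidate in any
case.

**ROPE.** EMA smoothing (`alpha` = 0.3) followed by first differences; the
origin is the argmax of |slope| (ties to the smallest index, the slope
indexed at its left endpoint).  Retention uses `|v̂ᵢ| ≥ τ_rope · maxᵢ|v̂ᵢ|`
(default 0.3); the comparison is ≥ so that at τ = 1 the rows achieving the
global maximum are retained rather than none.

**MAQ.** Detected lags are anchored at the scanline's own origin
(candidates ĝ ± lag), the candidate closer to the origin wins (ties toward
ĝ−p), and |q| > `tau_maq` (default: half the crop side) is suppressed as
implausible.  Suppressed and missing entries stay NaN; they are never
zero-filled.

**Directional statistics.** For each direction the magnitude statistic is

```
q̄_d = Σ (non-suppressed |q_i|) / K_d,     K_d = number of scanlines with a retained origin
```

so the mean is weighted by the detection fraction: a direction detecting a
displacement on 2 of 30 candidate scanlines carries proportionally less
weight than one detecting on 16.  This is essential for the vote —
with a plain mean over detections only, a single spurious scanline in a
misaligned direction outweighs a consistent aligned direction and can swing
θ by tens of degrees.  The dispersion σ_d is the population standard
deviation of the detected |q_i| (the consistency that the reliability swap
ranks); it is boosted by `beta` (default 1) and then the four boosted values
are permuted so the smallest dispersion receives the largest value (min↔max,
middles exchanged).  A direction with no detections gets q̄ = 0 and a
dispersion sentinel just above the largest real one: the sentinel must rank
last, but because the swap permutes *values* onto other directions, an
inflated sentinel would reappear as the z-coordinate of the most reliable
vertex and contaminate the magnitude readout.

**Octagon, triplet, readout.** The eight 3-D points place ±q̄ along each
family's axis with the reliability as z; diagonal vertices sit at (±q̄, ±q̄)
— a 2-D radius of q̄·√2 — which converts the diagonal families' lag units
(√2 px per index step) back to pixels.  All eight circularly adjacent
triplets are scored by summed distance from the origin (ties to the smallest
start index); θ is the four-quadrant angle of the winning triplet's centre
of mass, θ′ = θ+180° its complement.  The magnitude q is the 3-D distance
from the origin to the point where the θ-ray crosses the boundary edge of
θ's 45° segment, solved as a 2×2 parametric system with the edge midpoint as
fallback when |det| < 1e-10 and the edge parameter clamped to [0, 1].

## Numerical choices and degenerate inputs

- Blank frame → "no object detected"; frame with an object but no detected
  displacement in any direction (e.g. at rest) → "no artifact signal".
- θ exactly at 360° wraps to boundary segment 1.
- A centre of mass at the exact origin is an error rather than an arbitrary
  angle.
- All floating-point output is written at 6 decimals with a stable field
  order, so repeated runs are byte-identical; the only randomness anywhere
  is the optional, explicitly seeded additive noise in the simulator.

## What passing tests do and do not show

The generator produces noise-free, single-object frames with an exactly
white background and an exactly known trajectory family.  Passing the
recovery and monotonicity checks therefore demonstrates the pipeline's
correctness in its intended regime, not robustness to sensor noise, texture,
illumination gradients, multiple objects or non-oscillatory motion — on such
data the ROPE threshold and the prominence criterion would face genuinely
harder discrimination problems, and the scanline-count normalisation would
dilute q̄ whenever background rows carry enough variance to pass the
validity mask.  The optional seeded gaussian noise hook exists for studying
that degradation but is off by default.

## Known limitations

- **Orientation class only.** Blur is bidirectional; θ and θ+180° cannot be
  distinguished from a single frame, so errors are assessed modulo 180°.
- **Axis-degenerate octagons.** When motion is exactly along one family's
  axis and the blur is long, the neighbouring families stop seeing replica
  pairs, their vertices collapse to the origin, and the θ-ray becomes
  collinear with its boundary edge — the midpoint fallback then halves q.
  The direction remains correct; the magnitude's monotonic growth in blur
  length is reliable at generic orientations but degrades near the principal
  axes at the long-trail end.
- **Magnitude scale.** q is the detection-fraction-weighted displacement, a
  monotone index of artifact strength rather than the raw replica spacing in
  pixels; the per-direction diagnostics expose the unweighted statistics.
- **Low-velocity blindness.** Below ≈0.12 m/s (15 px trail) the replica
  spacing drops under the replica diameter and detection fails — the method's
  documented lower operating bound, mirrored by the `performance_map` "safe
  zone".
- Four fixed scanline families bound the angular resolution of the vote;
  finer interpolation is traded for the 4-direction computational budget.
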