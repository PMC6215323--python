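# Methods

## The diffusion model of the chip

The chip cross-section perpendicular to the leaching-channel axis is modeled
as a 2D heterogeneous diffusion problem: a PDMS slab (default 24.6 mm wide,
2 mm tall) on glass, with the cell chamber (10 mm) and the leaching channel
(0.5 mm) moulded into the bottom 0.15 mm and separated by a 0.1 mm PDMS
wall, the chamber offset 4 mm from the chip side wall, and a 0.5 mm PMMA
barrier on top. Default diffusivities: PDMS 3·10⁻⁹ m²/s, culture medium
3.2·10⁻⁹ m²/s (water at 40 °C), PMMA 3.7·10⁻¹² m²/s. Boundary conditions:
21 % O₂ (Dirichlet) on the outer left/right/top surfaces exposed to air,
zero flux at the glass bottom, and 0 % O₂ throughout the scavenged leaching
channel. Concentrations are carried as %O₂ everywhere (the assay is
calibrated in %, so no conversion to molarity is ever needed); lengths are
mm and times hours at the interface, diffusivities being converted to
mm²/h internally.

Reducing the chip to its 2D cross-section assumes the geometry is uniform
along the channel axis, which holds away from the chamber's tapered
in/outlet regions; the PMMA access ports are likewise omitted. Deviations
near the chip edges are therefore expected (and are seen experimentally in
this kind of device).

### Discretisation and solvers

Cell-centred finite volumes on a uniform grid (default spacing 0.05 mm —
the coarsest grid that resolves the 0.1 mm separating wall with two cells;
`build_domain` rejects anything coarser). Interface conductances use the
harmonic mean of the two cell diffusivities, which conserves flux across
material boundaries and is nodally exact for 1D piecewise-constant
problems. Outer Dirichlet values and the channel sink are imposed at cell
faces (half-cell conductance of the interior cell's own material): the
scavenged liquid is at 0 % up to its boundary, so putting the condition at
the neighbouring cell centre would thicken the wall by half a cell and
bias the hypoxic end upward by ~0.2 %O₂.

The steady state is a single sparse direct solve; the residual of the
assembled system is checked afterwards against `tol` (default 10⁻⁸ of the
ambient scale) and a failure raises rather than returning a field. The
transient solver uses Crank–Nicolson with a default step of 60 s
(unconditionally stable, so the step is an accuracy choice; tests and the
bundled long runs use 120 s, which changes the reported timescales by less
than the output resolution). The first two steps are backward Euler
(Rannacher smoothing): a uniform initial condition is discontinuous
against the 0 % sink, and plain Crank–Nicolson barely damps the
grid-scale modes this excites — on the 1D slab benchmark the startup steps
reduce the error against the analytic series from ~8 % to below 0.01 %.

Both solvers are verified against closed forms: the two-material series
slab (piecewise-linear steady profile from the resistance formula, exact
to round-off), the homogeneous-slab transient series solution, and the
dominant-mode equilibration time τ₁ = L²/(π²D). The solution respects the
discrete maximum principle (all values within the imposed 0–21 % range)
and approaches the steady state monotonically in max norm.

### Predicted timescales, and a known discrepancy

With the stated geometry the model develops the gradient *shape* quickly —
the chamber-floor profile correlates > 0.99 with the steady profile at 4 h,
matching observation — and reaches the steady concentrations (1 %O₂
tolerance, max norm over the chamber floor) at ≈ 6 h. Experimentally this
class of device reaches its predicted concentrations only after ~17 h. The
gap is a limitation of the 2D reduction, not of the solver (which matches
the analytic oracles above): the cross-section's slowest mode decays with
τ₁ = W²/(π²·D_PDMS) ≈ 5.7 h, whereas the real chip equilibrates through
longer 3D paths — the 26 mm of chamber plus tapered in/outlet arms along
the channel axis, and the PMMA access ports — and the measured figure also
includes perfusion start-up. The corresponding acceptance test asserts the
10–24 h experimental window and is expected to fail on this model; it is
kept failing rather than loosened, as an honest record of what the 2D
model does and does not reproduce.

## Stern–Volmer oximetry

Fluorescence of an oxygen-quenched dye follows I₀/I = 1 + K_q·[O₂]. Images
are split into strips (default 10 px) perpendicular to the gradient axis;
a final partial strip at least half a strip wide is kept, anything shorter
is merged into its neighbour. Per strip, I₀ is the mean of the 0 % image
and K_q = (I₀/Ī₂₁ − 1)/c_ambient from the ambient image; strips without
actual quenching (Ī₂₁ ≥ I₀) are flagged invalid rather than fatal.
Inversion applies [O₂] = (I₀/Ī − 1)/K_q per strip. Because calibration and
measurement share strips, any per-strip illumination gain cancels exactly —
the reason calibration is done at the measurement location. Negative
recovered concentrations (noise at the hypoxic end) are reported as-is
with a warning; clipping would bias profile averages upward. No
photobleaching, temperature, or flat-field corrections are applied. Pixel
size is optional config; absent a known camera scale, profiles are
reported in pixels.

One systematic effect is worth noting: the strip statistic is the mean
*intensity*, and intensity is convex in [O₂], so where the field varies
within a strip the recovered value sits slightly below the strip-mean
oxygen (≈ 0.1 %O₂ for a 0–21 % linear field over 120 px at 10 px strips).
This mirrors what any strip-averaging instrument measures and is left
uncorrected.

## Track statistics

Tracks are time-stamped 2D positions (μm, minutes), at least two frames,
strictly increasing times. Per cell: FMI parallel/perpendicular = net
displacement projected on the gradient direction (and its 90° CCW
rotation) divided by total path length; mean velocity = path length /
elapsed time; per population: centre-of-mass displacement = mean final −
mean initial position, and a weighted angular histogram (default eight 45°
bins, edges at [k·45°, (k+1)·45°) counterclockwise from +x) where each
motile cell contributes weight dᵢ/mean(d), so weights sum to the number of
contributing cells. Cells with zero net displacement are excluded from the
histogram (and from mean(d)) but enter FMI averages; zero-path-length
cells have undefined FMI and propagate as missing with a warning.

Sign convention: the gradient frame's unit vector points toward *higher*
oxygen, so migration toward hypoxia shows up as negative FMI_parallel.
The convention is explicit and configurable (`GradientFrame.from_axis`).

Group comparison is a Kruskal–Wallis rank test with tie correction,
implemented directly so the degenerate all-identical-observations case can
return H = 0, p = 1 instead of erroring; it is cross-checked against
scipy's implementation on tied data and against full permutation
enumeration at small N (agreement with the exact mid-p to within the
permutation distribution's granularity, ~0.06 at N = 7). Both the omnibus
test across all four conditions and pairwise tests against a reference
condition are provided, without multiple-testing correction. Aggregation
supports both pooling all cells and averaging within replicate experiments
first; the two orders weight replicates differently and both are exposed.

`local_response` samples the oxygen profile (linear interpolation, or any
callable field) at each cell's un-offset starting position and tabulates
it against per-cell FMI and velocity; positions outside the profile
support are flagged missing.

## Synthetic data

The generator emulates the experiment's sampling design: 50 cells per
condition, positions every 10 min over a 390 min window (the stable-
gradient portion of a 24 h run), four conditions (bulk / CSC-enriched,
each with and without gradient), and a mixed mode interleaving two
population labels 1:1 with at least 30 cells per label.

The walk model: each step direction is a von Mises draw whose natural
parameter is the vector sum κ·b̂ + κ_p·û_prev of a bias term toward the
gradient axis and a persistence term toward the previous step direction,
with κ_p chosen so the step-to-step direction correlation equals the
`persistence` parameter (Best–Fisher inversion of I₁/I₀). Limits behave
correctly: κ = 0 and persistence 0 give an isotropic walk; κ → ∞ gives
straight runs; at κ = 1 the mean step cosine matches I₁(1)/I₀(1) ≈ 0.446.
Speeds are lognormal per step (positive, right-skewed, as cell speeds
are), mean 0.5 μm/min and sd 0.25 μm/min by default so toy numbers stay
hand-checkable; no speed or persistence estimates exist to anchor these,
so they are fixed package defaults, not fitted values. Image stacks come
from the Stern–Volmer forward model with independent additive Gaussian
noise per pixel and image; all generation flows from a single seed.

What the generator deliberately does not emulate: cell division, death,
collisions and crowding, spatially varying speed, oxygen-dependent
motility (an optional local-κ coupling exists but defaults off, matching
the absence of a clear local-oxygen effect in single-cell data), or the
rendering of cells into images (tracking is upstream of this package).
Passing tests therefore show the *statistics* are computed correctly and
are well-calibrated under the assumed sampling design — not that real
migration follows a biased von Mises walk.

## Problem sizes and determinism

Bundled runs use the 0.05 mm grid (492 × 50 cells; the grid-convergence
check re-solves at 0.025 mm), 48 h transient horizons at 120 s steps,
500–2000 synthetic tracks for distributional checks, 200 replicate
experiments for the null rejection-rate calibration, and 10 000 Monte
Carlo datasets for the chi-square level check — sizes chosen so the whole
suite runs in well under a minute while keeping Monte Carlo error small
relative to the asserted bands. Every stochastic component takes an
explicit seed; repeat runs are bit-identical, and report files contain no
timestamps so reruns produce byte-identical outputs.
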