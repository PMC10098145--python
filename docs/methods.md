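# Methods

This note describes the model, the numerical choices, and the design
decisions behind the package, together with what the synthetic
experiments do and do not demonstrate.

## The imaging problem

A short laser pulse deposits optical energy in an absorber resting on
the entrance face of an ultrasonic pipe; thermoelastic expansion turns
the absorbed pattern P (the image) into an acoustic transient.  The
pipe guides the transient into a right-angle prism whose reverberation
scrambles it, and a single small transducer at the prism's lower corner
records one time series.  Encoding position into temporal structure
makes single-shot widefield imaging with a single element possible: the
recorded trace is the linear superposition

    s(t) = sum_i k_i(t) P_i,        s = K P,

where k_i is the transducer's impulse response to a point source at
field-of-view (FOV) pixel i.  K is measured once by pointwise
calibration.  The image is recovered by minimising

    || s - K P ||^2 + 2 lambda Phi_TV(P),

with Phi_TV the isotropic discrete total variation, using TwIST
(two-step iterative shrinkage/thresholding with a TV proximal step).

The decisive property of the pipe-plus-prism encoder is the
**boundary-safe window**.  Whatever rests on the entrance face (the
object, the coupling gel, air) changes the late part of the trace,
because prism-reflected energy travels back up the pipe, interacts with
that boundary, and returns.  The earliest such path crosses the pipe
three times, so the window [0, 3 L/c) — L the pipe length, c the
encoder sound speed — cannot contain boundary-reflected energy that
left through the pipe.  Cropping both K and s to this window removes
the object-dependent signal content, which is why one calibration
serves different objects.

## Acoustic model and solver

Linear lossless acoustics (first-order pressure/velocity form) in
heterogeneous 2-D media; shear waves in the solid are neglected (fluid
model for fused silica) — a known simplification that changes mode
conversion at the glass boundaries but not the encoding mechanism.
The solver is a staggered-grid Fourier pseudospectral scheme with
leapfrog time stepping and the k-space temporal correction
kappa = sinc(c_ref |k| dt / 2), c_ref = max(c): propagation is then
dispersion-free wherever the local speed equals c_ref (the encoder
material), which keeps wavefront arrival times exact on the grid.
Split-field PML (12 cells, polynomial grading of order 4, ~2 Np/cell
peak) absorbs outgoing waves; measured boundary reflections are below
0.1% in amplitude.

Numerical choices that matter:

* **CFL 0.3** at dx = 0.1 mm and c_max = 5900 m/s gives dt ~ 5.08 ns.
* **Surround density 400 kg/m^3** (at the 343 m/s sound speed of air).
  The physical 1833:1 silica/air density ratio destabilises the global
  spectral stencil (the product of the solid's stiffness and the gas's
  mobility amplifies round-off across the interface); at 400 kg/m^3
  the scheme is stable with margin while the interface still reflects
  ~98% in pressure amplitude, preserving the reverberant behaviour
  that the impedance contrast — not its exact value — drives.
* **Medium smoothing (0.7 cells)** inside the solver.  Single-cell
  material edges carry near-Nyquist content whose scattered field
  rings globally through the spectral derivative; a sub-cell Gaussian
  blur of the maps removes this artefact.  Geometry maps returned to
  the user remain crisp.
* **Source band limit 0.4 mm** (raised-cosine spatial low-pass, unity
  below 0.8 k_c): suppresses under-resolved spatial frequencies.
  Sub-resolved sources are invalid input for any spectral scheme: a
  single-cell impulse leaks globally at the few-percent level.
* Grid shapes are rounded up to FFT-friendly sizes.

### The launch

A photoacoustic source is an initial pressure distribution, but an
isotropic release directly under the entrance face insonifies the
boundary immediately and contaminates the early window.  The package
models the *net downward-transmitted wavelet* of a surface absorber:
each pixel blob is released as a one-way state — every plane-wave
component is given the matched particle velocity for downward
propagation (e(k) = -sign(k_y) k/|k|).  Two regularisations make this
construction compatible with a compact source region: the sign kernel
is smoothed (tanh over a 2 mm transition length), which turns its ~1/y
spatial tails into exponentially decaying ones, and the velocity field
is masked to zero above the entrance face.  The blob centre sits one
coupling-layer thickness plus three blob widths below the face.  The
residual upward/grazing radiation is a few percent in amplitude; see
"What the tests show" below.

### Reciprocity calibration

Pointwise calibration needs one propagation per pixel.  The reciprocal
path records the whole matrix in a single run: a pressure release over
the transducer aperture, recorded at every pixel with the adjoint
pairing of the calibration launch under the acoustic energy inner
product — pressure weighted by phi/(rho c^2) at cell centres plus each
staggered velocity component weighted by -rho_sg u0_a, where u0 is the
pixel blob's one-way launch velocity.  The pairing follows from a
conserved cross-quantity (discrete Wronskian) of the symmetric
leapfrog recursion and is exact up to PML asymmetry; note the source
release must carry the per-cell rho c^2 factor of the *solver's*
(smoothed) medium, which varies across the aperture at the prism
corner.  Per-column correlation with direct calibration is 1.000 on
the coarse preset and above 0.95 on the demo preset; the direct path
remains the reference.

## Encoder geometry

2-D cross-section: the prism is a right isosceles triangle (right angle
top-left, vertical left leg, hypotenuse to the lower corner where the
transducer sits); the pipe is a vertical rectangle centred on the prism
top face; a thin water-speed coupling layer (the ultrasound-gel
analogue) always covers the entrance face; boundary variants are
additional material layers painted on top of it, either across the
whole aperture or only above selected FOV pixels.  Validation enforces
the two design rules of the encoder: the pipe must be longer than the
prism edge (the safe window lasts one pipe round trip and must give
the reverberant field time to reach the transducer) and the pipe
aperture must be smaller than the prism edge (the field must scramble
before collection).

Prism edge roughening emulates grinding irregular grooves into the
glass: a seeded Gaussian profile (RMS depth = roughness amplitude,
correlation length = feature size, clipped at 3 amplitudes) displaces
the left leg and the hypotenuse along their normals, excluding the
mated top face and a guard zone of two transducer sizes around the
transducer corner.  Feature sizes must be at least the nominal acoustic
wavelength for the grooves to act as reflectors.

Presets: `demo_2d` (pipe 20 x 6 mm, prism 10 mm, 16 FOV pixels at
0.25 mm — the test workhorse), `fig3_2d` (pipe 60 x 10 mm, prism
30 mm, bare face — the wave-propagation geometry), `fig4_2d` (pipe
30 x 3 mm, prism 5 mm, 0.2 mm transducer), `tiny_2d` (coarse 0.2 mm
cells, plumbing tests).  The 2-D pipe width of the propagation
geometry is not fixed by the source description; 10 mm (the
experimental aperture) is the default and is exposed in config.
Record length defaults to 6 L/c: the boundary-safe window plus an
equal-length contaminated tail for the full-signal comparison.

## Reconstruction

TwIST with "auto" two-step weights derived from an assumed spectral
range [1e-4, 1] of the normalised K^T K; operator normalisation by
power iteration; back-projection initialisation (K^T s); TV proximal
map by Chambolle dual projection (default 10 inner iterations);
optional non-negativity by projection (default on — absorbances are
non-negative); monotone safeguard (fall back to a plain IST step, and
stop if even that cannot decrease the objective), which makes the
recorded objective sequence non-increasing by construction.  Default
stopping: relative objective change < 1e-4 or 200 iterations.

lambda defaults to 0.05 ||K^T s||_inf, the usual shrinkage-solver
scale for moderately noisy data.  The synthetic end-to-end experiments
use 1e-3 ||K^T s||_inf: their data are noiseless, and on the 16-pixel
demo system the 0.05 scale visibly over-smooths (it halves the
correlation with ground truth for matched and changed boundaries
alike).  The matrix-mode recovery experiments use the same 1e-3 scale.

## What the synthetic experiments show — and what they do not

The generator reproduces the *conditions* of the desk-scale study:
geometry and sound speeds of the encoder, pointwise calibration over a
pixel row, single-shot widefield synthesis as the superposed launch of
all pixel blobs (exactly linear, so model fidelity of K P against the
full-physics trace is machine-precision under a matched boundary), and
boundary variants as material layers above the coupling layer.

Measured on the demo geometry, windowed traces of the same phantom
under two boundary variants agree to a few times 1e-2 relative L2
while full records differ by ~0.2: windowing removes most — not all —
of the boundary sensitivity.  The residue is physical within this
model: the source sits adjacent to the boundary, and its residual
upward/grazing radiation probes the variant layer within the window.
A perfectly boundary-clean window exists only in the ray-path
idealisation of the mechanism.

Reconstruction from the windowed trace recovers C- and T-shaped
phantoms (1-D bar motifs in the 2-D setting) with r ~ 1.0 from a
single calibration under changed boundaries.  The *failure* of
full-signal reconstruction, in contrast, does not reproduce at desk
scale: with thousands of time samples constraining 16-51 pixels, the
boundary contamination is nearly orthogonal to the operator's column
space and TV-regularised least squares absorbs it (r drops by at most
~0.05).  That failure mode belongs to the full-scale regime (thousands
of pixels, 3-D) that is deliberately out of desk-scale scope.  The
package therefore demonstrates boundary independence at the trace
level and calibrate-once recovery at the image level, not the
predecessor's collapse.

Other idealisations: no acoustic absorption or dispersion, no shear
waves, scalar pulse-energy jitter only (no beam-profile variation), a
rectangular pipe cross-section standing in for the experimental
hexagonal one, and additive white Gaussian measurement noise referenced
to the windowed signal RMS.

## Problem sizes

The default test suite simulates 2-D grids of ~50k cells (demo: 140 x
360 at 0.1 mm) for ~4000 steps per propagation, and one 350 x 960
grid for ~6900 steps for the full propagation geometry; a pointwise
demo calibration is 16 propagations.  The acceptance script runs the
full-geometry propagation once.
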