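"""Calibration basis, widefield measurement synthesis, and time windowing.

A single-shot transducer trace s from a widefield-illuminated object is
a linear combination of per-pixel impulse responses,

    s = sum_i k_i P_i = K P,

where column k_i of the calibration matrix K is the trace recorded for
a point source at FOV pixel i.  Calibration is simulated either
directly (one propagation per pixel) or through acoustic reciprocity
(one propagation sourced at the transducer, recorded at every pixel).

The boundary-safe time window [0, 3 L/c) crops every trace to the part
that cannot yet contain energy reflected off the entrance-face
boundary: the earliest contaminated path runs down the pipe, back up
after prism reflection, and down again — three pipe transits.  Applying
the same window to K and s removes the object-dependent part of the
measurement and is what makes one calibration serve different objects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acoustic_core import (
    InitialPressure,
    PressureTrace,
    SensorSpec,
    SimGrid,
    band_limit_source,
    gaussian_blob,
    simulate,
)
from .encoder_geometry import (
    BoundaryVariant,
    EncoderLayout,
    EncoderParams,
    FovGrid,
    ImageEstimate,
    build_encoder_medium,
)

__all__ = [
    "TimeWindow",
    "CalibrationMatrix",
    "WidefieldMeasurement",
    "boundary_safe_window",
    "apply_window",
    "calibrate_direct",
    "calibrate_reciprocal",
    "synthesize_widefield",
    "project_widefield",
    "energy_normalize",
    "source_blob",
]

DEFAULT_CUTOFF = 0.4e-3  # spatial band limit of source blobs (metres)


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval [t_start, t_end) in seconds."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if not (0 <= self.t_start < self.t_end):
            raise ValueError("need 0 <= t_start < t_end")


@dataclass
class CalibrationMatrix:
    """System matrix K: one recorded time series per FOV pixel.

    ``matrix`` is (n_time, n_pixels); column i is k_i.  ``window``
    records the crop already applied so the identical crop can be
    applied to measurements; ``norm_factors`` records any per-column
    scaling (unit scaling by default).
    """

    matrix: np.ndarray
    fov: FovGrid
    dt: float
    t0: float = 0.0
    window: Optional[TimeWindow] = None
    norm_factors: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (time x pixels)")
        if self.matrix.shape[1] != self.fov.n_pixels:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns for "
                f"{self.fov.n_pixels} FOV pixels"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix entries must be finite")
        if self.norm_factors is None:
            self.norm_factors = np.ones(self.matrix.shape[1])

    @property
    def n_time(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_time) * self.dt

    def copy(self) -> "CalibrationMatrix":
        return CalibrationMatrix(
            self.matrix.copy(), self.fov, self.dt, self.t0, self.window,
            None if self.norm_factors is None else self.norm_factors.copy(),
            dict(self.meta),
        )


@dataclass
class WidefieldMeasurement:
    """Single-shot transducer trace with pulse-energy metadata."""

    trace: PressureTrace
    pulse_energy: float = 1.0
    variant_label: str = ""
    window: Optional[TimeWindow] = None

    def __post_init__(self):
        if self.pulse_energy <= 0:
            raise ValueError("pulse_energy must be positive")
        if not np.isfinite(self.trace.values).all():
            raise ValueError("trace must be finite")

    def copy(self) -> "WidefieldMeasurement":
        return WidefieldMeasurement(
            self.trace.copy(), self.pulse_energy, self.variant_label, self.window
        )


# ---------------------------------------------------------------------------
# windowing


def boundary_safe_window(params: EncoderParams) -> TimeWindow:
    """Boundary-independent window [0, 3 L_pipe / c_encoder).

    The earliest boundary-contaminated energy must traverse the pipe
    three times (down, up after prism reflection, down again); any path
    through the prism adds strictly positive time, so cropping at 3 L/c
    is conservative.
    """
    return TimeWindow(0.0, 3.0 * params.pipe_length / params.c_encoder)


def _window_indices(nt: int, dt: float, t0: float, w: TimeWindow) -> slice:
    end_time = t0 + nt * dt
    if w.t_end > end_time + dt / 2:
        raise ValueError(
            f"window end {w.t_end:.3e}s lies beyond the recorded duration "
            f"{end_time:.3e}s"
        )
    times = t0 + np.arange(nt) * dt
    keep = (times >= w.t_start - dt * 1e-6) & (times < w.t_end - dt * 1e-6)
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        raise ValueError("window keeps no samples")
    return slice(idx[0], idx[-1] + 1)


def apply_window(obj, w: TimeWindow):
    """Crop a trace, measurement or calibration matrix to a time window.

    Samples outside [t_start, t_end) are dropped and t0 updated; the
    window is recorded so it can be re-applied (a second application of
    the same window is a no-op).  Returns a new object.
    """
    if isinstance(obj, PressureTrace):
        sl = _window_indices(obj.nt, obj.dt, obj.t0, w)
        meta = dict(obj.meta, window=(w.t_start, w.t_end))
        return PressureTrace(obj.values[sl].copy(), obj.dt,
                             obj.t0 + sl.start * obj.dt, meta)
    if isinstance(obj, WidefieldMeasurement):
        tr = apply_window(obj.trace, w)
        return WidefieldMeasurement(tr, obj.pulse_energy, obj.variant_label, w)
    if isinstance(obj, CalibrationMatrix):
        sl = _window_indices(obj.n_time, obj.dt, obj.t0, w)
        return CalibrationMatrix(
            obj.matrix[sl].copy(), obj.fov, obj.dt, obj.t0 + sl.start * obj.dt,
            w, obj.norm_factors.copy(), dict(obj.meta),
        )
    raise TypeError(f"cannot window object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# sources


def _geometry_hash(params: EncoderParams, grid: SimGrid) -> str:
    text = repr(params) + repr(grid)
    return hashlib.md5(text.encode()).hexdigest()[:12]


def launch_mask(grid: SimGrid, layout: EncoderLayout) -> np.ndarray:
    """Vertical taper confining launch velocity below the boundary layer.

    Unity up to the entrance face, cosine roll-off across the coupling
    layer, zero at and above the layer where boundary variants live.
    Confining the one-way velocity field (whose projection kernel has
    slowly decaying tails) below the face keeps the launch strictly
    identical under every boundary variant.
    """
    t_c = max(layout.params.couple_layer_thickness, 3 * grid.dx)
    y = (np.arange(grid.shape[-1]) + 0.5) * grid.dx
    prof = np.ones(grid.shape[-1])
    ramp = (y >= layout.y_face) & (y < layout.y_face + t_c)
    prof[ramp] = np.cos(0.5 * np.pi * (y[ramp] - layout.y_face) / t_c) ** 2
    prof[y >= layout.y_face + t_c] = 0.0
    return np.broadcast_to(prof, grid.shape)


def source_blob(
    grid: SimGrid,
    layout: EncoderLayout,
    x: float,
    source_width: float,
    cutoff_wavelength: float = DEFAULT_CUTOFF,
    amplitude: float = 1.0,
    direction: str = "down",
    label: str = "",
) -> InitialPressure:
    """Band-limited Gaussian launch blob for FOV position ``x``.

    The blob is centred inside the encoder material, one coupling-layer
    thickness plus one source width below the entrance face, and its
    one-way launch velocity is masked below the face, so the initial
    condition is identical under every boundary variant; the ``"down"``
    launch models the net transmitted photoacoustic wavelet of a
    surface absorber entering the waveguide.
    """
    params = layout.params
    depth = params.couple_layer_thickness + 3.0 * source_width
    center = (x, layout.y_face - depth)
    p0 = gaussian_blob(grid, center, fwhm=source_width, amplitude=amplitude)
    mask = launch_mask(grid, layout) if direction == "down" else None
    src = InitialPressure(p0, label=label, direction=direction,
                          velocity_mask=mask)
    return band_limit_source(src, grid, cutoff_wavelength)


def _combined_blob(grid, layout, fov, values, source_width, cutoff, direction):
    """Superposition of pixel blobs weighted by the phantom values."""
    p0 = np.zeros(grid.shape)
    params = layout.params
    depth = params.couple_layer_thickness + 3.0 * source_width
    for x, v in zip(fov.pixel_centers[:, 0], np.ravel(values)):
        if v != 0:
            p0 += v * gaussian_blob(grid, (x, layout.y_face - depth), fwhm=source_width)
    mask = launch_mask(grid, layout) if direction == "down" else None
    src = InitialPressure(p0, direction=direction, velocity_mask=mask)
    return band_limit_source(src, grid, cutoff)


# ---------------------------------------------------------------------------
# calibration


def calibrate_direct(
    grid: SimGrid,
    params: EncoderParams,
    fov: FovGrid,
    variant: BoundaryVariant | None = None,
    source_width: float | None = None,
    cutoff_wavelength: float = DEFAULT_CUTOFF,
    progress: bool = False,
) -> CalibrationMatrix:
    """Pointwise calibration: one propagation per FOV pixel.

    This is the reference calibration path (the in-silico analogue of
    scanning a focused beam across the FOV).  Deterministic given the
    geometry seed.
    """
    source_width = source_width or fov.pitch
    if source_width < 2 * grid.dx:
        raise ValueError("source_width must be at least 2*dx")
    med, layout = build_encoder_medium(params, grid, variant, fov)
    cols = np.zeros((grid.nt, fov.n_pixels))
    iterator = range(fov.n_pixels)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="calibrate", unit="px")
    for i in iterator:
        x = fov.pixel_centers[i, 0]
        src = source_blob(grid, layout, x, source_width, cutoff_wavelength,
                          label=f"pixel {i}")
        try:
            tr = simulate(grid, med, src, [layout.transducer])[0]
        except Exception as exc:  # annotate with the pixel index
            raise type(exc)(f"pixel {i}: {exc}") from exc
        cols[:, i] = tr.values
    meta = {
        "geometry": _geometry_hash(params, grid),
        "pipe_length": params.pipe_length,
        "c_encoder": params.c_encoder,
        "source_width": source_width,
        "cutoff_wavelength": cutoff_wavelength,
        "variant": variant.label if variant else "",
        "method": "direct",
        "seed": params.seed,
    }
    return CalibrationMatrix(cols, fov, grid.dt, 0.0, None, None, meta)


def calibrate_reciprocal(
    grid: SimGrid,
    params: EncoderParams,
    fov: FovGrid,
    variant: BoundaryVariant | None = None,
    source_width: float | None = None,
    cutoff_wavelength: float = DEFAULT_CUTOFF,
) -> CalibrationMatrix:
    """Reciprocity shortcut: one propagation sourced at the transducer.

    Acoustic reciprocity lets the whole matrix be recorded in a single
    run: a blob released over the transducer aperture is recorded at
    every FOV pixel with a footprint matched to the calibration blob.
    The directed (cardioid) launch used by the direct path corresponds,
    under source/receiver exchange, to the one-way receiver combination
    p - (rho c) u_y evaluated at the pixel.  Intended as the fast path
    for large FOVs; validated against :func:`calibrate_direct`.
    """
    source_width = source_width or fov.pitch
    if source_width < 2 * grid.dx:
        raise ValueError("source_width must be at least 2*dx")
    med, layout = build_encoder_medium(params, grid, variant, fov)
    # source: adjoint mirror of the transducer readout. The mean-pressure
    # readout with weights w corresponds, under the energy inner product of
    # the solver's (smoothed) medium, to the pressure release
    # psi = rho c^2 w — the material factor matters because the aperture
    # sits at the prism corner where the smoothed maps vary cell to cell.
    from .acoustic_core import effective_medium as _eff

    med_for_src = _eff(med)
    rc2_src = med_for_src.density * med_for_src.sound_speed**2
    tcells = layout.transducer.cells
    tct = tuple(tcells.T)
    p0 = np.zeros(grid.shape)
    p0[tct] = rc2_src[tct] / (len(tcells) * rc2_src[tct].mean())
    src = InitialPressure(p0, label="transducer")

    # receivers: adjoint pairing of the directed calibration blob under the
    # acoustic energy inner product — pressure weighted by phi/(rho c^2) at
    # cell centres, and each staggered velocity component by
    # -rho_sg * u0_a, where u0 is the one-way launch velocity of the blob.
    # Weights use the effective (solver-smoothed) medium so the pairing
    # matches the propagation operator exactly.
    from .acoustic_core import _stagger, effective_medium, oneway_velocity

    med_eff = effective_medium(med)
    rho_c2 = med_eff.density * med_eff.sound_speed**2
    rho_c = med_eff.density * med_eff.sound_speed
    rho_sg = [_stagger(med_eff.density, a) for a in range(grid.ndim)]
    vmask = launch_mask(grid, layout)
    depth = params.couple_layer_thickness + 3.0 * source_width
    p_sensors, v_sensors = [], []
    for i in range(fov.n_pixels):
        x = fov.pixel_centers[i, 0]
        blob = gaussian_blob(grid, (x, layout.y_face - depth), fwhm=source_width)
        blob = band_limit_source(InitialPressure(blob), grid, cutoff_wavelength).p0
        u0 = oneway_velocity(blob, grid, med.c_max, rho_c)
        u0 = [ua * vmask for ua in u0]
        support = np.abs(blob) > 1e-4 * np.abs(blob).max()
        for a in range(grid.ndim):
            support |= np.abs(u0[a]) * rho_c.max() > 1e-4 * np.abs(blob).max()
        cells = np.argwhere(support)
        ct = tuple(cells.T)
        p_sensors.append(SensorSpec(cells, weights=blob[ct] / rho_c2[ct],
                                    normalize=False, label=f"pixel {i}"))
        v_sensors.append([
            SensorSpec(cells, weights=-(rho_sg[a] * u0[a])[ct],
                       normalize=False, label=f"pixel {i} v{a}")
            for a in range(grid.ndim)
        ])
    n = fov.n_pixels
    sensors = p_sensors + [vs[a] for a in range(grid.ndim) for vs in v_sensors]
    all_p, all_v = simulate(grid, med, src, sensors,
                            record_velocity_axis=tuple(range(grid.ndim)))
    cols = np.zeros((grid.nt, n))
    for i in range(n):
        col = all_p[i].values.copy()
        for a in range(grid.ndim):
            col += all_v[a][n + a * n + i].values
        cols[:, i] = col
    meta = {
        "geometry": _geometry_hash(params, grid),
        "pipe_length": params.pipe_length,
        "c_encoder": params.c_encoder,
        "source_width": source_width,
        "cutoff_wavelength": cutoff_wavelength,
        "variant": variant.label if variant else "",
        "method": "reciprocal",
        "seed": params.seed,
    }
    return CalibrationMatrix(cols, fov, grid.dt, 0.0, None, None, meta)


# ---------------------------------------------------------------------------
# widefield measurement


def synthesize_widefield(
    grid: SimGrid,
    params: EncoderParams,
    variant: BoundaryVariant | None,
    phantom: ImageEstimate,
    fov: FovGrid,
    pulse_energy: float = 1.0,
    noise_snr_db: float | None = None,
    seed: int = 0,
    source_width: float | None = None,
    cutoff_wavelength: float = DEFAULT_CUTOFF,
) -> WidefieldMeasurement:
    """Full-physics single-shot measurement of a phantom.

    One propagation whose initial pressure is the superposition of the
    pixel blobs weighted by the phantom; by solver linearity this
    equals K P for the matching variant (plus the boundary-variant
    discrepancy outside the safe window).  Optional additive white
    Gaussian noise at the stated SNR (power-referenced to the RMS of
    the trace inside the boundary-safe window); seeded.
    """
    if phantom.fov != fov:
        raise ValueError("phantom is not defined on the given FOV grid")
    if (phantom.values < 0).any():
        raise ValueError("phantom values must be non-negative")
    if pulse_energy <= 0:
        raise ValueError("pulse_energy must be positive")
    source_width = source_width or fov.pitch
    med, layout = build_encoder_medium(params, grid, variant, fov)
    src = _combined_blob(grid, layout, fov, phantom.values, source_width,
                         cutoff_wavelength, "down")
    tr = simulate(grid, med, src, [layout.transducer])[0]
    values = tr.values * pulse_energy
    if noise_snr_db is not None:
        w = boundary_safe_window(params)
        sl = _window_indices(len(values), grid.dt, 0.0, w)
        rms = np.sqrt(np.mean(values[sl] ** 2))
        sigma = rms * 10.0 ** (-noise_snr_db / 20.0)
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, sigma, len(values))
    trace = PressureTrace(values, grid.dt, 0.0, {
        "variant": variant.label if variant else "",
        "pulse_energy": pulse_energy,
        "noise_snr_db": noise_snr_db,
        "seed": seed,
    })
    return WidefieldMeasurement(trace, pulse_energy,
                                variant.label if variant else "")


def project_widefield(K: CalibrationMatrix, P: ImageEstimate) -> PressureTrace:
    """Synthetic trace K P (the linear forward model)."""
    if P.fov != K.fov:
        raise ValueError("image is not defined on the calibration FOV")
    values = K.matrix @ P.ravel()
    meta = {"projected": True}
    if K.window is not None:
        meta["window"] = (K.window.t_start, K.window.t_end)
    return PressureTrace(values, K.dt, K.t0, meta)


def energy_normalize(m: WidefieldMeasurement) -> WidefieldMeasurement:
    """Divide the trace by the recorded pulse energy (idempotent)."""
    if m.pulse_energy <= 0:
        raise ValueError("pulse_energy must be positive")
    tr = m.trace.copy()
    tr.values = tr.values / m.pulse_energy
    return WidefieldMeasurement(tr, 1.0, m.variant_label, m.window)
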