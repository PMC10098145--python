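"""Geometry of the spatiotemporal encoder: ultrasonic pipe atop a prism.

The encoder is a long fused-silica pipe standing on the top face of a
right-angle prism, surrounded by air.  A photoacoustic source on the
pipe's entrance (top) face launches a wave that travels down the pipe,
enters the prism and reverberates there; a small transducer at the
prism's lower corner records a time series whose shape encodes the
lateral source position.  Because any energy that interacts with
whatever sits on the entrance face needs at least one extra pipe round
trip before it can reach the transducer, the early part of the trace is
independent of that boundary — the property that makes a single
calibration serve different objects.

The 2-D cross-section modelled here (axis 0 = x, horizontal; axis 1 =
y, vertical, increasing upward): the prism is a right isosceles
triangle with its right angle at the top-left, vertical leg on the
left, hypotenuse running from top-right to the bottom corner, where the
transducer sits; the pipe is a vertical rectangle centred on the prism
top face.  Prism edges (left leg and hypotenuse, away from the mated
top face and the transducer corner) can be roughened with a seeded
random groove/ridge profile to strengthen the scrambling of the
reverberant field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .acoustic_core import DEFAULT_CFL, DEFAULT_PML_CELLS, MediumMap, SensorSpec, SimGrid, build_grid

__all__ = [
    "EncoderParams",
    "BoundaryVariant",
    "FovGrid",
    "ImageEstimate",
    "EncoderLayout",
    "SimSettings",
    "Preset",
    "PRESETS",
    "get_preset",
    "build_encoder_grid",
    "build_encoder_medium",
    "roughen_prism_edges",
    "place_fov_pixels",
    "rubber_layer",
    "derived_times",
]

# default material properties (speed m/s, density kg/m^3).  The surround
# keeps the sound speed of air but a stiffened density: the encoder physics
# is driven by the (still ~50:1) impedance contrast, while the physical
# 1833:1 solid/air density ratio destabilises the global spectral stencil.
FUSED_SILICA = (5900.0, 2200.0)
AIR = (343.0, 400.0)
GEL = (1500.0, 1000.0)  # ultrasound-gel / water analogue
RUBBER = (1600.0, 1100.0)

MARGIN_CELLS = 8  # free cells between the structure and the PML


@dataclass(frozen=True)
class EncoderParams:
    """Geometry and material parameters of the encoder.

    All lengths in metres.  ``roughness_amplitude`` is the RMS depth of
    the random edge profile and ``roughness_feature_size`` its
    correlation length; both zero gives the smooth (off-the-shelf)
    prism.  ``nominal_wavelength`` is the acoustic wavelength at the
    centre of the source band, used only for validity checks.
    """

    pipe_length: float = 20e-3
    pipe_width: float = 6e-3
    prism_edge: float = 10e-3
    c_encoder: float = FUSED_SILICA[0]
    c_surround: float = AIR[0]
    rho_encoder: float = FUSED_SILICA[1]
    rho_surround: float = AIR[1]
    couple_layer_thickness: float = 0.4e-3
    couple_speed: float = GEL[0]
    couple_density: float = GEL[1]
    # NB: rho_surround defaults to a stiffened value, not 1.2 kg/m^3 air;
    # see the numerical-stability note in docs/methods.md

    transducer_size: float = 0.5e-3
    transducer_site: str = "prism_corner"
    roughness_amplitude: float = 0.0
    roughness_feature_size: float = 0.6e-3
    nominal_wavelength: float = 0.4e-3
    seed: int = 0

    def __post_init__(self):
        if self.pipe_length <= self.prism_edge:
            raise ValueError(
                "design rule violated: the pipe must be longer than the prism "
                f"edge (pipe_length={self.pipe_length} <= prism_edge="
                f"{self.prism_edge}); the boundary-safe window lasts one pipe "
                "round trip and must leave the reverberant field time to reach "
                "the transducer"
            )
        if self.pipe_width >= self.prism_edge:
            raise ValueError(
                "design rule violated: the pipe aperture must be smaller than "
                f"the prism edge (pipe_width={self.pipe_width} >= prism_edge="
                f"{self.prism_edge}); otherwise the waves cannot scramble "
                "inside the prism before collection"
            )
        if self.transducer_site != "prism_corner":
            raise ValueError("only the prism_corner transducer site is supported")
        if self.roughness_amplitude > 0 and (
            self.roughness_feature_size < self.nominal_wavelength
        ):
            raise ValueError(
                "roughness_feature_size must be at least the nominal acoustic "
                "wavelength for the grooves to act as reflectors"
            )
        for name in ("pipe_length", "pipe_width", "prism_edge", "c_encoder",
                     "c_surround", "transducer_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BoundaryVariant:
    """Acoustic properties of the layer resting on the pipe's entrance face.

    ``coverage_mask`` restricts the layer to strips above selected FOV
    pixels (``None`` covers the whole pipe aperture).  The layer sits on
    top of the coupling layer, which is always present and identical
    between calibration and measurement.
    """

    layer_speed: float = RUBBER[0]
    layer_density: float = RUBBER[1]
    layer_thickness: float = 0.6e-3
    coverage_mask: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        if self.layer_speed <= 0 or self.layer_density <= 0 or self.layer_thickness <= 0:
            raise ValueError("layer properties must be positive")
        if self.coverage_mask is not None:
            self.coverage_mask = np.asarray(self.coverage_mask, dtype=bool)


@dataclass
class FovGrid:
    """Field-of-view pixel grid on the pipe's entrance face.

    In the 2-D simulation the FOV is a 1-D row of pixels (``shape ==
    (n,)``); purely synthetic grids (matrix-mode solver tests, 2-D
    phantom rasterisation) may have any shape and no physical centres.
    Pixel order is row-major from the corner nearest the coordinate
    origin; index <-> position is a fixed bijection.
    """

    shape: tuple[int, ...]
    pitch: float
    pixel_centers: Optional[np.ndarray] = None  # (*shape, ndim_pos) metres

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if any(n < 1 for n in self.shape):
            raise ValueError("FOV shape must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.pixel_centers is not None:
            self.pixel_centers = np.asarray(self.pixel_centers, dtype=float)

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def synthetic(cls, shape, pitch: float = 1.0) -> "FovGrid":
        return cls(tuple(np.atleast_1d(shape)), pitch)

    def __eq__(self, other):
        if not isinstance(other, FovGrid):
            return NotImplemented
        same = self.shape == other.shape and self.pitch == other.pitch
        if not same:
            return False
        if (self.pixel_centers is None) != (other.pixel_centers is None):
            return False
        if self.pixel_centers is None:
            return True
        return np.allclose(self.pixel_centers, other.pixel_centers)


@dataclass
class ImageEstimate:
    """Pixel intensities over a :class:`FovGrid` (arbitrary units)."""

    values: np.ndarray
    fov: FovGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.fov.shape:
            raise ValueError(
                f"image shape {self.values.shape} != fov shape {self.fov.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("image values must be finite")

    def ravel(self) -> np.ndarray:
        return self.values.reshape(-1)

    def copy(self) -> "ImageEstimate":
        return ImageEstimate(self.values.copy(), self.fov)


@dataclass
class EncoderLayout:
    """Derived landmark coordinates of a built encoder (metres/cells)."""

    x_prism: float
    y_prism_bottom: float
    y_prism_top: float
    x_center: float
    y_face: float
    transducer: SensorSpec
    params: EncoderParams
    grid: SimGrid
    edge_profiles: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimSettings:
    dx: float = 0.1e-3
    cfl: float = DEFAULT_CFL
    pml_cells: int = DEFAULT_PML_CELLS
    duration: Optional[float] = None  # None -> 6 L / c
    source_width: Optional[float] = None  # None -> fov pitch
    cutoff_wavelength: float = 0.4e-3


@dataclass(frozen=True)
class Preset:
    name: str
    params: EncoderParams
    sim: SimSettings
    fov_extent: float
    fov_pitch: float

    @property
    def duration(self) -> float:
        if self.sim.duration is not None:
            return self.sim.duration
        return 6.0 * self.params.pipe_length / self.params.c_encoder

    @property
    def source_width(self) -> float:
        return self.sim.source_width or self.fov_pitch


PRESETS: dict[str, Preset] = {
    # fast preset used by the test suite and demo runs
    "demo_2d": Preset(
        "demo_2d",
        EncoderParams(
            pipe_length=20e-3, pipe_width=6e-3, prism_edge=10e-3,
            transducer_size=0.5e-3,
            roughness_amplitude=0.4e-3, roughness_feature_size=0.6e-3,
        ),
        SimSettings(),
        fov_extent=3.75e-3, fov_pitch=0.25e-3,
    ),
    # wave-propagation illustration geometry: 6 cm pipe, 3 cm prism,
    # fused silica in air, bare entrance face
    "fig3_2d": Preset(
        "fig3_2d",
        EncoderParams(
            pipe_length=60e-3, pipe_width=10e-3, prism_edge=30e-3,
            couple_layer_thickness=0.0, transducer_size=1e-3,
        ),
        SimSettings(duration=35e-6),
        fov_extent=6e-3, fov_pitch=0.1e-3,
    ),
    # desk-scale analogue of the 3-D comparison geometry (30 mm pipe,
    # 5 mm prism, 0.2 mm transducer)
    "fig4_2d": Preset(
        "fig4_2d",
        EncoderParams(
            pipe_length=30e-3, pipe_width=3e-3, prism_edge=5e-3,
            transducer_size=0.2e-3,
            roughness_amplitude=0.3e-3, roughness_feature_size=0.6e-3,
        ),
        SimSettings(),
        fov_extent=2e-3, fov_pitch=0.25e-3,
    ),
    # coarse plumbing preset for fast integration tests
    "tiny_2d": Preset(
        "tiny_2d",
        EncoderParams(
            pipe_length=10e-3, pipe_width=4e-3, prism_edge=6e-3,
            transducer_size=0.6e-3, couple_layer_thickness=0.4e-3,
            roughness_amplitude=0.4e-3, roughness_feature_size=0.8e-3,
            nominal_wavelength=0.8e-3,
        ),
        SimSettings(dx=0.2e-3, cutoff_wavelength=0.8e-3),
        fov_extent=1.8e-3, fov_pitch=0.6e-3,
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def derived_times(params: EncoderParams) -> dict[str, float]:
    """Characteristic times: pipe transit L/c, round trip 2L/c, window end 3L/c."""
    L, c = params.pipe_length, params.c_encoder
    return {"transit": L / c, "round_trip": 2 * L / c, "window_end": 3 * L / c}


# ---------------------------------------------------------------------------
# grid and layout


LAYER_ALLOWANCE = 1.4e-3  # head-room above the face for couple + variant layers


def required_extent(params: EncoderParams, dx: float, pml_cells: int) -> tuple[float, float]:
    from scipy.fft import next_fast_len

    m = (pml_cells + MARGIN_CELLS) * dx
    ex = params.prism_edge + 2 * m
    ey = (
        params.prism_edge + params.pipe_length + params.couple_layer_thickness
        + LAYER_ALLOWANCE + 2 * m
    )
    # round cell counts up to FFT-friendly sizes (extra cells enlarge the
    # surround on the far sides; the encoder stays anchored at the margin)
    return tuple(
        next_fast_len(int(np.ceil(e / dx))) * dx for e in (ex, ey)
    )


def build_encoder_grid(preset_or_params, sim: SimSettings | None = None,
                       duration: float | None = None) -> SimGrid:
    """Build the simulation grid that houses an encoder."""
    if isinstance(preset_or_params, Preset):
        params, sim = preset_or_params.params, preset_or_params.sim
        duration = duration if duration is not None else preset_or_params.duration
    else:
        params = preset_or_params
        sim = sim or SimSettings()
        if duration is None:
            duration = 6.0 * params.pipe_length / params.c_encoder
    extent = required_extent(params, sim.dx, sim.pml_cells)
    c_max = max(params.c_encoder, params.c_surround, params.couple_speed)
    return build_grid(extent, sim.dx, duration, sim.cfl, c_max, sim.pml_cells)


def _layout_coords(params: EncoderParams, grid: SimGrid) -> dict[str, float]:
    m = (grid.pml_cells + MARGIN_CELLS) * grid.dx
    x_prism = m
    y_prism_bottom = m
    y_prism_top = y_prism_bottom + params.prism_edge
    return {
        "x_prism": x_prism,
        "y_prism_bottom": y_prism_bottom,
        "y_prism_top": y_prism_top,
        "x_center": x_prism + params.prism_edge / 2.0,
        "y_face": y_prism_top + params.pipe_length,
    }


def place_fov_pixels(
    params: EncoderParams,
    fov_extent: float,
    pitch: float,
    dx: float = 0.1e-3,
    pml_cells: int = DEFAULT_PML_CELLS,
) -> FovGrid:
    """Row of FOV pixel centres on the pipe entrance face (1-D in 2-D mode).

    ``n = floor(extent/pitch) + 1`` pixels, centred on the pipe axis.
    """
    if fov_extent < 0 or pitch <= 0:
        raise ValueError("fov_extent must be >= 0 and pitch > 0")
    if fov_extent > params.pipe_width:
        raise ValueError(
            f"fov_extent {fov_extent} exceeds the pipe aperture {params.pipe_width}"
        )
    # layout coordinates for a grid built with the same dx/pml convention
    grid = build_encoder_grid(params, SimSettings(dx=dx, pml_cells=pml_cells),
                              duration=dx / params.c_encoder)
    co = _layout_coords(params, grid)
    n = int(np.floor(fov_extent / pitch + 1e-9)) + 1
    xs = co["x_center"] + (np.arange(n) - (n - 1) / 2.0) * pitch
    centers = np.stack([xs, np.full(n, co["y_face"])], axis=-1)
    return FovGrid((n,), pitch, centers)


# ---------------------------------------------------------------------------
# medium construction


def _edge_profile(rng, n: int, dx: float, amplitude: float, feature: float,
                  exclude: np.ndarray) -> np.ndarray:
    """Seeded random groove/ridge depth profile along one edge (metres).

    Filtered white noise with correlation length ~``feature``,
    normalised to RMS ``amplitude`` over the active region, clipped to
    +-3 amplitude, and zeroed where ``exclude`` is set.
    """
    raw = rng.standard_normal(n)
    prof = gaussian_filter1d(raw, sigma=max(feature / dx / 2.0, 1e-6), mode="reflect")
    active = ~exclude
    if active.sum() == 0:
        return np.zeros(n)
    rms = np.sqrt(np.mean(prof[active] ** 2))
    if rms > 0:
        prof = prof * (amplitude / rms)
    prof = np.clip(prof, -3 * amplitude, 3 * amplitude)
    prof[exclude] = 0.0
    return prof


def roughen_prism_edges(
    medium: MediumMap,
    params: EncoderParams,
    grid: SimGrid,
    layout: "EncoderLayout",
) -> MediumMap:
    """Re-rasterise the prism with a seeded rough edge profile.

    Only the left leg and the hypotenuse are perturbed; the top face
    (mated to the pipe) and a guard zone of two transducer sizes around
    the transducer corner stay flush.  Deterministic given
    ``params.seed``.
    """
    if params.roughness_amplitude == 0:
        return medium
    if params.roughness_feature_size < 2 * grid.dx:
        raise ValueError("roughness_feature_size must be at least 2*dx")
    new = MediumMap(medium.sound_speed.copy(), medium.density.copy())
    _paint_prism(new, params, grid, layout, rough=True)
    return new


def _prism_row_bounds(params, grid, co, rough: bool):
    """Per-row [x_left, x_right) bounds of the prism cross-section.

    Returns (iy indices, x_left, x_right, profiles dict)."""
    dx = grid.dx
    y0, y1 = co["y_prism_bottom"], co["y_prism_top"]
    iy = np.arange(int(np.floor(y0 / dx)), int(np.ceil(y1 / dx)))
    yc = (iy + 0.5) * dx
    inside = (yc >= y0) & (yc < y1)
    iy, yc = iy[inside], yc[inside]
    x_left = np.full(len(iy), co["x_prism"])
    x_right = co["x_prism"] + (yc - y0)
    profiles = {}
    if rough and params.roughness_amplitude > 0:
        rng = np.random.default_rng(params.seed)
        guard = 2.0 * params.transducer_size
        # left leg: exclude the transducer corner zone (bottom) and the
        # top corner mated to the pipe face
        excl_left = (yc - y0 < guard) | (y1 - yc < 2 * dx)
        d_left = _edge_profile(rng, len(iy), dx, params.roughness_amplitude,
                               params.roughness_feature_size, excl_left)
        # hypotenuse: arc-length position ~ sqrt(2)*(yc-y0); exclude near
        # both end corners
        excl_hyp = (np.sqrt(2) * (yc - y0) < guard) | (y1 - yc < 2 * dx)
        d_hyp = _edge_profile(rng, len(iy), dx, params.roughness_amplitude,
                              params.roughness_feature_size, excl_hyp)
        x_left = x_left + d_left  # groove: d>0 eats into the prism
        x_right = x_right + d_hyp * np.sqrt(2)  # normal depth -> horizontal shift
        profiles = {"left": d_left, "hyp": d_hyp, "iy": iy}
    return iy, x_left, x_right, profiles


def _paint_prism(medium: MediumMap, params, grid, layout, rough: bool):
    co = {
        "x_prism": layout.x_prism, "y_prism_bottom": layout.y_prism_bottom,
        "y_prism_top": layout.y_prism_top,
    }
    dx = grid.dx
    nx = grid.shape[0]
    xc_cells = (np.arange(nx) + 0.5) * dx
    # clear the previous prism area generously, then repaint
    iy, xl, xr, profiles = _prism_row_bounds(params, grid, co, rough)
    pad = 3 * params.roughness_amplitude + dx
    for k, row in enumerate(iy):
        clear = (xc_cells >= co["x_prism"] - pad) & (
            xc_cells < co["x_prism"] + (iy[k] + 0.5) * dx - co["y_prism_bottom"] + pad
        )
        medium.sound_speed[clear, row] = params.c_surround
        medium.density[clear, row] = params.rho_surround
        inside = (xc_cells >= xl[k]) & (xc_cells < xr[k])
        medium.sound_speed[inside, row] = params.c_encoder
        medium.density[inside, row] = params.rho_encoder
    layout.edge_profiles = profiles


def build_encoder_medium(
    params: EncoderParams,
    grid: SimGrid,
    variant: BoundaryVariant | None = None,
    fov: FovGrid | None = None,
) -> tuple[MediumMap, EncoderLayout]:
    """Rasterise the encoder into a medium map.

    Returns the map plus an :class:`EncoderLayout` with the transducer
    aperture and landmark coordinates.  The optional boundary
    ``variant`` paints a layer on top of the (always present) coupling
    layer, either across the whole pipe aperture or, when it carries a
    ``coverage_mask``, only above the masked FOV pixels.
    """
    dx = grid.dx
    co = _layout_coords(params, grid)
    ext = required_extent(params, dx, grid.pml_cells)
    have = tuple(n * dx for n in grid.shape)
    if have[0] < ext[0] - dx / 2 or have[1] < ext[1] - dx / 2:
        raise ValueError(
            f"grid extent {have} too small for this encoder; need >= {ext}"
        )

    med = MediumMap.homogeneous(grid.shape, params.c_surround, params.rho_surround)

    # pipe
    xc, w = co["x_center"], params.pipe_width
    ix = _cells_in(grid, 0, xc - w / 2, xc + w / 2)
    iy_pipe = _cells_in(grid, 1, co["y_prism_top"], co["y_face"])
    med.sound_speed[np.ix_(ix, iy_pipe)] = params.c_encoder
    med.density[np.ix_(ix, iy_pipe)] = params.rho_encoder

    layout = EncoderLayout(
        x_prism=co["x_prism"], y_prism_bottom=co["y_prism_bottom"],
        y_prism_top=co["y_prism_top"], x_center=co["x_center"],
        y_face=co["y_face"], transducer=None, params=params, grid=grid,
    )

    # prism (rough if requested)
    _paint_prism(med, params, grid, layout, rough=params.roughness_amplitude > 0)

    # coupling layer on the entrance face, spanning the pipe aperture
    t_c = params.couple_layer_thickness
    if t_c > 0:
        iy_c = _cells_in(grid, 1, co["y_face"], co["y_face"] + t_c)
        med.sound_speed[np.ix_(ix, iy_c)] = params.couple_speed
        med.density[np.ix_(ix, iy_c)] = params.couple_density

    # boundary-variant layer above the coupling layer
    if variant is not None:
        y_lo = co["y_face"] + t_c
        y_hi = y_lo + variant.layer_thickness
        iy_v = _cells_in(grid, 1, y_lo, y_hi)
        if len(iy_v) == 0:
            raise ValueError("variant layer thinner than one cell")
        if variant.coverage_mask is None:
            cols = [_cells_in(grid, 0, xc - w / 2, xc + w / 2)]
        else:
            if fov is None:
                raise ValueError("coverage_mask requires the FOV grid")
            if len(variant.coverage_mask) != fov.n_pixels:
                raise ValueError("coverage_mask length must equal fov.n_pixels")
            cols = [
                _cells_in(grid, 0, x - fov.pitch / 2, x + fov.pitch / 2)
                for x, m in zip(fov.pixel_centers[:, 0], variant.coverage_mask) if m
            ]
        for c_ix in cols:
            med.sound_speed[np.ix_(c_ix, iy_v)] = variant.layer_speed
            med.density[np.ix_(c_ix, iy_v)] = variant.layer_density

    layout.transducer = _transducer_sensor(params, grid, co, med)
    return med, layout


def _cells_in(grid: SimGrid, axis: int, lo: float, hi: float) -> np.ndarray:
    n = grid.shape[axis]
    xc = (np.arange(n) + 0.5) * grid.dx
    return np.nonzero((xc >= lo) & (xc < hi))[0]


def _transducer_sensor(params, grid, co, med: MediumMap) -> SensorSpec:
    """Aperture cells along the prism's left leg at the bottom corner."""
    dx = grid.dx
    ix0 = int(np.floor(co["x_prism"] / dx))
    iy = _cells_in(grid, 1, co["y_prism_bottom"], co["y_prism_bottom"] + params.transducer_size)
    cells = []
    for row in iy:
        # first encoder-speed cell in this row at/right of the left leg
        for ixx in range(ix0, ix0 + 4):
            if med.sound_speed[ixx, row] == params.c_encoder:
                cells.append((ixx, row))
                break
    if not cells:
        raise ValueError("could not place the transducer inside the prism corner")
    return SensorSpec(np.array(cells), label="transducer")


def rubber_layer(coverage_mask=None, label: str = "", thickness: float = 0.6e-3) -> BoundaryVariant:
    """Convenience constructor for the rubber-like boundary layer."""
    return BoundaryVariant(RUBBER[0], RUBBER[1], thickness, coverage_mask, label)
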