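"""Shared fixtures.

Expensive wave simulations are session-scoped and shared: the tiny
preset bundle backs the fast unit tests, the demo-preset bundle (one
pointwise calibration plus a handful of single-shot measurements)
backs the end-to-end acceptance checks.
"""

import numpy as np
import pytest

from paise import (
    ImageEstimate,
    boundary_safe_window,
    build_encoder_grid,
    calibrate_direct,
    calibrate_reciprocal,
    get_preset,
    place_fov_pixels,
    rubber_layer,
    synthesize_widefield,
)
from paise.phantoms_eval import make_phantom


def _fov_for(pre):
    return place_fov_pixels(pre.params, pre.fov_extent, pre.fov_pitch,
                            pre.sim.dx, pre.sim.pml_cells)


class Bundle:
    """Lazy per-preset collection of calibration and measurement runs."""

    def __init__(self, name):
        self.preset = get_preset(name)
        self.grid = build_encoder_grid(self.preset)
        self.fov = _fov_for(self.preset)
        self.cal_variant = rubber_layer(label="full")
        self._cache = {}

    def _get(self, key, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def K(self):
        return self._get("K", lambda: calibrate_direct(
            self.grid, self.preset.params, self.fov, self.cal_variant,
            self.preset.source_width, self.preset.sim.cutoff_wavelength))

    @property
    def K_reciprocal(self):
        return self._get("Kr", lambda: calibrate_reciprocal(
            self.grid, self.preset.params, self.fov, self.cal_variant,
            self.preset.source_width, self.preset.sim.cutoff_wavelength))

    @property
    def window(self):
        return boundary_safe_window(self.preset.params)

    def phantom(self, kind):
        return self._get(("ph", kind), lambda: make_phantom(kind, self.fov))

    def measure(self, kind, variant_key):
        """Single-shot measurement of a phantom under a variant.

        variant_key: "matched" (the calibration variant) or "footprint"
        (layer only over the phantom's own footprint).
        """
        def build():
            ph = self.phantom(kind)
            if variant_key == "matched":
                var = self.cal_variant
            else:
                var = rubber_layer(coverage_mask=ph.footprint_mask,
                                   label="footprint")
            return synthesize_widefield(
                self.grid, self.preset.params, var, ph.values, self.fov,
                source_width=self.preset.source_width,
                cutoff_wavelength=self.preset.sim.cutoff_wavelength)
        return self._get(("m", kind, variant_key), build)


@pytest.fixture(scope="session")
def tiny():
    return Bundle("tiny_2d")


@pytest.fixture(scope="session")
def demo():
    return Bundle("demo_2d")
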