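"""Beam-hardening linearisation and relative-density calibration.

Beam hardening — the preferential absorption of low-energy photons — bends
the attenuation-vs-thickness relation and produces cupping and banding in
reconstructed volumes.  Cone-beam reconstruction software commonly corrects
it by mapping grey values through a fixed polynomial "linearisation"
profile.  The profile shipped here as ``nikon-preset-4`` uses the quartic
coefficients (c0..c4) = (0.0, 0.2, 0.8, 0.0, 0.0) with scale 4.44, i.e.
p(x) = 4.44 * (0.8 x^2 + 0.2 x) on normalised attenuation x in [0, 1] —
strictly increasing there, so intensity ordering is preserved, and anchored
at p(0) = 0.

Two conventions in this module are deliberate package choices rather than a
vendor reproduction (the vendor's exact use of "Scale" is not public): the
profile is applied to reconstructed grey values, not projections, and Scale
acts as a global multiplier of the polynomial in normalised space, with the
result rescaled by the normalisation maximum.

Density calibration against a co-scanned water phantom is provided as a
scaffold: an affine map anchoring a measured air ROI at 0 and the water ROI
at 1 yields relative density units; no absolute g/cm3 claim is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .volume_io import Volume

__all__ = [
    "BeamHardeningPreset",
    "DensityCalibration",
    "PRESETS",
    "linearise_beam_hardening",
    "invert_linearisation",
    "calibrate_density",
]


@dataclass(frozen=True)
class BeamHardeningPreset:
    """Polynomial linearisation profile p(x) = scale * sum_k coef[k] x^k."""

    coef: tuple[float, float, float, float, float]  # c0..c4
    scale: float
    name: str = ""

    def __post_init__(self):
        if len(self.coef) != 5:
            raise ValueError("need exactly five coefficients c0..c4")
        if not any(self.coef):
            raise ValueError("at least one coefficient must be nonzero")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def polynomial(self, x):
        c0, c1, c2, c3, c4 = self.coef
        return self.scale * (((c4 * x + c3) * x + c2) * x + c1) * x + self.scale * c0


#: Built-in profiles; "nikon-preset-4" is the default used for the coral scans.
PRESETS: dict[str, BeamHardeningPreset] = {
    "identity": BeamHardeningPreset((0.0, 1.0, 0.0, 0.0, 0.0), 1.0, "identity"),
    "nikon-preset-4": BeamHardeningPreset(
        (0.0, 0.2, 0.8, 0.0, 0.0), 4.44, "nikon-preset-4"
    ),
}


def linearise_beam_hardening(
    values, preset: BeamHardeningPreset | str = "nikon-preset-4",
    normalisation_max: float | None = None,
):
    """Map grey values through a polynomial beam-hardening profile.

    Each value v is normalised x = v / normalisation_max, mapped through
    p(x), then rescaled by normalisation_max.  ``normalisation_max``
    defaults to the maximum of the input (it must be positive).  Accepts a
    scalar, an array, or a :class:`Volume` (returned as a float Volume).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    is_volume = isinstance(values, Volume)
    arr = values.voxels if is_volume else values
    arr = np.asarray(arr, dtype=np.float64)
    if normalisation_max is None:
        normalisation_max = float(arr.max()) if arr.size else 1.0
    if not normalisation_max > 0:
        raise ValueError(f"normalisation_max must be positive, got {normalisation_max}")
    out = normalisation_max * preset.polynomial(arr / normalisation_max)
    if is_volume:
        return Volume(out, values.voxel_size_um, bit_depth=32,
                      intensity_units=values.intensity_units)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def invert_linearisation(
    values, preset: BeamHardeningPreset | str = "nikon-preset-4",
    normalisation_max: float = 1.0,
    x_max: float = 1.0,
):
    """Numerically invert :func:`linearise_beam_hardening` on [0, x_max].

    Valid only where the profile is strictly monotone on the bracket (true
    for preset 4 on [0, 1]).  Root-finds each value to ~1e-12.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    arr = np.asarray(values, dtype=np.float64)

    def solve(y):
        target = y / normalisation_max

        def f(x):
            return preset.polynomial(x) - target

        lo, hi = 0.0, x_max
        if f(lo) * f(hi) > 0:
            raise ValueError(f"value {y} outside the invertible range")
        return normalisation_max * brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)

    out = np.vectorize(solve)(arr)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


@dataclass
class DensityCalibration:
    """Affine intensity -> relative-density map (air = 0, water = 1)."""

    water_mean: float
    air_mean: float

    def __post_init__(self):
        if self.water_mean == self.air_mean:
            raise ValueError("water and air ROI means must differ")

    def apply(self, values):
        return (np.asarray(values, dtype=np.float64) - self.air_mean) / (
            self.water_mean - self.air_mean
        )


def calibrate_density(
    volume: Volume,
    water_roi: tuple[slice, slice, slice],
    air_roi: tuple[slice, slice, slice],
    noise_floor: float = 1e-9,
) -> tuple[Volume, DensityCalibration]:
    """Rescale a volume to relative density units against a water phantom.

    ``water_roi`` / ``air_roi`` are (z, y, x) slice triples into the volume.
    The affine map sends the air ROI mean to 0 and the water ROI mean to 1;
    the result is labelled "relative density (water = 1)".
    """
    water = float(volume.voxels[water_roi].mean())
    air = float(volume.voxels[air_roi].mean())
    if abs(water - air) <= noise_floor:
        raise ValueError(
            f"water ({water}) and air ({air}) ROI means are indistinguishable"
        )
    cal = DensityCalibration(water_mean=water, air_mean=air)
    out = Volume(
        cal.apply(volume.voxels),
        volume.voxel_size_um,
        bit_depth=32,
        intensity_units="relative density (water = 1)",
    )
    return out, cal
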