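"""TIFF stack I/O, volume metadata, and bit-depth reduction.

A micro-CT scan arrives as a stack of grayscale TIFF slices (one file per
axial slice, or one multi-page file).  The :class:`Volume` container pairs
the voxel grid with the isotropic voxel edge length, which every downstream
physical measurement depends on.  Deposited volumes are typically reduced
to 8 bit after processing to keep archives manageable; that step is
:func:`convert_to_8bit`.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "WindowSpec",
    "read_tiff_stack",
    "write_tiff_stack",
    "convert_to_8bit",
    "natural_sort_key",
    "round_half_away",
]

SIDECAR_NAME = "volume.json"

_DTYPE_FOR_DEPTH = {8: np.uint8, 16: np.uint16, 32: np.float32}


def round_half_away(x):
    """Round to nearest integer, halves away from zero (platform-stable)."""
    return np.trunc(x + np.copysign(0.5, x))


def natural_sort_key(name: str):
    """Sort key using the last integer group in ``name`` (natural sort).

    ``slice_2.tif`` sorts before ``slice_10.tif``.  Names without any digit
    group fall back to plain lexicographic order after all numbered names.
    """
    groups = re.findall(r"\d+", name)
    if not groups:
        return (1, 0, name)
    return (0, int(groups[-1]), name)


@dataclass
class Volume:
    """A 3-D scalar grid indexed (slice z, row y, col x) with physical scale.

    Parameters
    ----------
    voxels
        3-D array of grey values.
    voxel_size_um
        Isotropic voxel edge length in micrometres; must be positive.
    bit_depth
        One of 8, 16, 32.  For 8/16 the values must lie in the dtype range;
        32 denotes floating-point grey values.
    intensity_units
        Free-text label such as ``"raw attenuation"`` or ``"8-bit grey"``.
    """

    voxels: np.ndarray
    voxel_size_um: float
    bit_depth: int = 32
    intensity_units: str = "raw attenuation"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(
                f"voxels must be a 3-D grid with all extents >= 1, got shape {self.voxels.shape}"
            )
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError(f"bit_depth must be 8, 16 or 32, got {self.bit_depth}")
        if self.bit_depth in (8, 16):
            hi = 2**self.bit_depth - 1
            lo, up = self.voxels.min(), self.voxels.max()
            if lo < 0 or up > hi:
                raise ValueError(
                    f"values [{lo}, {up}] outside [0, {hi}] for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def z_extent(self) -> int:
        return self.voxels.shape[0]

    def astype_float(self) -> "Volume":
        """Copy with float64 voxels (bit_depth 32) for lossless arithmetic."""
        return Volume(
            self.voxels.astype(np.float64),
            self.voxel_size_um,
            bit_depth=32,
            intensity_units=self.intensity_units,
        )

    def copy(self) -> "Volume":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class WindowSpec:
    """Intensity window for bit-depth reduction.

    mode=``explicit`` uses (lower, upper) as given; ``minmax`` takes the
    volume extrema; ``percentile`` clips ``percentile_tail`` percent from
    each tail before windowing (guards against hot pixels).
    """

    lower: float = 0.0
    upper: float = 0.0
    mode: str = "minmax"
    percentile_tail: float = 0.05

    def __post_init__(self):
        if self.mode not in ("explicit", "minmax", "percentile"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.mode == "explicit" and not self.lower < self.upper:
            raise ValueError("explicit window requires lower < upper")
        if self.mode == "percentile" and not 0 <= self.percentile_tail < 50:
            raise ValueError("percentile_tail must lie in [0, 50)")

    def resolve(self, values: np.ndarray) -> tuple[float, float]:
        """Concrete (lower, upper) bounds for ``values``."""
        if self.mode == "explicit":
            return float(self.lower), float(self.upper)
        if self.mode == "minmax":
            return float(values.min()), float(values.max())
        lo, hi = np.percentile(values, [self.percentile_tail, 100 - self.percentile_tail])
        return float(lo), float(hi)


def _read_sidecar(path: Path) -> dict:
    if path.is_file():
        with open(path) as fh:
            return json.load(fh)
    return {}


def _voxel_size_from_tags(page) -> float | None:
    # TIFF XResolution is pixels per unit; unit from ResolutionUnit tag
    # (2 = inch, 3 = cm).  Unit-ambiguous in the wild, so the JSON sidecar
    # wins on conflict.
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None:
        return None
    return unit_um * den / num


def _check_page(arr: np.ndarray, name: str, ref_shape, ref_dtype):
    if arr.ndim != 2:
        raise ValueError(f"{name}: RGB/multichannel pages are not supported (shape {arr.shape})")
    if ref_shape is not None and arr.shape != ref_shape:
        raise ValueError(
            f"{name}: page shape {arr.shape} differs from first page {ref_shape}"
        )
    if ref_dtype is not None and arr.dtype != ref_dtype:
        raise ValueError(f"{name}: page dtype {arr.dtype} differs from first page {ref_dtype}")


def _depth_of_dtype(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    return 32


def read_tiff_stack(path, voxel_size_um: float | None = None) -> Volume:
    """Read a TIFF stack (directory of slices or one multi-page file).

    Slices from a directory are ordered by the last integer group in each
    filename (natural sort), so ``slice_2.tif`` precedes ``slice_10.tif``.
    The voxel size comes from the JSON sidecar next to the stack, else from
    the TIFF resolution tags, else from the explicit ``voxel_size_um``
    argument; with none of the three the read is refused.
    """
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: natural_sort_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        meta = _read_sidecar(path / SIDECAR_NAME)
        slices = []
        tag_voxel = None
        ref_shape = ref_dtype = None
        for f in files:
            with tifffile.TiffFile(f) as tf:
                for page in tf.pages:
                    arr = page.asarray()
                    _check_page(arr, f.name, ref_shape, ref_dtype)
                    if ref_shape is None:
                        ref_shape, ref_dtype = arr.shape, arr.dtype
                        tag_voxel = _voxel_size_from_tags(page)
                    slices.append(arr)
        voxels = np.stack(slices)
    else:
        if not path.is_file():
            raise FileNotFoundError(path)
        meta = _read_sidecar(path.with_suffix(".json"))
        with tifffile.TiffFile(path) as tf:
            pages = list(tf.pages)
            if not pages:
                raise ValueError(f"{path} contains no pages")
            first = pages[0].asarray()
            _check_page(first, path.name, None, None)
            tag_voxel = _voxel_size_from_tags(pages[0])
            slices = [first]
            for page in pages[1:]:
                arr = page.asarray()
                _check_page(arr, path.name, first.shape, first.dtype)
                slices.append(arr)
        voxels = np.stack(slices)

    vs = meta.get("voxel_size_um") or tag_voxel or voxel_size_um
    if vs is None:
        raise ValueError(
            f"voxel size for {path} not found in sidecar or TIFF tags; "
            "pass voxel_size_um explicitly"
        )
    return Volume(
        voxels,
        float(vs),
        bit_depth=int(meta.get("bit_depth", _depth_of_dtype(voxels.dtype))),
        intensity_units=str(meta.get("intensity_units", "raw attenuation")),
    )


def write_tiff_stack(volume: Volume, path, layout: str = "per-slice") -> list[Path]:
    """Write ``volume`` as TIFF plus a JSON metadata sidecar.

    layout=``per-slice`` writes one zero-padded file per axial slice into
    the directory ``path``; layout=``multipage`` writes a single multi-page
    file at ``path``.  Returns the manifest of written files.  Integer
    volumes round-trip bit-exactly through :func:`read_tiff_stack`.
    """
    if layout not in ("per-slice", "multipage"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    data = np.ascontiguousarray(volume.voxels, dtype=_DTYPE_FOR_DEPTH[volume.bit_depth])
    sidecar = {
        "voxel_size_um": volume.voxel_size_um,
        "bit_depth": volume.bit_depth,
        "intensity_units": volume.intensity_units,
    }
    written: list[Path] = []
    if layout == "per-slice":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(volume.z_extent)))
        for z in range(volume.z_extent):
            f = path / f"slice_{z + 1:0{width}d}.tif"
            tifffile.imwrite(f, data[z], photometric="minisblack")
            written.append(f)
        sidecar_path = path / SIDECAR_NAME
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
        written.append(path)
        sidecar_path = path.with_suffix(".json")
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    written.append(sidecar_path)
    return written


def convert_to_8bit(volume: Volume, window: WindowSpec | None = None) -> Volume:
    """Reduce a 16/32-bit volume to 8 bit through an affine clamp window.

    Values at or below the window's lower bound map to 0, at or above the
    upper bound to 255, linearly in between with round-half-away-from-zero.
    The mapping is monotone non-decreasing.  A degenerate window (e.g.
    minmax on a constant volume) maps everything to 0 with a warning.
    """
    if volume.bit_depth not in (16, 32):
        raise ValueError(f"convert_to_8bit expects bit depth 16 or 32, got {volume.bit_depth}")
    window = window or WindowSpec(mode="minmax")
    vals = volume.voxels.astype(np.float64)
    lo, hi = window.resolve(vals)
    if hi <= lo:
        warnings.warn(
            f"degenerate intensity window [{lo}, {hi}]; output is all zeros",
            stacklevel=2,
        )
        out = np.zeros_like(vals, dtype=np.uint8)
    else:
        scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0) * 255.0
        out = round_half_away(scaled).astype(np.uint8)
    return Volume(out, volume.voxel_size_um, bit_depth=8, intensity_units="8-bit grey")
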