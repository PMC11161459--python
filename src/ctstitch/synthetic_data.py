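"""Ground-truthed synthetic volumes and acquisition-artefact simulation.

Two phantom families are generated here:

* a tall banded cylinder emulating a bamboo-coral skeleton — a dark organic
  core wrapped in alternating bright calcite and dark organic rings, with a
  slow axial drift of the ring phase so that no two axial slices are
  identical (real skeletons taper and band along their length; the fusion
  slice search relies on exactly this slice-to-slice texture variation);
* the "hourglass" geometric calibration phantom — pairs of equal-diameter
  high-sphericity spheres in contact, rendered with sub-voxel supersampled
  surfaces so that metrology on the synthetic volume is not limited by a
  binary mask.

:func:`simulate_overlapping_scans` then splits a tall volume into several
vertically overlapping scan positions and applies the distortions the
stitching pipeline is meant to undo: per-scan affine intensity change and a
within-scan linear axial gain ramp (the heel effect), additive Gaussian
noise, integer XY misalignment, and an optional intensity roll-off at stack
ends standing in for cone-beam under-sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume_io import Volume
from .stitching import TranslationXY, translate_xy

__all__ = [
    "CoralPhantomSpec",
    "ScanSplitSpec",
    "PhantomGeometry",
    "ScanSimTruth",
    "generate_coral_volume",
    "generate_hourglass_phantom",
    "simulate_overlapping_scans",
    "HOURGLASS_DIAMETERS_MM",
]

#: Nominal sphere diameters of the hourglass phantom (mm), smallest first.
HOURGLASS_DIAMETERS_MM = (3.000, 6.000, 9.525)

LABEL_BACKGROUND, LABEL_ORGANIC, LABEL_CALCITE = 0, 1, 2


@dataclass
class CoralPhantomSpec:
    """Parameters of the banded-cylinder coral phantom.

    The cylinder axis runs along z through the XY centre.  Radially the
    specimen is a dark organic core of radius ``core_radius_vox`` wrapped in
    ``n_rings`` rings of width ``ring_period_vox``; the inner half of each
    ring is bright calcite, the outer half dark organic.  Two axial
    variations give every slice a unique texture (the fusion-slice search
    needs slice-to-slice variation to key on): the ring phase drifts by
    ``axial_drift_vox_per_slice`` voxels per slice, and the whole cross
    section tapers conically by a relative ``taper_per_slice`` per slice
    (widest at the top).  The phase drift alone repeats every
    period/drift slices; the taper makes the volume aperiodic, as a real
    tapering skeleton is.  Intensities are noise-free grey levels; noise
    belongs to the scan simulator.
    """

    z_extent: int = 120
    y_extent: int = 96
    x_extent: int = 96
    core_radius_vox: float = 8.0
    n_rings: int = 4
    ring_period_vox: float = 6.0
    organic_level: float = 60.0
    calcite_level: float = 200.0
    background_level: float = 10.0
    axial_drift_vox_per_slice: float = 0.25
    taper_per_slice: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if min(self.z_extent, self.y_extent, self.x_extent) < 1:
            raise ValueError("all extents must be positive")
        if not self.calcite_level > self.organic_level > self.background_level:
            raise ValueError("need calcite_level > organic_level > background_level")
        if self.core_radius_vox <= 0 or self.ring_period_vox <= 0:
            raise ValueError("core radius and ring period must be positive")
        if self.n_rings < 0:
            raise ValueError("n_rings must be non-negative")

    @property
    def outer_radius_vox(self) -> float:
        return self.core_radius_vox + self.n_rings * self.ring_period_vox


def generate_coral_volume(
    spec: CoralPhantomSpec, voxel_size_um: float = 50.0
) -> tuple[Volume, np.ndarray]:
    """Render the coral phantom; returns (volume, label grid).

    Labels are 0 background, 1 organic (core and dark ring halves),
    2 calcite (bright ring halves).  Deterministic for a given spec.
    """
    outer = spec.outer_radius_vox
    s_max = 1.0 + abs(spec.taper_per_slice) * (spec.z_extent - 1) / 2.0
    half_extent = min(spec.y_extent, spec.x_extent) / 2.0
    if outer * s_max + 1 > half_extent:
        raise ValueError(
            f"outer radius {outer * s_max:.1f} vox (incl. taper) does not fit "
            f"the XY extent ({spec.y_extent}x{spec.x_extent})"
        )
    cy, cx = (spec.y_extent - 1) / 2.0, (spec.x_extent - 1) / 2.0
    yy, xx = np.mgrid[0 : spec.y_extent, 0 : spec.x_extent]
    r = np.hypot(yy - cy, xx - cx)

    vol = np.full((spec.z_extent, spec.y_extent, spec.x_extent), spec.background_level,
                  dtype=np.float64)
    labels = np.zeros(vol.shape, dtype=np.uint8)

    z_mid = (spec.z_extent - 1) / 2.0
    for z in range(spec.z_extent):
        # conical taper: cross section scaled by s(z), widest at the top
        s = 1.0 + spec.taper_per_slice * (z - z_mid)
        r_eff = r / s
        inside = r_eff < outer
        core = r_eff < spec.core_radius_vox
        phase = spec.axial_drift_vox_per_slice * z
        slice_vals = np.full(r.shape, spec.background_level)
        slice_lab = np.zeros(r.shape, dtype=np.uint8)
        if spec.n_rings:
            # ring-local position in [0, 1); phase drift wraps within the ring
            ring_frac = np.mod(r_eff - spec.core_radius_vox + phase,
                               spec.ring_period_vox) / spec.ring_period_vox
            calcite = inside & ~core & (ring_frac < 0.5)
            organic_ring = inside & ~core & ~calcite
            slice_vals[calcite] = spec.calcite_level
            slice_vals[organic_ring] = spec.organic_level
            slice_lab[calcite] = LABEL_CALCITE
            slice_lab[organic_ring] = LABEL_ORGANIC
        slice_vals[core] = spec.organic_level
        slice_lab[core] = LABEL_ORGANIC
        vol[z] = slice_vals
        labels[z] = slice_lab

    return Volume(vol, voxel_size_um, bit_depth=32), labels


@dataclass
class PhantomGeometry:
    """Ground-truth geometry of an hourglass phantom rendering.

    ``centres_mm`` are the exact continuous sphere centres (generally
    off-grid); ``pair_ids`` groups sphere indices into equal-diameter pairs
    in contact, so within each pair the centre-to-centre distance equals the
    shared diameter.
    """

    sphere_diameters_mm: list[float]
    centres_mm: list[np.ndarray]
    pair_ids: list[tuple[int, int]]
    voxel_size_um: float

    def __post_init__(self):
        self.centres_mm = [np.asarray(c, dtype=float) for c in self.centres_mm]
        for i, j in self.pair_ids:
            di, dj = self.sphere_diameters_mm[i], self.sphere_diameters_mm[j]
            if not math.isclose(di, dj, rel_tol=1e-12):
                raise ValueError(f"pair ({i},{j}) diameters differ: {di} vs {dj}")
            dist = float(np.linalg.norm(self.centres_mm[i] - self.centres_mm[j]))
            if not math.isclose(dist, di, rel_tol=1e-9):
                raise ValueError(
                    f"pair ({i},{j}) not in contact: distance {dist} vs diameter {di}"
                )

    def pair_distances_mm(self) -> list[float]:
        return [
            float(np.linalg.norm(self.centres_mm[i] - self.centres_mm[j]))
            for i, j in self.pair_ids
        ]


def _render_sphere(vol, centre, radius, sphere_level, background_level, supersample=4):
    """Paint one sphere with fractional-coverage antialiasing at the surface.

    Voxel centres sit at integer indices.  Voxels whose centre is further
    than half a voxel diagonal from the surface are painted solid; the
    boundary shell is supersampled ``supersample``^3 times per voxel.
    """
    half_diag = math.sqrt(3.0) / 2.0
    zc, yc, xc = centre
    lo = [max(0, int(math.floor(c - radius - 1))) for c in centre]
    hi = [
        min(n, int(math.ceil(c + radius + 2)))
        for c, n in zip(centre, vol.shape)
    ]
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    dist = np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2)
    region = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region[dist <= radius - half_diag] = sphere_level

    band = np.abs(dist - radius) < half_diag
    if not band.any():
        return
    pz, py, px = zz[band], yy[band], xx[band]
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    sub = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)  # (s^3, 3)
    pts = np.stack([pz, py, px], axis=1).astype(np.float64)  # (N, 3)
    # (N, s^3) squared distances of subsample points to the centre
    d2 = (
        (pts[:, None, 0] + sub[None, :, 0] - zc) ** 2
        + (pts[:, None, 1] + sub[None, :, 1] - yc) ** 2
        + (pts[:, None, 2] + sub[None, :, 2] - xc) ** 2
    )
    frac = np.mean(d2 <= radius * radius, axis=1)
    region[band] = background_level + frac * (sphere_level - background_level)


def generate_hourglass_phantom(
    diameters_mm=HOURGLASS_DIAMETERS_MM,
    voxel_size_um: float = 50.0,
    sphere_level: float = 200.0,
    background_level: float = 20.0,
    margin_vox: int = 4,
    supersample: int = 4,
) -> tuple[Volume, PhantomGeometry]:
    """Render the hourglass phantom: one tangent sphere pair per diameter.

    Each pair is two equal spheres in contact along the z axis; pairs are
    laid out side by side along x.  Centres carry small deterministic
    sub-voxel offsets so the rendering never aligns specially with the grid.
    Returns the volume and the exact ground-truth geometry.
    """
    diameters_mm = list(diameters_mm)
    if not diameters_mm or any(d <= 0 for d in diameters_mm):
        raise ValueError("diameters must be positive")
    if margin_vox < 2:
        raise ValueError("margin_vox must be >= 2")
    radii_vox = [d * 1000.0 / voxel_size_um / 2.0 for d in diameters_mm]
    if min(radii_vox) * 2 < 4:
        raise ValueError(
            f"voxel size {voxel_size_um} um too coarse: smallest sphere spans "
            f"{min(radii_vox) * 2:.1f} voxels (< 4)"
        )
    max_r = max(radii_vox)
    # deterministic sub-voxel jitter, cycle of 3
    jitter = [(0.3, 0.2, 0.1), (0.1, 0.4, 0.3), (0.2, 0.1, 0.4)]

    zc = margin_vox + 2 * max_r  # pair midpoint height
    z_extent = int(math.ceil(2 * zc)) + 1
    y_extent = int(math.ceil(2 * margin_vox + 2 * max_r)) + 1
    yc = y_extent / 2.0
    x_cursor = float(margin_vox)
    centres, diams = [], []
    for k, (d, r) in enumerate(zip(diameters_mm, radii_vox)):
        jz, jy, jx = jitter[k % 3]
        xk = x_cursor + r + jx
        centres.append(np.array([zc - r + jz, yc + jy, xk]))
        centres.append(np.array([zc + r + jz, yc + jy, xk]))
        diams.extend([d, d])
        x_cursor += 2 * r + margin_vox
    x_extent = int(math.ceil(x_cursor)) + 1

    vol = np.full((z_extent, y_extent, x_extent), background_level, dtype=np.float64)
    for c, d in zip(centres, diams):
        r_vox = d * 1000.0 / voxel_size_um / 2.0
        _render_sphere(vol, c, r_vox, sphere_level, background_level, supersample)

    scale = voxel_size_um / 1000.0
    geometry = PhantomGeometry(
        sphere_diameters_mm=diams,
        centres_mm=[c * scale for c in centres],
        pair_ids=[(2 * k, 2 * k + 1) for k in range(len(diameters_mm))],
        voxel_size_um=voxel_size_um,
    )
    return Volume(vol, voxel_size_um, bit_depth=32), geometry


@dataclass
class ScanSplitSpec:
    """How to split a tall volume into overlapping vertical scan positions.

    Neighbouring scans share exactly ``overlap_slices`` physical slices.
    Each scan's slice at local height z is distorted as
    ``v * scan_gain[i] * (1 + heel_gain_per_slice * z) + scan_offset[i]``
    plus Gaussian noise, then shifted in XY by ``xy_shift_px[i]``.
    ``edge_rolloff_slices`` optionally fades the outer slices of every scan
    towards the volume minimum, mimicking cone-beam under-sampling at stack
    ends.
    """

    n_scans: int = 3
    overlap_slices: int = 10
    heel_gain_per_slice: float = 0.0
    scan_gain: list[float] | None = None
    scan_offset: list[float] | None = None
    xy_shift_px: list[tuple[int, int]] | None = None
    noise_sd: float = 0.0
    edge_rolloff_slices: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.overlap_slices < 3:
            raise ValueError("overlap_slices must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scan_gain is None:
            self.scan_gain = [1.0] * self.n_scans
        if self.scan_offset is None:
            self.scan_offset = [0.0] * self.n_scans
        if self.xy_shift_px is None:
            self.xy_shift_px = [(0, 0)] * self.n_scans
        for name, lst in (("scan_gain", self.scan_gain),
                          ("scan_offset", self.scan_offset),
                          ("xy_shift_px", self.xy_shift_px)):
            if len(lst) != self.n_scans:
                raise ValueError(f"{name} must have length n_scans={self.n_scans}")


@dataclass
class ScanSimTruth:
    """Everything the simulator knows that the pipeline must recover."""

    fusion_pairs: list[tuple[int, int]]  # per adjacent pair: (bottom idx, top idx), 0-based
    slab_ranges: list[tuple[int, int]]  # each scan's [start, stop) in the source volume
    scan_gain: list[float]
    scan_offset: list[float]
    heel_gain_per_slice: float
    xy_shift_px: list[tuple[int, int]]

    def fusion_pairs_cumulative(self) -> list[tuple[int, int]]:
        """Fusion pairs with the bottom index in stitched-so-far coordinates.

        ``fusion_pairs`` indexes each pair's bottom slice within that scan;
        when scans are folded left-to-right the working bottom volume spans
        the source from slice 0, so the bottom index becomes global:
        scan start + local index.  This is the form ``stitch_many`` expects
        in manual mode.
        """
        return [
            (self.slab_ranges[i][0] + b, t)
            for i, (b, t) in enumerate(self.fusion_pairs)
        ]


def simulate_overlapping_scans(
    volume: Volume, split: ScanSplitSpec
) -> tuple[list[Volume], ScanSimTruth]:
    """Split ``volume`` into distorted overlapping scans plus ground truth.

    The ground-truth fusion pair for adjacent scans (i, i+1) points at the
    middle slice of their shared overlap: the same physical slice indexed in
    the bottom and in the top stack.
    """
    Z = volume.z_extent
    n, v = split.n_scans, split.overlap_slices
    total = Z + (n - 1) * v
    base, rem = divmod(total, n)
    lengths = [base + (1 if i < rem else 0) for i in range(n)]
    if any(L <= v for L in lengths):
        raise ValueError(
            f"infeasible split: z extent {Z} too short for {n} scans with "
            f"{v}-slice overlap"
        )
    starts = [0]
    for L in lengths[:-1]:
        starts.append(starts[-1] + L - v)

    rng = np.random.default_rng(split.seed)
    src = volume.voxels.astype(np.float64)
    scans: list[Volume] = []
    for i, (s, L) in enumerate(zip(starts, lengths)):
        slab = src[s : s + L].copy()
        zloc = np.arange(L, dtype=np.float64)[:, None, None]
        slab = slab * split.scan_gain[i] * (1.0 + split.heel_gain_per_slice * zloc) \
            + split.scan_offset[i]
        k = split.edge_rolloff_slices
        if k > 0:
            # linear fade over the outer k slices: 1/(k+1) at the stack end
            fade = np.ones(L)
            ramp = (np.arange(k) + 1) / (k + 1)
            fade[:k] = ramp
            fade[L - k :] = ramp[::-1]
            floor = slab.min()
            slab = floor + (slab - floor) * fade[:, None, None]
        if split.noise_sd > 0:
            slab = slab + rng.normal(0.0, split.noise_sd, size=slab.shape)
        scan = Volume(slab, volume.voxel_size_um, bit_depth=32,
                      intensity_units=volume.intensity_units)
        dy, dx = split.xy_shift_px[i]
        if (dy, dx) != (0, 0):
            scan = translate_xy(scan, TranslationXY(dy, dx), fill=float(slab.min()))
        scans.append(scan)

    fusion_pairs = []
    for i in range(n - 1):
        f_global = starts[i + 1] + v // 2
        fusion_pairs.append((f_global - starts[i], v // 2))

    truth = ScanSimTruth(
        fusion_pairs=fusion_pairs,
        slab_ranges=[(s, s + L) for s, L in zip(starts, lengths)],
        scan_gain=list(split.scan_gain),
        scan_offset=list(split.scan_offset),
        heel_gain_per_slice=split.heel_gain_per_slice,
        xy_shift_px=[tuple(t) for t in split.xy_shift_px],
    )
    return scans, truth
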