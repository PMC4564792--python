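"""Synthetic dental-CT phantom with per-tooth ground truth.

The phantom reproduces the imaging situation that makes per-tooth
segmentation hard: a mandible-like arch of alveolar (socket) bone in which
tube-like teeth sit whose mean intensity exceeds the surrounding bone by only
a small, configurable gap; dark dentin/pulp cores inside each tooth that
produce holes under thresholding; and cross-sections that drift gradually
from slice to slice (linear radius taper toward the root, with optional
in-plane tilt).  Crowns protrude a few slices above the bone into soft
tissue; the bone continues a few slices below the root apices, as the
mandibular body does.

Materials, darkest to brightest: air background, soft tissue, pulp, socket
bone, tooth (= socket + contrast_gap).  Noise is additive Gaussian; no
beam-hardening or metal artifacts are simulated.  Generation is a pure
function of the configuration: the same ``rng_seed`` gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .region_grow import BoundingBox
from .slice_state import ToothSeedSet
from .threshold_search import Histogram
from .volume_io import LabelVolume, VolumeImage

__all__ = ["PhantomConfig", "generate_phantom", "histogram"]


@dataclass
class PhantomConfig:
    """Geometry and intensity model of the synthetic dentition.

    The intensity ordering background < tissue < socket < tooth is enforced,
    with pulp below socket so pulp interiors fall out of any tooth threshold
    and must be recovered by hole filling.  ``contrast_gap`` is the tooth
    minus socket difference in HU — the knob that controls how close the
    phantom is to the hard regime where teeth and sockets are nearly
    isointense.  ``taper`` is the fractional radius change per axial slice.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    n_teeth: int = 14
    arch_radius_vox: float = 46.0
    tooth_radius_vox: float = 4.6
    taper: float = 0.01
    intensity_background: float = -1000.0
    intensity_tissue: float = 200.0
    intensity_socket: float = 1300.0
    contrast_gap: float = 150.0
    intensity_pulp: float = 600.0
    noise_sigma: float = 20.0
    rng_seed: int = 0
    # layout details
    arch_span_deg: float = 215.0
    axis_ratio: float = 1.1  # radial over tangential semi-axis of the cross-section
    pulp_radius_frac: float = 0.45
    tilt_vox_per_slice: float = 0.0
    root_slice: int = 10
    crown_slice: int = 54
    crown_slices_above_bone: int = 4
    bone_margin_below_root: int = 4
    bone_pad_vox: float = 3.0  # socket bone beyond the outermost tooth surface
    tissue_pad_vox: float = 8.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ConfigError(f"shape must be three positive ints, got {self.shape}")
        if self.n_teeth < 1:
            raise ConfigError("n_teeth must be >= 1")
        if not (
            self.intensity_background
            < self.intensity_tissue
            < self.intensity_socket
            < self.intensity_tooth
        ):
            raise ConfigError("need background < tissue < socket < tooth intensity ordering")
        if not self.intensity_pulp < self.intensity_socket:
            raise ConfigError("pulp intensity must fall below socket intensity")
        if self.contrast_gap <= 0:
            raise ConfigError("contrast_gap must be > 0")
        if not 0 <= self.taper < 1:
            raise ConfigError("taper must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0 < self.pulp_radius_frac < 1:
            raise ConfigError("pulp_radius_frac must be in (0, 1)")
        if not 0 <= self.root_slice < self.crown_slice < self.shape[2]:
            raise ConfigError("need 0 <= root_slice < crown_slice < nz")

    @property
    def intensity_tooth(self) -> float:
        return self.intensity_socket + self.contrast_gap

    @property
    def reference_slice(self) -> int:
        return self.shape[2] // 2


def _tooth_geometry(cfg: PhantomConfig) -> Iterator[tuple[int, float, float, float]]:
    """Yield (tooth_id, center_x, center_y, angle) on the reference slice."""
    nx, ny, _ = cfg.shape
    cx, cy = nx / 2.0, ny / 2.0
    span = np.deg2rad(cfg.arch_span_deg)
    start = np.pi / 2.0 - span / 2.0
    if cfg.n_teeth == 1:
        angles = [np.pi / 2.0]
    else:
        angles = [start + i * span / (cfg.n_teeth - 1) for i in range(cfg.n_teeth)]
    for k, th in enumerate(angles, start=1):
        yield k, cx + cfg.arch_radius_vox * np.cos(th), cy + cfg.arch_radius_vox * np.sin(th), th


def _radius_at(cfg: PhantomConfig, z: int) -> float:
    """Cross-section base radius at slice z (widest at the crown, tapering
    root-ward); zero outside the tooth's z-extent."""
    if not cfg.root_slice <= z <= cfg.crown_slice:
        return 0.0
    return cfg.tooth_radius_vox * (1.0 - cfg.taper * (cfg.crown_slice - z))


def _ellipse_mask(
    xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, a: float, b: float, angle: float
) -> np.ndarray:
    """Pixels inside the ellipse with semi-axis ``a`` along ``angle`` (the
    radial direction) and ``b`` tangential."""
    dx = xx - cx
    dy = yy - cy
    ur = dx * np.cos(angle) + dy * np.sin(angle)
    ut = -dx * np.sin(angle) + dy * np.cos(angle)
    return (ur / a) ** 2 + (ut / b) ** 2 <= 1.0


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[VolumeImage, LabelVolume, ToothSeedSet]:
    """Build the phantom volume, its ground-truth labels, and a seed set.

    The label volume marks each tooth's full extent including its pulp core.
    The seed set carries one seed per tooth on the middle (reference) slice,
    placed at the tooth centroid and displaced outward along the arch radius
    if the centroid lands in pulp, plus a bounding box around the dentition.
    Raises :class:`ConfigError` if the configured geometry would make two
    teeth overlap (ground truth is never silently merged).
    """
    nx, ny, nz = cfg.shape
    vol = np.full(cfg.shape, cfg.intensity_background, dtype=np.float64)
    labels = np.zeros(cfg.shape, dtype=np.int16)
    pulp = np.zeros(cfg.shape, dtype=bool)

    cx0, cy0 = nx / 2.0, ny / 2.0
    xs = np.arange(nx, dtype=float)
    ys = np.arange(ny, dtype=float)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    rr = np.hypot(xx - cx0, yy - cy0)

    a_max = cfg.tooth_radius_vox * max(cfg.axis_ratio, 1.0)
    bone_lo = max(0, cfg.root_slice - cfg.bone_margin_below_root)
    bone_hi = min(nz - 1, cfg.crown_slice - cfg.crown_slices_above_bone)
    bone_band = (rr >= cfg.arch_radius_vox - a_max - cfg.bone_pad_vox) & (
        rr <= cfg.arch_radius_vox + a_max + cfg.bone_pad_vox
    )
    tissue_disc = rr <= cfg.arch_radius_vox + a_max + cfg.bone_pad_vox + cfg.tissue_pad_vox

    teeth = list(_tooth_geometry(cfg))
    z_ref = cfg.reference_slice
    for z in range(nz):
        sl = vol[:, :, z]
        sl[tissue_disc] = cfg.intensity_tissue
        if bone_lo <= z <= bone_hi:
            sl[bone_band] = cfg.intensity_socket
        r = _radius_at(cfg, z)
        if r < 0.5:
            continue
        for k, tcx, tcy, th in teeth:
            ex = tcx + cfg.tilt_vox_per_slice * (z - z_ref) * np.cos(th)
            ey = tcy + cfg.tilt_vox_per_slice * (z - z_ref) * np.sin(th)
            a = r * cfg.axis_ratio
            b = r
            tooth_px = _ellipse_mask(xx, yy, ex, ey, a, b, th)
            if np.any(labels[:, :, z][tooth_px] != 0):
                raise ConfigError(
                    f"teeth overlap at slice {z}: tooth {k} collides with a neighbor; "
                    "increase arch_radius_vox or reduce tooth_radius_vox/n_teeth"
                )
            sl[tooth_px] = cfg.intensity_tooth
            labels[:, :, z][tooth_px] = k
            # pulp core, only where a >= 1-px dentin ring remains around it
            ap = a * cfg.pulp_radius_frac
            bp = b * cfg.pulp_radius_frac
            if a - ap >= 1.2 and bp >= 0.5:
                pulp_px = _ellipse_mask(xx, yy, ex, ey, ap, bp, th)
                sl[pulp_px] = cfg.intensity_pulp
                pulp[:, :, z] |= pulp_px

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.rng_seed)
        vol = vol + rng.normal(0.0, cfg.noise_sigma, size=vol.shape)
    data = np.clip(np.rint(vol), -32768, 32767).astype(np.int16)

    seeds = _place_seeds(cfg, labels, pulp, teeth)
    bbox = BoundingBox.from_mask(labels != 0, margin=3)
    # tight z-range around the dentition: the box a user would draw
    zs = np.nonzero(labels.any(axis=(0, 1)))[0]
    bbox = BoundingBox(
        (bbox.mins[0], bbox.mins[1], max(0, int(zs.min()) - 1)),
        (bbox.maxs[0], bbox.maxs[1], min(nz, int(zs.max()) + 2)),
    )
    seedset = ToothSeedSet(reference_slice=z_ref, seeds=seeds, bbox=bbox)

    spacing = (0.2, 0.2, 0.2)  # mm, CBCT-like isotropic voxels
    return (
        VolumeImage(data, spacing),
        LabelVolume(labels, spacing),
        seedset,
    )


def _place_seeds(
    cfg: PhantomConfig,
    labels: np.ndarray,
    pulp: np.ndarray,
    teeth: list[tuple[int, float, float, float]],
) -> dict[int, list[tuple[int, int]]]:
    z = cfg.reference_slice
    lab2d = labels[:, :, z]
    pulp2d = pulp[:, :, z]
    out: dict[int, list[tuple[int, int]]] = {}
    for k, _, _, th in teeth:
        mask = lab2d == k
        if not mask.any():
            raise ConfigError(f"tooth {k} has no voxels on the reference slice {z}")
        pts = np.argwhere(mask)
        cx, cy = pts.mean(axis=0)
        px, py = int(round(cx)), int(round(cy))
        # displace outward along the arch radial direction while in pulp
        step = 0
        while pulp2d[px, py] or not mask[px, py]:
            step += 1
            px = int(round(cx + step * np.cos(th)))
            py = int(round(cy + step * np.sin(th)))
            if step > labels.shape[0]:
                raise ConfigError(f"could not place a seed inside tooth {k}")
        out[k] = [(px, py)]
    return out


def histogram(vol: VolumeImage, bin_width: float) -> Histogram:
    """Intensity histogram with fixed-width bins spanning [min, max].

    The total count equals the voxel count; a constant volume yields a single
    populated bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    data = vol.data
    lo = float(data.min())
    hi = float(data.max())
    n_bins = max(1, int(np.floor((hi - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(data, bins=edges)
    return Histogram(edges, counts)
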