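"""Extraction of disc-centred and vertebra-centred volumes for grading.

Disc volumes are centred at the midpoint between the centroids of two
adjacent vertebra detections, rotated in-plane so the lower endplate of the
upper vertebra is horizontal, sized to twice the larger vertebral-body width
with a 2:1 width:height aspect, and resampled to 112 x 224 per slice.
Vertebra volumes are a tightly fitted, slightly expanded axis-aligned cuboid
resampled to 224 x 224 per slice.  Both keep the slices covered by the
instance(s) plus one margin slice on each side, and store an invertible
affine back to scan coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .levels import LEVEL_INDEX
from .scan_io import SagittalScan
from .vfr import VertebraInstance


@dataclass
class RotatedAffine:
    """Maps volume pixel (i, j) on any kept slice to scan pixel (row, col).

    scan = centre + (i - out_h/2) * scale_h * v + (j - out_w/2) * scale_w * u
    where u is the in-plane unit vector along the (rotated) width axis and
    v = perp(u) points inferiorly.
    """

    centre: np.ndarray            # (row, col)
    u: np.ndarray                 # width-axis unit vector (row, col)
    v: np.ndarray                 # height-axis unit vector (row, col)
    scale_h: float                # scan px per volume px, height axis
    scale_w: float
    out_shape: tuple[int, int]
    slice_indices: list[int]

    def volume_to_scan(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        oh, ow = self.out_shape
        di = (pts[:, 0] - oh / 2.0) * self.scale_h
        dj = (pts[:, 1] - ow / 2.0) * self.scale_w
        return self.centre + di[:, None] * self.v + dj[:, None] * self.u

    def scan_to_volume(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - self.centre
        oh, ow = self.out_shape
        i = rel @ self.v / self.scale_h + oh / 2.0
        j = rel @ self.u / self.scale_w + ow / 2.0
        return np.stack([i, j], axis=1)


@dataclass
class DiscVolume:
    voxels: np.ndarray            # (112, 224, S)
    level: str                    # e.g. "L5/S1"
    sequence: str
    affine: RotatedAffine


@dataclass
class VBVolume:
    voxels: np.ndarray            # (224, 224, S)
    level: str | None
    sequence: str
    affine: RotatedAffine


def _kept_slices(scan: SagittalScan, instances: list[VertebraInstance],
                 margin: int = 1) -> list[int]:
    lo = min(min(i.slice_indices) for i in instances) - margin
    hi = max(max(i.slice_indices) for i in instances) + margin
    return [s for s in range(lo, hi + 1) if 0 <= s < scan.n_slices]


def _sample_rotated(scan: SagittalScan, affine: RotatedAffine) -> np.ndarray:
    oh, ow = affine.out_shape
    ii, jj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
    pts = affine.volume_to_scan(np.stack([ii.ravel(), jj.ravel()], axis=1))
    out = np.zeros((oh, ow, len(affine.slice_indices)), dtype=np.float32)
    for si, s in enumerate(affine.slice_indices):
        vals = ndimage.map_coordinates(scan.voxels[s].astype(np.float64),
                                       np.stack([pts[:, 0], pts[:, 1]]),
                                       order=1, mode="constant", cval=0.0)
        out[:, :, si] = vals.reshape(oh, ow)
    return out


def extract_disc_volume(scan: SagittalScan, upper: VertebraInstance,
                        lower: VertebraInstance,
                        out_shape: tuple[int, int] = (112, 224),
                        slice_margin: int = 1) -> DiscVolume:
    """Extract the intervertebral-disc volume between two adjacent vertebrae.

    The window is centred at the midpoint of the two instance centroids and
    rotated so the upper instance's inferior endplate (AI -> PI edge) is
    horizontal; its width is twice the larger VB width and its height half
    the width (2:1 aspect).
    """
    if upper.level is not None and lower.level is not None:
        if LEVEL_INDEX.get(lower.level, -99) - LEVEL_INDEX.get(upper.level, 99) != 1:
            raise ValueError(
                f"instances are not adjacent levels: {upper.level} / {lower.level}")
    cu = upper.centroid_px()[1:]
    cl = lower.centroid_px()[1:]
    centre = 0.5 * (cu + cl)
    quad = upper.central_quad
    edge = quad.corners["PI"].position - quad.corners["AI"].position
    u = edge / np.linalg.norm(edge)
    if u[1] < 0:                       # keep width axis oriented along +col
        u = -u
    v = np.array([u[1], -u[0]])
    if v[0] < 0:                       # keep height axis pointing inferior
        v = -v
    width_px = 2.0 * max(upper.central_quad.width(), lower.central_quad.width())
    height_px = width_px / 2.0
    oh, ow = out_shape
    slices = _kept_slices(scan, [upper, lower], slice_margin)
    affine = RotatedAffine(centre=centre, u=u, v=v,
                           scale_h=height_px / oh, scale_w=width_px / ow,
                           out_shape=out_shape, slice_indices=slices)
    voxels = _sample_rotated(scan, affine)
    level = None
    if upper.level is not None and lower.level is not None:
        level = f"{upper.level}/{lower.level}"
    return DiscVolume(voxels=voxels, level=level or "", sequence=scan.sequence.value,
                      affine=affine)


def extract_vb_volume(scan: SagittalScan, instance: VertebraInstance,
                      expansion: float = 0.2,
                      out_shape: tuple[int, int] = (224, 224),
                      slice_margin: int = 1) -> VBVolume:
    """Extract an axis-aligned, slightly expanded cuboid around one vertebra."""
    if not instance.quads:
        raise ValueError("empty instance")
    corners = np.concatenate([q.corner_array() for q in instance.quads])
    r0, r1 = corners[:, 0].min(), corners[:, 0].max()
    c0, c1 = corners[:, 1].min(), corners[:, 1].max()
    dr, dc = (r1 - r0) * expansion, (c1 - c0) * expansion
    r0, r1 = r0 - dr, r1 + dr
    c0, c1 = c0 - dc, c1 + dc
    centre = np.array([(r0 + r1) / 2.0, (c0 + c1) / 2.0])
    oh, ow = out_shape
    slices = _kept_slices(scan, [instance], slice_margin)
    affine = RotatedAffine(centre=centre, u=np.array([0.0, 1.0]),
                           v=np.array([1.0, 0.0]),
                           scale_h=(r1 - r0) / oh, scale_w=(c1 - c0) / ow,
                           out_shape=out_shape, slice_indices=slices)
    voxels = _sample_rotated(scan, affine)
    return VBVolume(voxels=voxels, level=instance.level,
                    sequence=scan.sequence.value, affine=affine)
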