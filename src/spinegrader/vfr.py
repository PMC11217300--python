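"""Vector Field Regression: vertebral-body detection in sagittal slices.

Each vertebral body (VB) is represented per slice as a quadrilateral with four
named corners (AS/PS/AI/PI = antero/postero-superior/inferior) plus a centroid.
A fully-convolutional network regresses, per slice:

* 5 detection channels — Gaussian peaks (max 1) at the 4 corner types and the
  centroid, with standard deviation proportional to sqrt(quad area);
* 8 grouping channels — for each corner type, a 2-component vector field
  which, in a square neighbourhood around the corner, holds the displacement
  from the pixel to the owning VB's centroid.  A corner landmark therefore
  "points at" its centroid, which lets landmarks be grouped into VB instances
  independently of vertebra size, rotation or flips.

This module contains target construction, the composite training losses,
landmark extraction, vector-field grouping, robust completion of partially
detected quads, patch splitting/merging for large fields of view, polygon IOU
and cross-slice stacking into 3-D vertebra instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .scan_io import PatchAffine, SagittalScan, resample_patch

CORNER_KINDS = ("AS", "PS", "AI", "PI")
ALL_KINDS = CORNER_KINDS + ("centroid",)
# diagonally opposite corner, used for robust completion
OPPOSITE = {"AS": "PI", "PI": "AS", "PS": "AI", "AI": "PS"}

# channel layout of the 13-channel target/output tensor
DET_SLICE = slice(0, 5)          # AS, PS, AI, PI, centroid
FIELD_SLICE = slice(5, 13)       # (d_row, d_col) per corner kind


def quad_area(corners: np.ndarray) -> float:
    """Shoelace area of a quad given corners ordered AS, PS, AI, PI."""
    poly = corners[[0, 1, 3, 2]]     # simple traversal AS->PS->PI->AI
    x = poly[:, 1]
    y = poly[:, 0]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# ---------------------------------------------------------------------------
# Target construction and losses
# ---------------------------------------------------------------------------

def build_targets(quads: list[tuple[np.ndarray, np.ndarray]],
                  shape: tuple[int, int],
                  c_peak: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Build the 13-channel training target for one patch.

    Parameters
    ----------
    quads : list of (corners (4,2), centroid (2,)) in patch pixel coordinates,
        corners ordered AS, PS, AI, PI, positions as (row, col).
    shape : (H, W) of the patch grid.
    c_peak : Gaussian peak sigma = c_peak * sqrt(quad area).

    Returns
    -------
    target : (13, H, W) array; detection channels in [0, 1] (overlapping peaks
        combined by element-wise max), grouping channels hold the displacement
        centroid - (i, j), zero outside the corner neighbourhoods.
    field_mask : (4, H, W) boolean; True where the corresponding corner's
        vector field is defined (the square neighbourhood of edge sqrt(area)/3).
    """
    h, w = shape
    target = np.zeros((13, h, w), dtype=np.float64)
    mask = np.zeros((4, h, w), dtype=bool)
    rr = np.arange(h)
    cc = np.arange(w)
    for corners, centroid in quads:
        corners = np.asarray(corners, dtype=float)
        centroid = np.asarray(centroid, dtype=float)
        area = quad_area(corners)
        if area <= 0:
            raise ValueError("quad with zero area")
        size = math.sqrt(area)
        sigma = c_peak * size
        landmarks = list(corners) + [centroid]
        for k, pos in enumerate(landmarks):
            cut = max(2, int(math.ceil(4 * sigma)) + 1)
            r0, r1 = max(0, int(pos[0]) - cut), min(h, int(pos[0]) + cut + 1)
            c0, c1 = max(0, int(pos[1]) - cut), min(w, int(pos[1]) + cut + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            dr = rr[r0:r1, None] - pos[0]
            dc = cc[None, c0:c1] - pos[1]
            g = np.exp(-(dr ** 2 + dc ** 2) / (2.0 * sigma ** 2))
            np.maximum(target[k, r0:r1, c0:c1], g, out=target[k, r0:r1, c0:c1])
        # grouping neighbourhoods
        half = (size / 3.0) / 2.0
        for l, pos in enumerate(corners):
            r0 = max(0, int(math.floor(pos[0] - half)))
            r1 = min(h, int(math.ceil(pos[0] + half)) + 1)
            c0 = max(0, int(math.floor(pos[1] - half)))
            c1 = min(w, int(math.ceil(pos[1] + half)) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            sub_r = rr[r0:r1, None]
            sub_c = cc[None, c0:c1]
            inside = (np.abs(sub_r - pos[0]) <= half) & (np.abs(sub_c - pos[1]) <= half)
            drow = np.broadcast_to(centroid[0] - sub_r, inside.shape)
            dcol = np.broadcast_to(centroid[1] - sub_c, inside.shape)
            ch = 5 + 2 * l
            target[ch, r0:r1, c0:c1] = np.where(inside, drow, target[ch, r0:r1, c0:c1])
            target[ch + 1, r0:r1, c0:c1] = np.where(inside, dcol,
                                                    target[ch + 1, r0:r1, c0:c1])
            mask[l, r0:r1, c0:c1] |= inside
    return target, mask


def detect_weights(target_det: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Per-pixel weights for the detection L1 loss.

    For each channel, pixels where the target >= threshold ("positive" pixels,
    count P) are weighted N/(N+P) and the rest P/(N+P), balancing the sparse
    peaks against the background.  An all-background channel gets zero weight.
    """
    k, h, w = target_det.shape
    weights = np.zeros_like(target_det)
    for ch in range(k):
        pos = target_det[ch] >= threshold
        p = int(pos.sum())
        n = h * w - p
        if p == 0:
            continue
        weights[ch] = np.where(pos, n / (n + p), p / (n + p))
    return weights


def loss_detect(output_det: np.ndarray, target_det: np.ndarray,
                threshold: float = 0.01) -> float:
    """Class-balanced L1 loss over the 5 detection channels."""
    if output_det.shape != target_det.shape:
        raise ValueError("shape mismatch between output and target")
    w = detect_weights(target_det, threshold)
    return float(np.sum(w * np.abs(output_det - target_det)))


def loss_group(output_fields: np.ndarray, target_fields: np.ndarray,
               field_mask: np.ndarray) -> float:
    """Summed squared field error over the corner neighbourhoods.

    output_fields/target_fields: (8, H, W); field_mask: (4, H, W).
    """
    total = 0.0
    for l in range(4):
        diff = output_fields[2 * l:2 * l + 2] - target_fields[2 * l:2 * l + 2]
        total += float(np.sum((diff ** 2) * field_mask[l]))
    return total


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Landmark:
    kind: str                       # one of ALL_KINDS
    position: np.ndarray            # (row, col), sub-pixel
    score: float
    pointing: np.ndarray | None = None   # corner fields sampled at the peak

    def endpoint(self) -> np.ndarray:
        """Where this corner claims its centroid sits."""
        return self.position + self.pointing


def _subpixel_offset(vals: np.ndarray) -> float:
    """Quadratic (log-parabola) peak refinement from 3 samples; exact for
    Gaussian profiles."""
    v = np.log(np.maximum(vals, 1e-12))
    denom = v[0] - 2 * v[1] + v[2]
    if denom >= 0:
        return 0.0
    off = 0.5 * (v[0] - v[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def extract_landmarks(tensor: np.ndarray, peak_threshold: float = 0.3,
                      min_separation: int = 4,
                      max_peaks: int = 64) -> list[Landmark]:
    """Local-maximum suppression on the detection channels.

    Peaks below `peak_threshold` are ignored; of two peaks closer than
    `min_separation` pixels only the higher survives.  At most `max_peaks`
    per channel are kept (highest first), which bounds the cost of grouping
    on degenerate plateau-filled heatmaps.  Positions are refined to
    sub-pixel accuracy by a separable quadratic fit, and corner landmarks
    carry the vector field sampled (bilinearly) at the peak.
    """
    heatmaps = tensor[DET_SLICE]
    fields = tensor[FIELD_SLICE]
    out: list[Landmark] = []
    size = max(2, int(min_separation))
    for k, kind in enumerate(ALL_KINDS):
        hm = heatmaps[k]
        local_max = ndimage.maximum_filter(hm, size=2 * size - 1, mode="constant")
        peaks = np.argwhere((hm >= peak_threshold) & (hm == local_max))
        if len(peaks) > max_peaks:
            order = np.argsort(hm[peaks[:, 0], peaks[:, 1]])[::-1]
            peaks = peaks[order[:max_peaks]]
        for r, c in peaks:
            pos = np.array([float(r), float(c)])
            if 0 < r < hm.shape[0] - 1:
                pos[0] += _subpixel_offset(hm[r - 1:r + 2, c])
            if 0 < c < hm.shape[1] - 1:
                pos[1] += _subpixel_offset(hm[r, c - 1:c + 2])
            pointing = None
            if kind != "centroid":
                pointing = np.array([
                    float(ndimage.map_coordinates(fields[2 * k + i],
                                                  [[pos[0]], [pos[1]]],
                                                  order=1, mode="nearest")[0])
                    for i in range(2)
                ])
            out.append(Landmark(kind=kind, position=pos, score=float(hm[r, c]),
                                pointing=pointing))
    return out


# ---------------------------------------------------------------------------
# Grouping into quadrilaterals
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class QuadDetection:
    slice_index: int
    corners: dict                     # kind -> Landmark
    centroid: Landmark
    completed: dict = field(default_factory=dict)   # kind/"centroid" -> bool
    confidence: float = 0.0

    def corner_array(self) -> np.ndarray:
        """Corners ordered AS, PS, AI, PI as an (4, 2) array."""
        return np.stack([self.corners[k].position for k in CORNER_KINDS])

    def polygon(self) -> np.ndarray:
        """Simple traversal AS -> PS -> PI -> AI."""
        return self.corner_array()[[0, 1, 3, 2]]

    def width(self) -> float:
        c = self.corners
        top = np.linalg.norm(c["PS"].position - c["AS"].position)
        bot = np.linalg.norm(c["PI"].position - c["AI"].position)
        return float(max(top, bot))


def default_group_tolerance(landmarks: list[Landmark]) -> float:
    """Half the typical inter-centroid spacing; from pointing magnitudes when
    fewer than two centroids are present."""
    centroids = [lm.position for lm in landmarks if lm.kind == "centroid"]
    if len(centroids) >= 2:
        pts = np.stack(centroids)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        return 0.5 * float(np.median(d.min(axis=1)))
    mags = [np.linalg.norm(lm.pointing) for lm in landmarks
            if lm.pointing is not None]
    return float(np.median(mags)) if mags else 5.0


def complete_missing_corner(corners: dict, centroid_pos: np.ndarray,
                            missing_kind: str) -> np.ndarray:
    """Infer a missing corner by point-reflecting its diagonal opposite
    through the centroid (exact for parallelograms)."""
    if len(corners) != 3 or missing_kind in corners:
        raise ValueError("completion needs exactly the 3 other corners")
    opp = OPPOSITE[missing_kind]
    if opp not in corners:
        raise ValueError(f"cannot complete {missing_kind}: opposite corner "
                         f"{opp} also missing")
    opp_pos = corners[opp].position if isinstance(corners[opp], Landmark) \
        else np.asarray(corners[opp], dtype=float)
    return 2.0 * np.asarray(centroid_pos, dtype=float) - opp_pos


def infer_centroid(corners: list[Landmark], tolerance: float) -> Landmark | None:
    """From four unassigned corners (one per kind) whose pointing endpoints
    mutually agree within `tolerance`, infer the missed centroid."""
    if len(corners) != 4 or {c.kind for c in corners} != set(CORNER_KINDS):
        return None
    endpoints = np.stack([c.endpoint() for c in corners])
    d = np.linalg.norm(endpoints[:, None] - endpoints[None], axis=-1)
    if d.max() > tolerance:
        return None
    return Landmark(kind="centroid", position=endpoints.mean(axis=0),
                    score=float(np.mean([c.score for c in corners])))


def group_landmarks(landmarks: list[Landmark], slice_index: int = 0,
                    tolerance: float | None = None) -> list[QuadDetection]:
    """Group landmarks of one slice into vertebra quadrilaterals.

    Every (corner, centroid) pair of matching-capacity is scored by the
    pointing error e = ||corner + pointing - centroid|| and accepted greedily
    in increasing e under uniqueness (a corner joins one centroid; a centroid
    takes at most one corner per kind).  Pairs with e > tolerance stay
    unassigned.  Centroids ending with 3 corners are completed by point
    reflection; with fewer they are dropped.  Finally, fully-unassigned corner
    quadruples with mutually agreeing endpoints yield inferred centroids.
    """
    if tolerance is None:
        tolerance = default_group_tolerance(landmarks)
    centroids = [lm for lm in landmarks if lm.kind == "centroid"]
    corners = [lm for lm in landmarks if lm.kind != "centroid"]

    pairs = []
    for ci, cen in enumerate(centroids):
        for pi, cor in enumerate(corners):
            e = float(np.linalg.norm(cor.endpoint() - cen.position))
            if e <= tolerance:
                pairs.append((e, ci, pi))
    pairs.sort(key=lambda t: t[0])
    corner_used = [False] * len(corners)
    assignment: dict[int, dict] = {ci: {} for ci in range(len(centroids))}
    for e, ci, pi in pairs:
        kind = corners[pi].kind
        if corner_used[pi] or kind in assignment[ci]:
            continue
        corner_used[pi] = True
        assignment[ci][kind] = corners[pi]

    quads: list[QuadDetection] = []
    for ci, cen in enumerate(centroids):
        got = assignment[ci]
        if len(got) < 3:
            for lm in got.values():     # release corners of dropped quads
                corner_used[corners.index(lm)] = False
            continue
        completed = {k: False for k in CORNER_KINDS}
        completed["centroid"] = False
        if len(got) == 3:
            missing = next(k for k in CORNER_KINDS if k not in got)
            pos = complete_missing_corner(got, cen.position, missing)
            got = dict(got)
            got[missing] = Landmark(kind=missing, position=pos, score=cen.score,
                                    pointing=cen.position - pos)
            completed[missing] = True
        conf = float(np.mean([lm.score for lm in got.values()] + [cen.score]))
        quads.append(QuadDetection(slice_index=slice_index, corners=got,
                                   centroid=cen, completed=completed,
                                   confidence=conf))

    # robust recovery of missed centroids from leftover corner quadruples
    leftovers = [corners[i] for i in range(len(corners)) if not corner_used[i]]
    by_kind = {k: [c for c in leftovers if c.kind == k] for k in CORNER_KINDS}
    while all(by_kind[k] for k in CORNER_KINDS):
        seed = by_kind["AS"].pop(0)
        group = [seed]
        ok = True
        for k in ("PS", "AI", "PI"):
            cands = by_kind[k]
            dists = [np.linalg.norm(c.endpoint() - seed.endpoint()) for c in cands]
            j = int(np.argmin(dists))
            if dists[j] > tolerance:
                ok = False
                break
            group.append(cands.pop(j))
        if not ok:
            continue
        cen = infer_centroid(group, tolerance)
        if cen is None:
            continue
        completed = {k: False for k in CORNER_KINDS}
        completed["centroid"] = True
        quads.append(QuadDetection(
            slice_index=slice_index,
            corners={c.kind: c for c in group},
            centroid=cen,
            completed=completed,
            confidence=float(np.mean([c.score for c in group])),
        ))
    return quads


# ---------------------------------------------------------------------------
# Patch splitting / merging
# ---------------------------------------------------------------------------

def _patch_offsets(extent_mm: float, edge_mm: float, stride_mm: float) -> list[float]:
    if extent_mm <= edge_mm:
        return [0.0]
    n = int(math.ceil((extent_mm - edge_mm) / stride_mm)) + 1
    return [i * stride_mm for i in range(n)]


def split_into_patches(scan: SagittalScan, slice_index: int,
                       edge_cm: float = 50.0, overlap: float = 0.4,
                       out_px: int = 224) -> list[tuple[np.ndarray, PatchAffine]]:
    """Tile one slice into overlapping square physical windows.

    Windows have edge `edge_cm` (50 cm default, about twice a lumbar field of
    view) and stride (1 - overlap) * edge; a slice smaller than one window
    yields a single patch.  Out-of-scan area is zero-padded by the resampler.
    """
    edge_mm = edge_cm * 10.0
    stride_mm = edge_mm * (1.0 - overlap)
    height_mm, width_mm = scan.extent_mm()
    patches = []
    for top in _patch_offsets(height_mm, edge_mm, stride_mm):
        for left in _patch_offsets(width_mm, edge_mm, stride_mm):
            pixels, affine = resample_patch(
                scan, slice_index, (top, left, edge_mm, edge_mm), out_px)
            patches.append((pixels, affine))
    return patches


def merge_patch_landmarks(per_patch: list[list[Landmark]],
                          affines: list[PatchAffine],
                          pixel_spacing_mm: tuple[float, float],
                          dup_radius_mm: float = 3.0) -> list[Landmark]:
    """Map per-patch landmarks into scan pixel coordinates and merge
    duplicates detected in overlapping patches (same kind within
    `dup_radius_mm`, keeping the higher score)."""
    mapped: list[Landmark] = []
    for landmarks, aff in zip(per_patch, affines):
        scale = np.asarray(aff.scale)
        for lm in landmarks:
            pos = aff.patch_to_scan(lm.position)[0]
            pointing = None if lm.pointing is None else lm.pointing * scale
            mapped.append(Landmark(kind=lm.kind, position=pos, score=lm.score,
                                   pointing=pointing))
    mapped.sort(key=lambda lm: -lm.score)
    spacing = np.asarray(pixel_spacing_mm)
    kept: list[Landmark] = []
    for lm in mapped:
        dup = False
        for other in kept:
            if other.kind != lm.kind:
                continue
            if np.linalg.norm((other.position - lm.position) * spacing) <= dup_radius_mm:
                dup = True
                break
        if not dup:
            kept.append(lm)
    return kept


# ---------------------------------------------------------------------------
# IOU and cross-slice stacking
# ---------------------------------------------------------------------------

def polygon_iou(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    """Intersection-over-union of two simple polygons given as (N, 2) arrays."""
    pa = Polygon(np.asarray(poly_a, dtype=float))
    pb = Polygon(np.asarray(poly_b, dtype=float))
    if not pa.is_valid:
        pa = pa.buffer(0)
    if not pb.is_valid:
        pb = pb.buffer(0)
    if pa.area <= 0 or pb.area <= 0:
        return 0.0
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return float(inter / union) if union > 0 else 0.0


@dataclass(eq=False)
class VertebraInstance:
    quads: list[QuadDetection]                 # consecutive slices, sorted
    level: str | None = None

    @property
    def slice_indices(self) -> list[int]:
        return [q.slice_index for q in self.quads]

    @property
    def central_quad(self) -> QuadDetection:
        return self.quads[len(self.quads) // 2]

    def centroid_px(self) -> np.ndarray:
        """(slice, row, col) mean centroid over slices."""
        rc = np.mean([q.centroid.position for q in self.quads], axis=0)
        return np.array([float(np.mean(self.slice_indices)), rc[0], rc[1]])

    def centroid_mm(self, scan: SagittalScan) -> np.ndarray:
        s, r, c = self.centroid_px()
        return np.array([s * scan.slice_spacing_mm,
                         r * scan.pixel_spacing_mm[0],
                         c * scan.pixel_spacing_mm[1]])

    def height_interval(self) -> tuple[float, float]:
        """[y_a, y_b) in rows on the central slice."""
        corners = self.central_quad.corner_array()
        return float(corners[:, 0].min()), float(corners[:, 0].max())

    def confidence(self) -> float:
        return float(np.mean([q.confidence for q in self.quads]))


def _greedy_match(prev_quads: list[QuadDetection],
                  next_quads: list[QuadDetection],
                  iou_threshold: float) -> list[tuple[int, int]]:
    cand = []
    for i, qa in enumerate(prev_quads):
        for j, qb in enumerate(next_quads):
            iou = polygon_iou(qa.polygon(), qb.polygon())
            if iou >= iou_threshold:
                dist = float(np.linalg.norm(qa.centroid.position - qb.centroid.position))
                cand.append((-iou, dist, i, j))
    cand.sort()
    used_a, used_b = set(), set()
    matches = []
    for _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def stack_slices(quads_by_slice: dict[int, list[QuadDetection]],
                 iou_threshold: float = 0.5) -> list[VertebraInstance]:
    """Stack per-slice quads into 3-D vertebra instances.

    Instances are seeded on the slice with the most detections and extended
    slice-by-slice outward; a quad attaches to the instance whose quad on the
    adjacent slice overlaps it most (IOU >= threshold, one-to-one, greedy by
    IOU then centroid distance).  Unattached quads start new instances.
    """
    slices = sorted(s for s, qs in quads_by_slice.items() if qs)
    if not slices:
        return []
    seed = max(slices, key=lambda s: len(quads_by_slice[s]))
    instances: list[VertebraInstance] = [
        VertebraInstance(quads=[q]) for q in quads_by_slice[seed]]

    def extend(order: list[int]):
        prev = seed
        for s in order:
            if s not in quads_by_slice:
                prev = s
                continue
            frontier = {}
            for idx, inst in enumerate(instances):
                for q in inst.quads:
                    if q.slice_index == prev:
                        frontier[idx] = q
            keys = list(frontier.keys())
            matches = _greedy_match([frontier[k] for k in keys],
                                    quads_by_slice[s], iou_threshold)
            attached = set()
            for i, j in matches:
                instances[keys[i]].quads.append(quads_by_slice[s][j])
                attached.add(j)
            for j, q in enumerate(quads_by_slice[s]):
                if j not in attached:
                    instances.append(VertebraInstance(quads=[q]))
            prev = s

    right = [s for s in range(seed + 1, max(slices) + 1)]
    left = [s for s in range(seed - 1, min(slices) - 1, -1)]
    extend(right)
    extend(left)
    for inst in instances:
        inst.quads.sort(key=lambda q: q.slice_index)
    instances.sort(key=lambda it: it.centroid_px()[1])
    return instances
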