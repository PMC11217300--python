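"""Fully-convolutional detection network for Vector Field Regression.

The contract is a patch-to-13-channel fully-convolutional model: 5 sigmoid
detection channels (corner/centroid heatmaps) and 8 linear grouping channels
(two vector-field components per corner type).  The default profile is a
small encoder-decoder with one downsampling stage and a skip connection,
sized for desk-scale training on 64-px phantom patches; width is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn, vfr


@dataclass
class VFRNetConfig:
    base_channels: int = 12
    patch_px: int = 64
    c_peak: float = 0.2         # sigma = c_peak * sqrt(area), in patch px
    peak_threshold: float = 0.3
    min_separation: int = 4
    group_weight: float = 0.0625   # grouping-loss scale in the composite loss


class VFRNet(nn.Module):
    def __init__(self, rng: np.random.Generator, cfg: VFRNetConfig | None = None):
        self.cfg = cfg or VFRNetConfig()
        c = self.cfg.base_channels
        self.conv1 = nn.Conv2d(1, c, 3, rng)
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng, stride=2)
        self.conv3 = nn.Conv2d(2 * c, 2 * c, 3, rng)
        self.conv3b = nn.Conv2d(2 * c, 2 * c, 3, rng)
        self.conv4 = nn.Conv2d(3 * c, c, 3, rng)
        self.head = nn.Conv2d(c, 13, 3, rng)

    def __call__(self, images: np.ndarray) -> nn.Tensor:
        """images (N, H, W) in [0,1] -> (N, 13, H, W); detection channels
        sigmoid-activated, field channels linear."""
        x = nn.Tensor(images[:, None, :, :])
        e1 = self.conv1(x).relu()
        d = self.conv2(e1).relu()
        d = self.conv3(d).relu()
        d = self.conv3b(d).relu()
        u = d.upsample2x()
        h = self.conv4(nn.concat([u, e1], axis=1)).relu()
        out = self.head(h)
        det = out[:, :5].sigmoid()
        return nn.concat([det, out[:, 5:]], axis=1)


def _training_example(image: np.ndarray,
                      quads: list[tuple[np.ndarray, np.ndarray]],
                      cfg: VFRNetConfig,
                      rng: np.random.Generator | None):
    """Optionally augment (coronal flip, small rotation), then build targets."""
    h, w = image.shape
    if rng is not None:
        if rng.random() < 0.5:      # coronal-plane flip: anterior <-> posterior
            image = image[:, ::-1].copy()
            flipped = []
            for corners, centroid in quads:
                c2 = corners.copy()
                c2[:, 1] = w - 1 - c2[:, 1]
                c2 = c2[[1, 0, 3, 2]]       # AS<->PS, AI<->PI
                flipped.append((c2, np.array([centroid[0], w - 1 - centroid[1]])))
            quads = flipped
        angle = rng.uniform(-8.0, 8.0)
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=float(image.min()))
        th = np.deg2rad(-angle)      # image rotation by +a moves points by -a
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        rotated = []
        for corners, centroid in quads:
            rc = (corners - centre) @ rot.T + centre
            rotated.append((rc, rc.mean(axis=0)))
        quads = rotated
    target, mask = vfr.build_targets(quads, image.shape, c_peak=cfg.c_peak)
    weights = vfr.detect_weights(target[vfr.DET_SLICE])
    return image, target, mask, weights


def train_vfr(net: VFRNet, slices: list[tuple[np.ndarray, list]],
              rng: np.random.Generator, epochs: int = 10, batch_size: int = 1,
              lr: float = 1e-3, augment: bool = True) -> list[float]:
    """Train on (image, quads) slices with the composite detection loss:
    class-balanced L1 on the heatmaps plus squared field error on the corner
    neighbourhoods."""
    opt = nn.Adam(net.parameters(), lr=lr, betas=(0.9, 0.999))
    history = []
    n = len(slices)
    cfg = net.cfg
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            imgs, tgts, masks, wts = [], [], [], []
            for i in idx:
                image, quads = slices[i]
                image, target, mask, weights = _training_example(
                    image, quads, cfg, rng if augment else None)
                imgs.append(image)
                tgts.append(target)
                masks.append(mask)
                wts.append(weights)
            images = np.stack(imgs)
            target = np.stack(tgts)
            fmask = np.stack(masks)
            weight = np.stack(wts)
            # expand corner mask (N,4,H,W) to field channels (N,8,H,W)
            fmask8 = np.repeat(fmask, 2, axis=1)
            pred = net(images)
            det_err = (pred[:, :5] - nn.Tensor(target[:, :5])).abs()
            det_loss = (det_err * nn.Tensor(weight)).sum()
            f_err = pred[:, 5:] - nn.Tensor(target[:, 5:])
            grp_loss = (f_err * f_err * nn.Tensor(fmask8.astype(float))).sum()
            loss = (det_loss + grp_loss * cfg.group_weight) * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        history.append(total / max(1, (n + batch_size - 1) // batch_size))
    return history


def detect_slice(net: VFRNet, image: np.ndarray,
                 slice_index: int = 0) -> list[vfr.QuadDetection]:
    """Run the network on one (already resampled) patch and group the
    resulting landmarks into quadrilaterals."""
    tensor = net(image[None]).data[0]
    landmarks = vfr.extract_landmarks(tensor,
                                      peak_threshold=net.cfg.peak_threshold,
                                      min_separation=net.cfg.min_separation)
    return vfr.group_landmarks(landmarks, slice_index=slice_index)


def detect_slice_landmarks(net: VFRNet, image: np.ndarray) -> list[vfr.Landmark]:
    tensor = net(image[None]).data[0]
    return vfr.extract_landmarks(tensor, peak_threshold=net.cfg.peak_threshold,
                                 min_separation=net.cfg.min_separation)


# ---------------------------------------------------------------------------
# Detection metrics (centroid-containment criterion)
# ---------------------------------------------------------------------------

def match_detections(detections: list[vfr.QuadDetection],
                     truth_quads: list[tuple[np.ndarray, np.ndarray]]
                     ) -> tuple[int, int, list[float]]:
    """A truth vertebra counts as detected when its centroid lies inside
    exactly one detected quadrilateral; a detection is correct when it
    contains exactly one truth centroid.  Returns (n_correct_truth,
    n_correct_detections, centroid errors in px for matched pairs)."""
    from shapely.geometry import Point, Polygon

    polys = [Polygon(d.polygon()) for d in detections]
    contain = np.zeros((len(truth_quads), len(detections)), dtype=bool)
    for ti, (_, centroid) in enumerate(truth_quads):
        pt = Point(centroid)
        for di, poly in enumerate(polys):
            contain[ti, di] = poly.contains(pt)
    correct_truth = 0
    errors = []
    for ti in range(len(truth_quads)):
        hits = np.flatnonzero(contain[ti])
        if len(hits) == 1:
            correct_truth += 1
            d = detections[hits[0]]
            errors.append(float(np.linalg.norm(
                d.centroid.position - truth_quads[ti][1])))
    correct_det = sum(1 for di in range(len(detections))
                      if contain[:, di].sum() == 1)
    return correct_truth, correct_det, errors


def evaluate_detection(net: VFRNet, phantoms: list) -> dict:
    """Precision/recall/localisation error over (scan, truth) phantoms,
    evaluated on the central slice resampled to the network patch size."""
    from .synthetic import truth_slice_quads

    n_truth = n_det = tp_truth = tp_det = 0
    errors: list[float] = []
    for scan, truth in phantoms:
        s = scan.n_slices // 2
        image, quads = prepare_slice(scan, truth, s, net.cfg.patch_px)
        dets = detect_slice(net, image, slice_index=s)
        ct, cd, err = match_detections(dets, quads)
        n_truth += len(quads)
        n_det += len(dets)
        tp_truth += ct
        tp_det += cd
        errors.extend(err)
    return {
        "recall": tp_truth / max(1, n_truth),
        "precision": tp_det / max(1, n_det),
        "mean_centroid_error_px": float(np.mean(errors)) if errors else float("nan"),
        "n_truth": n_truth,
        "n_detections": n_det,
    }


def prepare_slice(scan, truth, slice_index: int, patch_px: int):
    """Resample one phantom slice (whole field of view) to the network patch
    size and map its truth quads into patch coordinates."""
    from .scan_io import resample_patch
    from .synthetic import truth_slice_quads

    height_mm, width_mm = scan.extent_mm()
    edge = max(height_mm, width_mm)
    image, affine = resample_patch(scan, slice_index, (0.0, 0.0, edge, edge),
                                   patch_px, order=3)
    quads = []
    for corners, centroid in truth_slice_quads(truth, slice_index):
        pc = affine.scan_to_patch(corners)
        quads.append((pc, pc.mean(axis=0)))
    return np.clip(image, 0.0, 1.0), quads
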