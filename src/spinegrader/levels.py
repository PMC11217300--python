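"""Anatomical level labelling of detected vertebrae (C3..S1).

Labelling combines two sources of evidence, mirroring how a radiologist
works: the *appearance* of each vertebra (a small classifier on a volume
extracted around the detection) and its *context* (the spatial configuration
of neighbouring detections).  Appearance predictions are written into a
probability-height map P (scan height x 23 levels), refined by a 1-D
convolutional context network along the height axis, and finally decoded
into a valid strictly-descending sequence of levels by a penalised beam
search, with soft penalties for skipped detections and transitional
(lumbosacral numeric-variant) anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .scan_io import SagittalScan
from .vfr import VertebraInstance

#: the 23-level ladder, superior -> inferior
LADDER = ["C3", "C4", "C5", "C6", "C7",
          "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10",
          "T11", "T12",
          "L1", "L2", "L3", "L4", "L5", "S1"]
LEVEL_INDEX = {name: i for i, name in enumerate(LADDER)}
N_LEVELS = len(LADDER)

#: virtual transitional slot (an extra lumbar vertebra between L5 and S1);
#: its ladder position is half-way so that crossing it is never a "skip"
VIRTUAL_LEVEL = "L6"
VIRTUAL_POS = LEVEL_INDEX["L5"] + 0.5


def level_index(name: str) -> int:
    return LEVEL_INDEX[name]


# ---------------------------------------------------------------------------
# Appearance volumes
# ---------------------------------------------------------------------------

def extract_appearance_volume(scan: SagittalScan, instance: VertebraInstance,
                              out_shape: tuple[int, int, int] = (224, 224, 16),
                              expansion: float = 0.5) -> np.ndarray:
    """Extract the classification volume around one vertebra instance.

    A tight 3-D cuboid around the instance is expanded by `expansion` of its
    extent in each direction (default 50%), square-padded in-plane so the
    in-plane resampling is isotropic (the sagittal axis is resampled to the
    requested slice count without isotropy), and zero-padded where it leaves
    the scan.
    """
    if not instance.quads:
        raise ValueError("empty instance")
    corners = np.concatenate([q.corner_array() for q in instance.quads])
    r0, r1 = corners[:, 0].min(), corners[:, 0].max()
    c0, c1 = corners[:, 1].min(), corners[:, 1].max()
    s_idx = instance.slice_indices
    s0, s1 = float(min(s_idx)), float(max(s_idx)) + 1.0
    dr, dc, ds = (r1 - r0) * expansion, (c1 - c0) * expansion, \
        (s1 - s0) * expansion
    r0, r1 = r0 - dr, r1 + dr
    c0, c1 = c0 - dc, c1 + dc
    s0, s1 = s0 - ds, s1 + ds
    # square-pad in-plane (preserves the vertebra's aspect ratio)
    h_mm = (r1 - r0) * scan.pixel_spacing_mm[0]
    w_mm = (c1 - c0) * scan.pixel_spacing_mm[1]
    if h_mm > w_mm:
        pad = (h_mm - w_mm) / 2.0 / scan.pixel_spacing_mm[1]
        c0, c1 = c0 - pad, c1 + pad
    else:
        pad = (w_mm - h_mm) / 2.0 / scan.pixel_spacing_mm[0]
        r0, r1 = r0 - pad, r1 + pad
    nr, nc, ns = out_shape
    rows = np.linspace(r0, r1, nr)
    cols = np.linspace(c0, c1, nc)
    slices = np.linspace(s0, s1 - 1.0, ns)
    gs, gr, gc = np.meshgrid(slices, rows, cols, indexing="ij")
    vol = ndimage.map_coordinates(scan.voxels.astype(np.float64),
                                  np.stack([gs.ravel(), gr.ravel(), gc.ravel()]),
                                  order=1, mode="constant", cval=0.0)
    return vol.reshape(ns, nr, nc).transpose(1, 2, 0)   # (rows, cols, slices)


# ---------------------------------------------------------------------------
# Appearance network (tiny profile)
# ---------------------------------------------------------------------------

class AppearanceNet(nn.Module):
    """Small convolutional 23-way vertebra-level classifier.

    The input volume is averaged across slices and resampled to
    ``in_px x in_px`` before the convolutional stack; this keeps desk-scale
    training cheap while preserving the in-plane shape cues (aspect ratio,
    neighbour spacing) the classifier relies on.
    """

    def __init__(self, rng: np.random.Generator, in_px: int = 32,
                 channels: tuple[int, int] = (8, 16), hidden: int = 64):
        self.in_px = in_px
        c1, c2 = channels
        self.conv1 = nn.Conv2d(1, c1, 3, rng, stride=2)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng, stride=2)
        q = in_px // 4
        self.fc1 = nn.Linear(q * q * c2, hidden, rng)
        self.fc2 = nn.Linear(hidden, N_LEVELS, rng)
        self._flat = q * q * c2

    def preprocess(self, volume: np.ndarray) -> np.ndarray:
        img = volume.mean(axis=2) if volume.ndim == 3 else volume
        if img.shape != (self.in_px, self.in_px):
            img = ndimage.zoom(img, (self.in_px / img.shape[0],
                                     self.in_px / img.shape[1]), order=1)
        return img

    def __call__(self, volumes: np.ndarray) -> nn.Tensor:
        """volumes: (N, in_px, in_px) preprocessed images -> (N, 23) logits."""
        x = nn.Tensor(volumes[:, None, :, :])
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        n = volumes.shape[0]
        h = h.transpose(0, 2, 3, 1).reshape(n, self._flat)
        return self.fc2(self.fc1(h).relu())

    def predict_logits(self, volume: np.ndarray) -> np.ndarray:
        return self(self.preprocess(volume)[None]).data[0]


def train_appearance(net: AppearanceNet, volumes: list[np.ndarray],
                     labels: np.ndarray, rng: np.random.Generator,
                     epochs: int = 30, batch_size: int = 32,
                     lr: float = 1e-3) -> list[float]:
    """Cross-entropy training of the appearance classifier."""
    imgs = np.stack([net.preprocess(v) for v in volumes])
    labels = np.asarray(labels, dtype=int)
    opt = nn.Adam(net.parameters(), lr=lr, betas=(0.9, 0.999))
    history = []
    n = len(labels)
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = net(imgs[idx])
            logp = logits.log_softmax(axis=-1)
            loss = -logp[np.arange(len(idx)), labels[idx]].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        history.append(total / n)
    return history


# ---------------------------------------------------------------------------
# Probability-height map
# ---------------------------------------------------------------------------

def band_rows(instance: VertebraInstance, height: int) -> tuple[int, int]:
    """Integer row band [y_c - (y_b-y_a)/2, y_c + (y_b-y_a)/2) of an instance."""
    y_a, y_b = instance.height_interval()
    y_c = 0.5 * (y_a + y_b)
    half = 0.5 * (y_b - y_a)
    lo = int(round(y_c - half))
    hi = int(round(y_c + half))
    return max(0, lo), min(height, max(hi, lo + 1))


def temperature_softmax(logits: np.ndarray, temperature: float = 0.1) -> np.ndarray:
    z = np.asarray(logits, dtype=float) / temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_prob_height_map(instances: list[VertebraInstance],
                          logits: np.ndarray, height: int,
                          temperature: float = 0.1) -> np.ndarray:
    """Write temperature-softmaxed appearance predictions onto height bands.

    Overlapping bands are combined by element-wise max and re-normalised per
    row; rows outside every band are zero.  Returns (height, 23).
    """
    p_map = np.zeros((height, N_LEVELS), dtype=np.float64)
    for inst, lg in zip(instances, logits):
        _, y_b = inst.height_interval()
        if y_b > height:
            raise ValueError("scan height smaller than an instance band")
        lo, hi = band_rows(inst, height)
        probs = temperature_softmax(lg, temperature)
        np.maximum(p_map[lo:hi], probs[None, :], out=p_map[lo:hi])
    sums = p_map.sum(axis=1, keepdims=True)
    np.divide(p_map, sums, out=p_map, where=sums > 0)
    return p_map


# ---------------------------------------------------------------------------
# Context network (1-D encoder-decoder along the height axis)
# ---------------------------------------------------------------------------

class ContextNet(nn.Module):
    """Height-axis encoder-decoder refining the probability-height map.

    Works on (H, 23) maps as (1, 23, H, 1) images; the receptive field spans
    several vertebral bands so a detection's level can be inferred from its
    neighbours even when its own band was zeroed.
    """

    def __init__(self, rng: np.random.Generator, width: int = 32, k: int = 9):
        self.enc1 = nn.Conv2d(N_LEVELS, width, 1, rng)
        self.enc1b = _Conv1dRows(width, width, k, rng)
        self.down = _Conv1dRows(width, width, k, rng, stride=2)
        self.mid = _Conv1dRows(width, width, k, rng)
        self.dec = _Conv1dRows(2 * width, width, k, rng)
        self.out = nn.Conv2d(width, N_LEVELS, 1, rng)

    def __call__(self, p_map: np.ndarray) -> np.ndarray:
        return self.forward_tensor(p_map).data

    def forward_tensor(self, p_map: np.ndarray) -> nn.Tensor:
        h = p_map.shape[0]
        # pad height to a multiple of 2 for the down/up path
        hp = h + (h % 2)
        x = np.zeros((1, N_LEVELS, hp, 1))
        x[0, :, :h, 0] = p_map.T
        t = nn.Tensor(x)
        e1 = self.enc1b(self.enc1(t).relu()).relu()
        d = self.down(e1).relu()
        d = self.mid(d).relu()
        u = d.upsample2x()[:, :, :hp, :1]
        cat = nn.concat([u, e1], axis=1)
        y = self.out(self.dec(cat).relu())
        return y[0, :, :h, 0].transpose(1, 0)    # (H, 23) logits

    def refine(self, p_map: np.ndarray) -> np.ndarray:
        """Refined map P': row-softmax of the output logits within detection
        bands (rows where P is non-zero), zero elsewhere."""
        logits = self(p_map)
        active = p_map.sum(axis=1) > 0
        out = np.zeros_like(p_map)
        if active.any():
            z = logits[active]
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            out[active] = e / e.sum(axis=1, keepdims=True)
        return out


class _Conv1dRows(nn.Module):
    """k x 1 convolution over the height axis of an (N, C, H, 1) tensor."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1):
        fan_in = c_in * k
        self.weight = nn.Tensor(
            rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, k, 1)),
            requires_grad=True)
        self.bias = nn.Tensor(np.zeros(c_out), requires_grad=True)
        self.k = k
        self.stride = stride

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        pad = self.k // 2
        n, c, h, w = x.shape
        xp = nn.concat([nn.Tensor(np.zeros((n, c, pad, w))), x,
                        nn.Tensor(np.zeros((n, c, pad, w)))], axis=2)
        return xp.conv2d(self.weight, self.bias, stride=self.stride, padding=0)


def train_context(net: ContextNet, examples: list[tuple[np.ndarray, list[tuple[int, int, int]]]],
                  rng: np.random.Generator, epochs: int = 10,
                  lr: float = 1e-3, band_drop_prob: float = 0.1) -> list[float]:
    """Train the context network on (probability-height map, bands) examples.

    `examples`: list of (P, bands) where bands is a list of
    (row_lo, row_hi, true_level_index).  During training each band is zeroed
    with probability `band_drop_prob` while its loss is kept, teaching the
    network to infer a missing detection's level from its neighbours.
    """
    opt = nn.Adam(net.parameters(), lr=lr, betas=(0.9, 0.999))
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(examples))
        total = 0.0
        for i in order:
            p_map, bands = examples[i]
            p_in = p_map.copy()
            for lo, hi, _lv in bands:
                if rng.random() < band_drop_prob:
                    p_in[lo:hi] = 0.0
            logits = net.forward_tensor(p_in)
            losses = []
            for lo, hi, lv in bands:
                band_logits = logits[lo:hi]
                logp = band_logits.log_softmax(axis=-1)
                losses.append(-logp[:, lv].mean())
            if not losses:
                continue
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            loss = loss * (1.0 / len(losses))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        history.append(total / max(1, len(examples)))
    return history


# ---------------------------------------------------------------------------
# Penalised beam-search decoding
# ---------------------------------------------------------------------------

@dataclass
class LevelSequence:
    labels: list[str]
    score: float
    skip_flags: list[bool] = field(default_factory=list)
    transitional: bool = False


def instance_prob_vectors(p_refined: np.ndarray,
                          instances: list[VertebraInstance]) -> np.ndarray:
    """Per-instance level probabilities: mean of P' rows over the band."""
    height = p_refined.shape[0]
    out = np.zeros((len(instances), N_LEVELS))
    for i, inst in enumerate(instances):
        lo, hi = band_rows(inst, height)
        band = p_refined[lo:hi]
        if band.size:
            out[i] = band.mean(axis=0)
    return out


def beam_search_decode(prob_vectors: np.ndarray,
                       beam_width: int = 50,
                       lambda_skip: float = math.log(0.2),
                       lambda_var: float = math.log(0.1),
                       eps: float = 1e-12) -> LevelSequence:
    """Decode per-instance level probabilities into a valid sequence.

    Instances must be ordered superior -> inferior.  A sequence assigns each
    instance a strictly-descending ladder slot (no repeats); its score is the
    sum of log-probabilities plus soft penalties: a gap of g > 1 levels
    between adjacent instances costs (g-1) * lambda_skip (missed detections),
    and using the virtual transitional slot (an extra lumbar vertebra between
    L5 and S1, emitted as "L6") costs lambda_var.  Standard beam search with
    hypothesis recombination (best hypothesis per (slot, transitional) state)
    and the default width 50 covers every reachable state, so decoding is an
    exact argmax.
    """
    n = prob_vectors.shape[0]
    if n == 0:
        return LevelSequence(labels=[], score=0.0)
    if n > N_LEVELS + 1:
        raise ValueError(f"{n} detections exceed the {N_LEVELS + 1}-slot ladder")
    logp = np.log(np.maximum(prob_vectors, eps))

    # slots: (ladder position, label, emission column)
    slots = [(float(i), LADDER[i], i) for i in range(N_LEVELS)]
    slots.append((VIRTUAL_POS, VIRTUAL_LEVEL, LEVEL_INDEX["L5"]))
    slots.sort(key=lambda s: s[0])

    # hypothesis: (score, labels, slot_pos, used_var, skip_flags)
    beams = []
    for pos, label, col in slots:
        is_var = label == VIRTUAL_LEVEL
        score = logp[0, col] + (lambda_var if is_var else 0.0)
        beams.append((score, [label], pos, is_var, [False]))
    beams = _prune(beams, beam_width)

    for i in range(1, n):
        nxt = []
        for score, labels, pos, used_var, flags in beams:
            for spos, label, col in slots:
                if spos <= pos:
                    continue
                is_var = label == VIRTUAL_LEVEL
                if is_var and used_var:
                    continue
                gap = int(math.ceil(spos - pos))
                pen = (gap - 1) * lambda_skip
                if is_var:
                    pen += lambda_var
                nxt.append((score + logp[i, col] + pen, labels + [label],
                            spos, used_var or is_var, flags + [gap > 1]))
        beams = _prune(nxt, beam_width)
    best = max(beams, key=lambda b: b[0])
    return LevelSequence(labels=best[1], score=float(best[0]),
                         skip_flags=best[4], transitional=best[3])


def _prune(beams: list, beam_width: int) -> list:
    """Hypothesis recombination, then keep the top `beam_width`."""
    by_state: dict[tuple, tuple] = {}
    for b in beams:
        state = (b[2], b[3])
        if state not in by_state or b[0] > by_state[state][0]:
            by_state[state] = b
    kept = sorted(by_state.values(), key=lambda b: -b[0])
    return kept[:beam_width]


def label_instances(scan: SagittalScan, instances: list[VertebraInstance],
                    appearance: AppearanceNet, context: ContextNet | None,
                    volume_shape: tuple[int, int, int] = (64, 64, 4),
                    temperature: float = 0.1,
                    beam_width: int = 50,
                    lambda_skip: float = math.log(0.2),
                    lambda_var: float = math.log(0.1)) -> LevelSequence:
    """Full labelling pass: appearance -> probability-height map -> context
    refinement -> beam search.  Instances are sorted superior->inferior and
    labelled in place (instance.level)."""
    if not instances:
        return LevelSequence(labels=[], score=0.0)
    instances.sort(key=lambda it: it.centroid_px()[1])
    logits = np.stack([
        appearance.predict_logits(
            extract_appearance_volume(scan, inst, out_shape=volume_shape))
        for inst in instances])
    height = scan.shape[1]
    p_map = build_prob_height_map(instances, logits, height, temperature)
    p_ref = context.refine(p_map) if context is not None else p_map
    probs = instance_prob_vectors(p_ref, instances)
    seq = beam_search_decode(probs, beam_width=beam_width,
                             lambda_skip=lambda_skip, lambda_var=lambda_var)
    for inst, label in zip(instances, seq.labels):
        inst.level = label
    return seq
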