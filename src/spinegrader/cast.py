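"""Context-Aware Spinal Transformer (CAST) for per-disc / per-vertebra grading.

Each extracted volume is encoded slice-by-slice by a shared 2-D convolutional
encoder; a learned-query multi-head attention pools the per-slice features
into one token, so any slice count works without architectural change and the
attention weights expose which slices drove the grading.  Tokens from every
unit (disc or vertebra) and every available MR sequence are then summed with
learnt level and sequence embeddings and contextualised by a 2-layer
transformer encoder; tokens belonging to the same unit are merged across
sequences by a final attention-pooling layer, and per-task linear heads
produce class probabilities.

Supervision handles report-derived labels: units labelled "unknown"
contribute no loss; when a task has only a study-level flag, the most
positive prediction across all units is trained toward it (multiple-instance
learning), which reduces exactly to masked cross-entropy whenever unit
labels are known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn

UNKNOWN = -1

SEQUENCE_VOCAB = {"T1w": 0, "T2w": 1, "STIR": 2, "FLAIR": 3, "OTHER": 4}


@dataclass
class GradingTaskSpec:
    name: str
    n_classes: int
    unit: str = "disc"              # "disc" | "vertebra"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("a grading task needs at least 2 classes")


#: the disc-level degenerative grading battery
DISC_TASKS = [
    GradingTaskSpec("pfirrmann", 5),
    GradingTaskSpec("disc_narrowing", 4),
    GradingTaskSpec("ccs", 2),
    GradingTaskSpec("spondylolisthesis", 2),
    GradingTaskSpec("endplate_defect_upper", 2),
    GradingTaskSpec("endplate_defect_lower", 2),
    GradingTaskSpec("marrow_change_upper", 2),
    GradingTaskSpec("marrow_change_lower", 2),
]

#: the vertebra-level spinal-cancer battery
VB_TASKS = [
    GradingTaskSpec("metastasis", 2, unit="vertebra"),
    GradingTaskSpec("fracture", 2, unit="vertebra"),
    GradingTaskSpec("compression", 2, unit="vertebra"),
]


@dataclass
class CastConfig:
    dim: int = 256
    n_heads: int = 4
    ff_dim: int = 512
    n_layers: int = 2
    dropout: float = 0.5
    n_levels: int = 23
    in_px: tuple[int, int] = (56, 112)     # slice resample size fed to encoder
    enc_channels: tuple[int, int, int] = (16, 32, 32)

    @staticmethod
    def tiny() -> "CastConfig":
        return CastConfig(dim=64, n_heads=4, ff_dim=128, dropout=0.1,
                          in_px=(14, 28), enc_channels=(8, 16, 16))


@dataclass(eq=False)
class VolumeToken:
    embedding: nn.Tensor            # (D,)
    level_idx: int
    sequence: str
    slice_weights: np.ndarray       # non-negative, sums to 1


class SliceEncoder(nn.Module):
    """Shared single-channel 2-D convolutional encoder applied per slice."""

    def __init__(self, cfg: CastConfig, rng: np.random.Generator):
        c1, c2, c3 = cfg.enc_channels
        self.conv1 = nn.Conv2d(1, c1, 3, rng, stride=2)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng, stride=2)
        self.conv3 = nn.Conv2d(c2, c3, 3, rng, stride=2)
        self.proj = nn.Linear(c3, cfg.dim, rng)
        self.in_px = cfg.in_px

    def preprocess(self, volume: np.ndarray) -> np.ndarray:
        """(H, W, S) volume -> (S, h, w) stack at the encoder input size."""
        h, w = self.in_px
        vol = np.moveaxis(np.asarray(volume, dtype=np.float64), 2, 0)
        if vol.shape[1:] != (h, w):
            vol = ndimage.zoom(vol, (1.0, h / vol.shape[1], w / vol.shape[2]),
                               order=1)
        return vol

    def __call__(self, slices: np.ndarray) -> nn.Tensor:
        """(S, h, w) -> (S, D) per-slice features."""
        x = nn.Tensor(slices[:, None, :, :])
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        feat = h.mean(axis=(2, 3))          # global average pool -> (S, C)
        return self.proj(feat)


class CastModel(nn.Module):
    def __init__(self, tasks: list[GradingTaskSpec], rng: np.random.Generator,
                 cfg: CastConfig | None = None):
        self.cfg = cfg or CastConfig()
        self.tasks = list(tasks)
        self.encoder = SliceEncoder(self.cfg, rng)
        self.slice_pool = nn.AttentionPool(self.cfg.dim, self.cfg.n_heads, rng)
        self.level_emb = nn.Embedding(self.cfg.n_levels, self.cfg.dim, rng)
        self.seq_emb = nn.Embedding(len(SEQUENCE_VOCAB), self.cfg.dim, rng)
        self.layers = [nn.TransformerEncoderLayer(self.cfg.dim, self.cfg.n_heads,
                                                  self.cfg.ff_dim, rng,
                                                  dropout=self.cfg.dropout)
                       for _ in range(self.cfg.n_layers)]
        self.cross_pool = nn.ConvexAttentionPool(self.cfg.dim, self.cfg.n_heads, rng)
        self.heads = [nn.Linear(self.cfg.dim, t.n_classes, rng) for t in tasks]
        self.use_transformer = True      # encoder-only ablation switch

    # -- stages ---------------------------------------------------------------
    def slice_encode_and_pool(self, volume: np.ndarray, level_idx: int,
                              sequence: str) -> VolumeToken:
        slices = self.encoder.preprocess(volume)
        feats = self.encoder(slices)
        pooled, weights = self.slice_pool(feats)
        return VolumeToken(embedding=pooled, level_idx=level_idx,
                           sequence=sequence, slice_weights=weights)

    def transformer_contextualize(self, tokens: list[VolumeToken],
                                  rng: np.random.Generator | None = None
                                  ) -> list[VolumeToken]:
        if not tokens:
            return []
        x = nn.stack([t.embedding for t in tokens], axis=0)
        lev = self.level_emb(np.array([t.level_idx for t in tokens]))
        seq = self.seq_emb(np.array([SEQUENCE_VOCAB.get(t.sequence,
                                                        SEQUENCE_VOCAB["OTHER"])
                                     for t in tokens]))
        x = x + lev + seq
        if self.use_transformer:
            for layer in self.layers:
                x = layer(x, rng)
        out = []
        for i, t in enumerate(tokens):
            out.append(VolumeToken(embedding=x[i], level_idx=t.level_idx,
                                   sequence=t.sequence,
                                   slice_weights=t.slice_weights))
        return out

    def cross_sequence_pool(self, tokens: list[VolumeToken]
                            ) -> dict[int, tuple[nn.Tensor, np.ndarray]]:
        """Merge tokens of the same unit across sequences.

        Returns {level_idx: (embedding, attention weights over that unit's
        tokens)}, ordered by level index.
        """
        groups: dict[int, list[VolumeToken]] = {}
        for t in tokens:
            groups.setdefault(t.level_idx, []).append(t)
        out = {}
        for idx in sorted(groups):
            stackd = nn.stack([t.embedding for t in groups[idx]], axis=0)
            pooled, w = self.cross_pool(stackd)
            out[idx] = (pooled, w)
        return out

    def predict(self, unit_embeddings: dict[int, tuple[nn.Tensor, np.ndarray]]
                ) -> dict[str, dict[int, nn.Tensor]]:
        """Per-task, per-unit class probabilities (softmax of linear heads)."""
        out: dict[str, dict[int, nn.Tensor]] = {t.name: {} for t in self.tasks}
        for idx, (emb, _) in unit_embeddings.items():
            for task, head in zip(self.tasks, self.heads):
                logits = head(emb.reshape(1, -1))
                out[task.name][idx] = logits.softmax(axis=-1).reshape(-1)
        return out

    def forward_study(self, volumes: list[tuple[int, str, np.ndarray]],
                      rng: np.random.Generator | None = None):
        """volumes: (level_idx, sequence, voxels) records for one study.

        Returns (per-task per-unit probabilities, attention record).
        An empty study yields empty predictions (a fully dropped-sequence
        batch is still a defined forward pass).
        """
        tokens = [self.slice_encode_and_pool(v, idx, seq)
                  for idx, seq, v in volumes]
        tokens = self.transformer_contextualize(tokens, rng)
        units = self.cross_sequence_pool(tokens)
        probs = self.predict(units)
        attention = {
            "slice": [(t.level_idx, t.sequence, t.slice_weights.tolist())
                      for t in tokens],
            "cross_sequence": {idx: w.tolist() for idx, (_, w) in units.items()},
        }
        return probs, attention


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def grading_loss(probs: dict[str, dict[int, nn.Tensor]],
                 labels: dict[str, dict[int, int]],
                 study_flags: dict[str, int | None] | None = None,
                 eps: float = 1e-12) -> nn.Tensor:
    """Masked single-instance + multiple-instance grading loss.

    Cross-entropy on units with known labels; UNKNOWN units contribute
    nothing.  For a task whose unit labels are all UNKNOWN but which carries
    a study-level flag, the maximum positive-class probability across units
    is trained toward the flag (cross-entropy on that scalar), so the
    gradient flows only through the most positive unit.
    """
    study_flags = study_flags or {}
    terms: list[nn.Tensor] = []
    for task, unit_probs in probs.items():
        task_labels = labels.get(task, {})
        known = [(idx, task_labels[idx]) for idx in unit_probs
                 if task_labels.get(idx, UNKNOWN) != UNKNOWN]
        if known:
            for idx, lab in known:
                p = unit_probs[idx]
                if not 0 <= lab < p.shape[0]:
                    raise ValueError(f"label {lab} out of range for task {task}")
                terms.append(-((p[lab] + eps).log()))
        elif study_flags.get(task) is not None and unit_probs:
            flag = int(study_flags[task])
            pos = nn.stack([unit_probs[idx][-1] for idx in unit_probs], axis=0)
            most_positive = pos.max()
            target_p = most_positive if flag == 1 else 1.0 - most_positive
            terms.append(-((target_p + eps).log()))
    if not terms:
        return nn.Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def sequence_dropout(volumes: list[tuple[int, str, np.ndarray]],
                     rng: np.random.Generator,
                     p_single: float = 0.4, p_both: float = 0.1):
    """Randomly drop one or both MR sequences of a training study.

    With probability `p_single` one of the two sequences is removed
    (uniformly), with probability `p_both` both are removed (the model then
    predicts from context/level embeddings alone).
    """
    sequences = sorted({seq for _, seq, _ in volumes})
    if len(sequences) < 2:
        return list(volumes)
    u = rng.random()
    if u < p_both:
        return []
    if u < p_both + p_single:
        drop = sequences[int(rng.integers(0, len(sequences)))]
        return [v for v in volumes if v[1] != drop]
    return list(volumes)


def balanced_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-class recall; UNKNOWN labels excluded, absent classes skipped
    with a warning."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    keep = labels != UNKNOWN
    predictions, labels = predictions[keep], labels[keep]
    if labels.size == 0:
        raise ValueError("no labelled examples")
    recalls = []
    for cls in np.unique(labels):
        mask = labels == cls
        recalls.append(float(np.mean(predictions[mask] == cls)))
    n_classes_seen = len(np.unique(labels))
    if n_classes_seen < 2:
        warnings.warn("a class is absent from the labels; it is excluded "
                      "from the balanced accuracy")
    return float(np.mean(recalls))


def binarize_ccs(grade: int) -> int:
    """Collapse the 4-point central-canal-stenosis scale: 1 = none -> 0;
    2-4 (mild/moderate/severe) -> 1."""
    if grade not in (1, 2, 3, 4):
        raise ValueError(f"CCS grade must be in 1..4, got {grade}")
    return 0 if grade == 1 else 1


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

AUGMENT_BOUNDS = {
    "rotation_deg": 15.0,
    "translation_px": 32.0,     # at the native 224-px scale
    "scale_frac": 0.10,
    "intensity_frac": 0.10,
}


def sample_augmentation(rng: np.random.Generator) -> dict[str, float]:
    return {
        "rotation_deg": rng.uniform(-AUGMENT_BOUNDS["rotation_deg"],
                                    AUGMENT_BOUNDS["rotation_deg"]),
        "translation_px": rng.uniform(-AUGMENT_BOUNDS["translation_px"],
                                      AUGMENT_BOUNDS["translation_px"]),
        "scale_frac": rng.uniform(-AUGMENT_BOUNDS["scale_frac"],
                                  AUGMENT_BOUNDS["scale_frac"]),
        "intensity_frac": rng.uniform(-AUGMENT_BOUNDS["intensity_frac"],
                                      AUGMENT_BOUNDS["intensity_frac"]),
    }


def augment_volume(volume: np.ndarray, params: dict[str, float]) -> np.ndarray:
    """Apply a sampled per-vertebra augmentation to an (H, W, S) volume."""
    h = volume.shape[0]
    shift = params["translation_px"] * h / 224.0
    out = np.empty_like(volume, dtype=np.float64)
    for s in range(volume.shape[2]):
        img = ndimage.rotate(volume[:, :, s], params["rotation_deg"],
                             reshape=False, order=1, mode="nearest")
        img = ndimage.shift(img, (shift, shift), order=1, mode="nearest")
        zoom = 1.0 + params["scale_frac"]
        zoomed = ndimage.zoom(img, zoom, order=1)
        if zoomed.shape[0] >= img.shape[0]:
            a = (zoomed.shape[0] - img.shape[0]) // 2
            b = (zoomed.shape[1] - img.shape[1]) // 2
            zoomed = zoomed[a:a + img.shape[0], b:b + img.shape[1]]
        else:
            pad_r = img.shape[0] - zoomed.shape[0]
            pad_c = img.shape[1] - zoomed.shape[1]
            zoomed = np.pad(zoomed, ((pad_r // 2, pad_r - pad_r // 2),
                                     (pad_c // 2, pad_c - pad_c // 2)),
                            mode="edge")
        out[:, :, s] = zoomed * (1.0 + params["intensity_frac"])
    return out


# ---------------------------------------------------------------------------
# Label file IO
# ---------------------------------------------------------------------------

def read_labels_csv(path, tasks: list[GradingTaskSpec],
                    flags_path=None) -> tuple[dict, dict]:
    """Read per-unit labels (columns: study, level, task, label) and optional
    study-level flags (columns: study, task, flag).

    "UNKNOWN" labels map to the UNKNOWN sentinel.  The compression task uses
    a default-negative rule: any unit not explicitly labelled is negative
    rather than unknown (severe cord compression is never omitted from a
    report), applied here at load time.
    """
    frame = pd.read_csv(path, dtype=str)
    labels: dict[str, dict[str, dict[str, int]]] = {}
    task_names = {t.name for t in tasks}
    studies = set(frame["study"])
    levels_by_study: dict[str, set] = {}
    for _, row in frame.iterrows():
        if row["task"] not in task_names:
            continue
        value = UNKNOWN if str(row["label"]).upper() == "UNKNOWN" else int(row["label"])
        labels.setdefault(row["study"], {}).setdefault(row["task"], {})[row["level"]] = value
        levels_by_study.setdefault(row["study"], set()).add(row["level"])
    if any(t.name == "compression" for t in tasks):
        for study in studies:
            seen = labels.setdefault(study, {}).setdefault("compression", {})
            for level in levels_by_study.get(study, set()):
                seen.setdefault(level, 0)
    flags: dict[str, dict[str, int]] = {}
    if flags_path is not None:
        fframe = pd.read_csv(flags_path, dtype=str)
        for _, row in fframe.iterrows():
            flags.setdefault(row["study"], {})[row["task"]] = int(row["flag"])
    return labels, flags


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _study_inputs(study):
    """(level_idx, sequence, voxels) records plus per-index labels/flags for a
    study object carrying .volumes [(level_name, level_idx, seq, voxels)],
    .labels {task: {level_name: y}} and .flags {task: flag|None}."""
    volumes = [(idx, seq, vox) for (_, idx, seq, vox) in study.volumes]
    name_by_idx = {idx: name for (name, idx, _, _) in study.volumes}
    labels = {}
    for task, per_level in study.labels.items():
        labels[task] = {idx: per_level.get(name, UNKNOWN)
                        for idx, name in name_by_idx.items()}
    flags = dict(getattr(study, "flags", {}) or {})
    return volumes, labels, flags


def train_cast(model: CastModel, studies: list, rng: np.random.Generator,
               epochs: int = 20, lr: float = 1e-3,
               seq_dropout_p: tuple[float, float] | None = (0.4, 0.1),
               augment: bool = False) -> list[float]:
    """Adam training of a CAST model on grading studies.

    Studies with both sequences are subject to sequence dropout; per-volume
    geometric/intensity augmentation is optional (off by default for the tiny
    desk-scale profile, where volumes are already small).
    """
    opt = nn.Adam(model.parameters(), lr=lr, betas=(0.9, 0.999))
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(studies))
        total, count = 0.0, 0
        for i in order:
            volumes, labels, flags = _study_inputs(studies[i])
            if seq_dropout_p is not None:
                volumes = sequence_dropout(volumes, rng,
                                           p_single=seq_dropout_p[0],
                                           p_both=seq_dropout_p[1])
            if augment:
                volumes = [(idx, seq, augment_volume(v, sample_augmentation(rng)))
                           for idx, seq, v in volumes]
            if not volumes:
                continue
            probs, _ = model.forward_study(volumes, rng)
            n_units = max(1, len(next(iter(probs.values())) if probs else {}))
            loss = grading_loss(probs, labels, flags) * (1.0 / n_units)
            if not loss.requires_grad:
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            count += 1
        history.append(total / max(1, count))
    return history


def predict_studies(model: CastModel, studies: list
                    ) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    """Inference: {task: {(study_id, level_name): class probabilities}}."""
    out: dict[str, dict[tuple[str, str], np.ndarray]] = \
        {t.name: {} for t in model.tasks}
    for study in studies:
        volumes, _, _ = _study_inputs(study)
        name_by_idx = {idx: name for (name, idx, _, _) in study.volumes}
        probs, _ = model.forward_study(volumes, rng=None)
        for task, per_unit in probs.items():
            for idx, p in per_unit.items():
                out[task][(study.study_id, name_by_idx[idx])] = p.data.copy()
    return out


def evaluate_balanced_accuracy(model: CastModel, studies: list,
                               task: str) -> float:
    preds = predict_studies(model, studies)[task]
    pairs = {}      # one prediction per (study, unit), whatever the sequences
    for study in studies:
        for (name, _idx, _seq, _v) in study.volumes:
            lab = study.labels.get(task, {}).get(name, UNKNOWN)
            key = (study.study_id, name)
            if lab == UNKNOWN or key not in preds:
                continue
            pairs[key] = (lab, int(np.argmax(preds[key])))
    y_true = np.array([t for t, _ in pairs.values()])
    y_pred = np.array([p for _, p in pairs.values()])
    return balanced_accuracy(y_pred, y_true)
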