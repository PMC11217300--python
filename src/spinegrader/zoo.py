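"""Training recipes for the tiny desk-scale model profiles.

These functions generate phantom data, train each stage and return the
trained models; they are used by the test suite, the acceptance script and
the CLI's synthetic-demo mode.  All randomness flows from the explicit seed.
"""

from __future__ import annotations

import numpy as np

from . import cast, levels, pipeline, vfr_net
from .scan_io import normalise_intensity
from .synthetic import (PhantomSpec, generate_phantom, instances_from_truth,
                        make_grading_dataset)

DETECT_VARIANTS = ["S1", "L5", "L3"]


def detection_phantoms(n: int, seed: int, noise_sd: float = 0.02) -> list:
    """Mixed-height lumbar/thoracolumbar phantoms for detector training."""
    out = []
    for i in range(n):
        spec = PhantomSpec(n_vertebrae=3 + (i % 6),
                           lowest_level=DETECT_VARIANTS[i % 3],
                           noise_sd=noise_sd, seed=seed + i)
        scan, truth = generate_phantom(spec)
        # match the deployment preprocessing (percentile intensity rescale)
        out.append((normalise_intensity(scan), truth))
    return out


def detection_slices(phantoms: list, patch_px: int = 64,
                     max_slices: int | None = None) -> list:
    slices = []
    for scan, truth in phantoms:
        for s in range(scan.n_slices):
            img, quads = vfr_net.prepare_slice(scan, truth, s, patch_px)
            if quads:
                slices.append((img, quads))
            if max_slices is not None and len(slices) >= max_slices:
                return slices
    return slices


def train_detector(seed: int, n_phantoms: int = 60, n_slices: int = 300,
                   epochs: int = 10) -> vfr_net.VFRNet:
    """Tiny VFR detector: 300 phantom slices, 10 epochs, 64-px patches."""
    phantoms = detection_phantoms(n_phantoms, seed)
    slices = detection_slices(phantoms, max_slices=n_slices)
    net = vfr_net.VFRNet(np.random.default_rng(seed + 1))
    # augmentation off at this problem size: with 10 epochs on 300 slices the
    # phantom variety already covers pose/scale, and warping slows convergence
    vfr_net.train_vfr(net, slices, np.random.default_rng(seed + 2),
                      epochs=epochs, augment=False)
    return net


def labelling_phantoms(n: int, seed: int, noise_sd: float = 0.02) -> list:
    """Phantoms whose level runs cover the whole C3..S1 ladder."""
    out = []
    for i in range(n):
        master = np.random.default_rng(seed + i)
        n_v = int(master.integers(4, 9))
        lowest_idx = int(master.integers(n_v - 1, levels.N_LEVELS))
        spec = PhantomSpec(n_vertebrae=n_v,
                           lowest_level=levels.LADDER[lowest_idx],
                           noise_sd=noise_sd, seed=seed + i)
        scan, truth = generate_phantom(spec)
        out.append((normalise_intensity(scan), truth))
    return out


def train_labeller(seed: int, n_train: int = 400, n_context: int = 120,
                   appearance_epochs: int = 300,
                   context_epochs: int = 16,
                   volume_shape: tuple[int, int, int] = (64, 64, 4)
                   ) -> tuple[levels.AppearanceNet, levels.ContextNet]:
    """Train the appearance classifier, then the context network.

    The context network trains on probability-height maps built from the
    appearance net's predictions on phantoms it never saw: in-sample
    predictions are far cleaner than deployment-time ones, and a context
    net fitted to them degrades rather than refines the maps.
    """
    phantoms = labelling_phantoms(n_train, seed)
    volumes, labels = [], []
    for scan, truth in phantoms:
        insts = instances_from_truth(truth)
        for inst, lv in zip(insts, truth.levels):
            if lv not in levels.LEVEL_INDEX:
                continue
            volumes.append(levels.extract_appearance_volume(
                scan, inst, out_shape=volume_shape))
            labels.append(levels.LEVEL_INDEX[lv])
    appearance = levels.AppearanceNet(np.random.default_rng(seed + 1))
    levels.train_appearance(appearance, volumes, np.array(labels),
                            np.random.default_rng(seed + 2),
                            epochs=appearance_epochs)

    ctx_phantoms = labelling_phantoms(n_context, seed + 500_000)
    examples = []
    for scan, truth in ctx_phantoms:
        insts = instances_from_truth(truth)
        entries = [(inst, levels.LEVEL_INDEX[lv])
                   for inst, lv in zip(insts, truth.levels)
                   if lv in levels.LEVEL_INDEX]
        if not entries:
            continue
        lg = np.stack([appearance.predict_logits(
            levels.extract_appearance_volume(scan, inst,
                                             out_shape=volume_shape))
            for inst, _ in entries])
        height = scan.shape[1]
        p_map = levels.build_prob_height_map([e[0] for e in entries], lg,
                                             height)
        bands = [(*levels.band_rows(inst, height), lv)
                 for inst, lv in entries]
        examples.append((p_map, bands))
    context = levels.ContextNet(np.random.default_rng(seed + 3))
    levels.train_context(context, examples, np.random.default_rng(seed + 4),
                         epochs=context_epochs)
    return appearance, context


def evaluate_labelling(appearance: levels.AppearanceNet,
                       context: levels.ContextNet | None,
                       seed: int, n_phantoms: int = 100,
                       dropped_frac: float = 0.1,
                       volume_shape: tuple[int, int, int] = (64, 64, 4)
                       ) -> dict:
    """Identification rate on held-out phantoms.

    In `dropped_frac` of phantoms one middle detection is removed before
    labelling, exercising the skip penalty; IDR counts exact level matches
    over the instances actually presented, IDR+-1 allows a one-level shift.
    """
    phantoms = labelling_phantoms(n_phantoms, seed)
    master = np.random.default_rng(seed + 7)
    n_exact = n_within1 = n_total = 0
    for scan, truth in phantoms:
        insts = instances_from_truth(truth)
        true_levels = list(truth.levels)
        if master.random() < dropped_frac and len(insts) > 2:
            k = int(master.integers(1, len(insts) - 1))
            insts = insts[:k] + insts[k + 1:]
            true_levels = true_levels[:k] + true_levels[k + 1:]
        seq = levels.label_instances(scan, insts, appearance, context,
                                     volume_shape=volume_shape)
        for pred, true in zip(seq.labels, true_levels):
            if true not in levels.LEVEL_INDEX or pred not in levels.LEVEL_INDEX:
                continue
            diff = abs(levels.LEVEL_INDEX[pred] - levels.LEVEL_INDEX[true])
            n_total += 1
            n_exact += diff == 0
            n_within1 += diff <= 1
    return {"idr": n_exact / max(1, n_total),
            "idr_within1": n_within1 / max(1, n_total),
            "n_vertebrae": n_total}


GRADER_TASKS = [cast.GradingTaskSpec("degeneration", 2),
                cast.GradingTaskSpec("neighbour", 2)]


def train_graders(seed: int, n_train: int = 200, n_test: int = 60,
                  epochs: int = 35) -> tuple:
    """Train tiny CAST and the encoder-only (no transformer) baseline on the
    same grading studies.  Returns (cast_model, baseline, train, test)."""
    train = make_grading_dataset(n_train, seed=seed)
    test = make_grading_dataset(n_test, seed=seed + 10_000)
    model = cast.CastModel(GRADER_TASKS, np.random.default_rng(seed + 1),
                           cast.CastConfig.tiny())
    cast.train_cast(model, train, np.random.default_rng(seed + 2),
                    epochs=epochs)
    baseline = cast.CastModel(GRADER_TASKS, np.random.default_rng(seed + 1),
                              cast.CastConfig.tiny())
    baseline.use_transformer = False
    cast.train_cast(baseline, train, np.random.default_rng(seed + 2),
                    epochs=epochs)
    return model, baseline, train, test


def train_demo_bundle(seed: int = 0, detector_epochs: int = 10,
                      fast: bool = False) -> pipeline.ModelBundle:
    """Train all three stages at the tiny profile and bundle them."""
    if fast:
        detector = train_detector(seed, n_phantoms=40, n_slices=200,
                                  epochs=max(8, detector_epochs))
        appearance, context = train_labeller(seed + 50, n_train=120,
                                             appearance_epochs=80,
                                             context_epochs=6)
        model, _, _, _ = train_graders(seed + 100, n_train=60, n_test=1,
                                       epochs=10)
    else:
        detector = train_detector(seed, epochs=detector_epochs)
        appearance, context = train_labeller(seed + 50)
        model, _, _, _ = train_graders(seed + 100)
    return pipeline.ModelBundle(detector=detector, appearance=appearance,
                                context=context, grader=model)
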