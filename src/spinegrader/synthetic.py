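"""Synthetic spine phantoms with exact ground truth.

Phantoms render a column of bright, mildly sheared/rotated quadrilateral
vertebral bodies separated by disc gaps on a dark background, across a
configurable number of sagittal slices.  Geometry and signal encode the
anatomical level: vertebral bodies grow and their in-plane aspect ratio
falls from cervical to lumbar, marrow signal brightens caudally, and S1 is
strongly sheared — so a classifier can estimate the level from appearance,
as on real scans, while the exact quadrilaterals, levels, disc grades and
lesion flags are known by construction.

Disc brightness decreases monotonically with the synthetic degeneration
grade (strongly on T2w, weakly on T1w), emulating the loss of T2 disc signal
that drives Pfirrmann grading; grading labels derived from these intensities
are therefore learnable from the rendered images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .levels import LADDER, LEVEL_INDEX, N_LEVELS
from .scan_io import SagittalScan, Sequence, normalise_intensity
from .vfr import CORNER_KINDS, Landmark, QuadDetection, VertebraInstance
from .volumes import extract_disc_volume

UNKNOWN = -1


@dataclass
class PhantomSpec:
    """Parameters of one phantom scan.

    The level run is `n_vertebrae` consecutive levels ending (inferiorly) at
    `lowest_level`; e.g. n_vertebrae=6, lowest_level="L5" spans T12..L5.
    """

    n_vertebrae: int = 7
    lowest_level: str = "S1"
    img_shape: tuple[int, int] | None = None       # (rows, cols); None = fit
    vb_height_px: tuple[float, float] = (7.0, 21.0)    # C3 .. S1 ramp
    vb_width_px: tuple[float, float] = (15.0, 17.0)
    disc_gap_px: tuple[float, float] = (3.0, 6.0)
    curvature: float = 0.03
    n_slices: int = 5
    noise_sd: float = 0.02
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_spacing_mm: float = 3.0
    sequence: Sequence = Sequence.T2W
    transitional: str | None = None                # None | "insert" | "delete"
    missing_corner_prob: float = 0.0
    missing_vertebra_prob: float = 0.0
    lesion_prob: float = 0.0
    size_jitter: float = 0.4                       # px, per-vertebra
    seed: int = 0

    def level_run(self) -> list[str]:
        lo = LEVEL_INDEX[self.lowest_level]
        hi = lo - self.n_vertebrae + 1
        if hi < 0:
            raise ValueError("level run extends above C3")
        run = [LADDER[i] for i in range(hi, lo + 1)]
        if self.transitional == "insert" and "L5" in run:
            run = run[:run.index("L5") + 1] + ["L6"] + run[run.index("L5") + 1:]
        elif self.transitional == "delete" and "L5" in run:
            run = [lv for lv in run if lv != "L5"]
        return run


@dataclass
class TruthQuad:
    vertebra: int
    corners: np.ndarray       # (4, 2) ordered AS, PS, AI, PI, (row, col)
    centroid: np.ndarray      # mean of the 4 corners


@dataclass
class PhantomTruth:
    levels: list[str]                          # per vertebra, superior->inferior
    quads_by_slice: list[list[TruthQuad]]      # [slice][vertebra-present]
    disc_grades: list[int]                     # per gap between vertebrae i, i+1
    lesions: list[bool]
    transitional: str | None = None


def _level_t(level: str) -> float:
    """Normalised position of a level on the ladder, 0 = C3, 1 = S1."""
    if level == "L6":
        return 1.0 - 0.5 / (N_LEVELS - 1)
    return LEVEL_INDEX[level] / (N_LEVELS - 1)


def _vb_intensity(t: float, sequence: Sequence) -> float:
    base = 0.45 + 0.45 * t
    return base * (0.92 if sequence == Sequence.T1W else 1.0)


def disc_intensity(grade: int, sequence: Sequence) -> float:
    """Mean disc signal: strongly grade-dependent on T2w, weak on T1w."""
    if sequence == Sequence.T2W:
        return 0.80 - 0.14 * grade
    return 0.44 - 0.02 * grade


def _quad_corners(centre_r: float, centre_c: float, h: float, w: float,
                  angle: float, shear: float) -> np.ndarray:
    local = np.array([
        [-h / 2.0, -w / 2.0],      # AS (anterior = smaller col)
        [-h / 2.0, +w / 2.0],      # PS
        [+h / 2.0, -w / 2.0],      # AI
        [+h / 2.0, +w / 2.0],      # PI
    ])
    local[:2, 1] += shear * h / 2.0        # shear the superior edge
    ca, sa = math.cos(angle), math.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    pts = local @ rot.T + np.array([centre_r, centre_c])
    return pts - (pts.mean(axis=0) - np.array([centre_r, centre_c]))


def generate_phantom(spec: PhantomSpec) -> tuple[SagittalScan, PhantomTruth]:
    """Render one phantom scan; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    run = spec.level_run()
    n = len(run)

    # per-vertebra geometry
    hs, ws, shears, gaps = [], [], [], []
    for lv in run:
        t = _level_t(lv)
        h = spec.vb_height_px[0] + (spec.vb_height_px[1] - spec.vb_height_px[0]) * t
        w = spec.vb_width_px[0] + (spec.vb_width_px[1] - spec.vb_width_px[0]) * t
        h += rng.uniform(-spec.size_jitter, spec.size_jitter)
        w += rng.uniform(-spec.size_jitter, spec.size_jitter)
        shear = 0.55 if lv == "S1" else rng.uniform(-0.08, 0.08)
        hs.append(h)
        ws.append(w)
        shears.append(shear)
    for i in range(n - 1):
        # disc height relative to VB height falls cervical -> lumbar
        t = _level_t(run[i])
        base = hs[i] * (0.45 - 0.22 * t)
        lo, hi = spec.disc_gap_px
        gaps.append(float(np.clip(base + rng.uniform(-0.3, 0.3), lo, hi)))

    margin = 8.0
    total_h = sum(hs) + sum(gaps)
    need_rows = int(math.ceil(total_h + 2 * margin))
    curve_amp = abs(spec.curvature) * (total_h + 2 * margin)
    need_cols = int(math.ceil(max(ws) + 2 * margin + 2 * curve_amp))
    need_cols = max(need_cols, 33)
    need_rows = max(need_rows, 33)
    if spec.img_shape is None:
        rows, cols = need_rows, need_cols
    else:
        rows, cols = spec.img_shape
        if rows < need_rows or cols < need_cols:
            raise ValueError(
                f"field of view too small: need >= {need_rows}x{need_cols}, "
                f"got {rows}x{cols}")

    missing = -1
    if spec.missing_vertebra_prob > 0 and rng.random() < spec.missing_vertebra_prob \
            and n > 2:
        missing = int(rng.integers(1, n - 1))

    # vertical layout (top -> bottom) on the central slice
    centres = []
    y = margin + (rows - need_rows) / 2.0
    for i in range(n):
        y_c = y + hs[i] / 2.0
        tpos = y_c / rows
        x_c = cols / 2.0 + spec.curvature * rows * math.sin(math.pi * tpos)
        centres.append((y_c, x_c))
        y += hs[i] + (gaps[i] if i < n - 1 else 0.0)
    angles = []
    for i in range(n):
        # follow the local curve tangent, plus jitter
        slope = spec.curvature * math.pi * math.cos(math.pi * centres[i][0] / rows)
        angles.append(math.atan(slope) + rng.uniform(-0.035, 0.035))

    disc_grades = [int(rng.integers(0, 5)) for _ in range(n - 1)]
    lesions = [bool(rng.random() < spec.lesion_prob) for _ in range(n)]
    vb_int = [_vb_intensity(_level_t(run[i]), spec.sequence)
              + rng.uniform(-0.01, 0.01) for i in range(n)]
    cut_corner = [[rng.random() < spec.missing_corner_prob for _ in range(4)]
                  for _ in range(n)]

    half_span = max(1, (spec.n_slices - 1) // 2)
    central = spec.n_slices // 2
    voxels = np.full((spec.n_slices, rows, cols), 0.05, dtype=np.float64)
    quads_by_slice: list[list[TruthQuad]] = [[] for _ in range(spec.n_slices)]

    noise = rng.normal(0.0, spec.noise_sd, size=voxels.shape) \
        if spec.noise_sd > 0 else None

    for s in range(spec.n_slices):
        d = s - central
        f = 1.0 - 0.35 * (abs(d) / (half_span + 0.5)) ** 2
        img = voxels[s]
        slice_quads = []
        for i in range(n):
            if i == missing:
                continue
            corners = _quad_corners(centres[i][0], centres[i][1],
                                    hs[i] * f, ws[i] * f, angles[i], shears[i])
            slice_quads.append(TruthQuad(vertebra=i, corners=corners,
                                         centroid=corners.mean(axis=0)))
        # discs first so vertebrae overwrite their edges
        for i in range(n - 1):
            if i == missing or i + 1 == missing:
                continue
            qa = slice_quads_for(slice_quads, i)
            qb = slice_quads_for(slice_quads, i + 1)
            if qa is None or qb is None:
                continue
            band = np.array([
                qa.corners[2] * 0.9 + qa.centroid * 0.1,
                qa.corners[3] * 0.9 + qa.centroid * 0.1,
                qb.corners[1] * 0.9 + qb.centroid * 0.1,
                qb.corners[0] * 0.9 + qb.centroid * 0.1,
            ])
            rr, cc = draw_polygon(band[:, 0], band[:, 1], shape=img.shape)
            img[rr, cc] = disc_intensity(disc_grades[i], spec.sequence)
        for q in slice_quads:
            i = q.vertebra
            poly = q.corners[[0, 1, 3, 2]]
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=img.shape)
            img[rr, cc] = vb_int[i]
            # central marrow notch: its contrast against the VB deepens
            # caudally, a level cue that survives per-scan intensity rescale
            t_i = _level_t(run[i])
            notch = 0.05 + (vb_int[i] - 0.05) * (1.0 - 0.68 * t_i)
            # the notch also drifts inferiorly along the ladder
            off_r = (t_i - 0.5) * 0.35 * hs[i] * f
            nr_, nc_ = draw_disk((q.centroid[0] + off_r, q.centroid[1]),
                                 max(1.0, 0.18 * hs[i] * f), shape=img.shape)
            img[nr_, nc_] = notch
            for ci in range(4):
                if cut_corner[i][ci]:
                    # chop the corner back to background (annotation unchanged)
                    tri = np.array([
                        q.corners[ci],
                        q.corners[ci] * 0.55 + q.centroid * 0.45,
                        q.corners[ci] * 0.75 + q.corners[[1, 0, 3, 2][ci]] * 0.25,
                    ])
                    tr, tc = draw_polygon(tri[:, 0], tri[:, 1], shape=img.shape)
                    img[tr, tc] = 0.05
            if lesions[i]:
                rr, cc = draw_disk((q.centroid[0], q.centroid[1]),
                                   max(1.5, 0.22 * hs[i] * f), shape=img.shape)
                img[rr, cc] = 0.22
        quads_by_slice[s] = slice_quads

    if noise is not None:
        voxels += noise
    np.clip(voxels, 0.0, 1.0, out=voxels)

    scan = SagittalScan(voxels=voxels.astype(np.float32),
                        pixel_spacing_mm=spec.pixel_spacing_mm,
                        slice_spacing_mm=spec.slice_spacing_mm,
                        sequence=spec.sequence,
                        study_id=f"phantom-{spec.seed}")
    truth = PhantomTruth(levels=run, quads_by_slice=quads_by_slice,
                         disc_grades=disc_grades, lesions=lesions,
                         transitional=spec.transitional)
    # renumber truth to present vertebrae only when one was dropped
    if missing >= 0:
        truth = _drop_vertebra(truth, missing)
    return scan, truth


def slice_quads_for(quads: list[TruthQuad], vertebra: int) -> TruthQuad | None:
    for q in quads:
        if q.vertebra == vertebra:
            return q
    return None


def _drop_vertebra(truth: PhantomTruth, idx: int) -> PhantomTruth:
    remap = {}
    levels = []
    for i, lv in enumerate(truth.levels):
        if i == idx:
            continue
        remap[i] = len(levels)
        levels.append(lv)
    quads = [[replace(q, vertebra=remap[q.vertebra]) for q in sl
              if q.vertebra != idx]
             for sl in truth.quads_by_slice]
    grades = [g for i, g in enumerate(truth.disc_grades)
              if i != idx and i != idx - 1]
    lesions = [l for i, l in enumerate(truth.lesions) if i != idx]
    return PhantomTruth(levels=levels, quads_by_slice=quads,
                        disc_grades=grades, lesions=lesions,
                        transitional=truth.transitional)


def truth_slice_quads(truth: PhantomTruth, s: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """(corners, centroid) pairs for one slice, as build_targets expects."""
    return [(q.corners, q.centroid) for q in truth.quads_by_slice[s]]


def instances_from_truth(truth: PhantomTruth,
                         with_levels: bool = False) -> list[VertebraInstance]:
    """Exact vertebra instances built from ground-truth quads."""
    n = len(truth.levels)
    instances = []
    for i in range(n):
        quads = []
        for s, sl in enumerate(truth.quads_by_slice):
            tq = slice_quads_for(sl, i)
            if tq is None:
                continue
            corners = {}
            for ci, kind in enumerate(CORNER_KINDS):
                corners[kind] = Landmark(kind=kind, position=tq.corners[ci].copy(),
                                         score=1.0,
                                         pointing=tq.centroid - tq.corners[ci])
            cen = Landmark(kind="centroid", position=tq.centroid.copy(), score=1.0)
            quads.append(QuadDetection(slice_index=s, corners=corners,
                                       centroid=cen,
                                       completed={k: False for k in
                                                  (*CORNER_KINDS, "centroid")},
                                       confidence=1.0))
        inst = VertebraInstance(quads=quads,
                                level=truth.levels[i] if with_levels else None)
        instances.append(inst)
    return instances


# ---------------------------------------------------------------------------
# Grading dataset
# ---------------------------------------------------------------------------

@dataclass
class GradingStudy:
    study_id: str
    volumes: list                      # (level_name, level_idx, sequence, voxels)
    labels: dict                       # task -> {level_name: class | UNKNOWN}
    flags: dict = field(default_factory=dict)   # task -> 1 | 0 | None
    grades: dict = field(default_factory=dict)  # level_name -> true grade

    def sequences(self) -> set[str]:
        return {seq for (_, _, seq, _) in self.volumes}


#: binary degeneration boundary: grades {2, 3, 4} are "degenerate"
DEGENERATE_FROM_GRADE = 2

GRADING_TASKS = ("degeneration", "neighbour")


def make_grading_dataset(n_studies: int, seed: int,
                         unknown_frac: float = 0.0,
                         study_flag_frac: float = 0.0,
                         drop_seq_prob: float = 0.2,
                         n_vertebrae: int = 7,
                         out_shape: tuple[int, int] = (28, 56),
                         n_slices: int = 3,
                         noise_sd: float = 0.02) -> list[GradingStudy]:
    """Generate lumbar phantom studies with disc volumes and grading labels.

    Each study renders the same geometry as a T2w and a T1w sequence (one of
    the two dropped with probability `drop_seq_prob`) and extracts a disc
    volume per level per sequence.  Two binary tasks are labelled from the
    underlying grades: "degeneration" (the disc's own grade >= 2, visible as
    low disc signal) and "neighbour" (the adjacent disc's grade >= 2, so the
    label of a unit depends on its neighbour's appearance, not its own).
    `unknown_frac` masks labels at random; `study_flag_frac` converts whole
    studies to study-level-only supervision (all unit labels unknown, one
    positive/negative flag) for multiple-instance training.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    master = np.random.default_rng(seed)
    studies = []
    for si in range(n_studies):
        phantom_seed = int(master.integers(0, 2 ** 31 - 1))
        sequences = ["T2w", "T1w"]
        if master.random() < drop_seq_prob:
            sequences = [sequences[int(master.integers(0, 2))]]
        spec = PhantomSpec(n_vertebrae=n_vertebrae, lowest_level="S1",
                           n_slices=n_slices, noise_sd=noise_sd,
                           seed=phantom_seed)
        volumes = []
        truth = None
        for seq_name in sequences:
            seq = Sequence.T2W if seq_name == "T2w" else Sequence.T1W
            scan, truth = generate_phantom(replace(spec, sequence=seq))
            scan = normalise_intensity(scan)   # deployment preprocessing
            instances = instances_from_truth(truth, with_levels=True)
            for i in range(len(instances) - 1):
                upper, lower = instances[i], instances[i + 1]
                disc = extract_disc_volume(scan, upper, lower,
                                           out_shape=out_shape, slice_margin=0)
                level_name = f"{upper.level}/{lower.level}"
                level_idx = LEVEL_INDEX[upper.level]
                volumes.append((level_name, level_idx, seq_name, disc.voxels))
        level_names = [f"{truth.levels[i]}/{truth.levels[i + 1]}"
                       for i in range(len(truth.levels) - 1)]
        grades = dict(zip(level_names, truth.disc_grades))
        deg = {lv: int(grades[lv] >= DEGENERATE_FROM_GRADE) for lv in level_names}
        nb = {}
        for i, lv in enumerate(level_names):
            j = i + 1 if i + 1 < len(level_names) else i - 1
            nb[lv] = deg[level_names[j]]
        labels = {"degeneration": dict(deg), "neighbour": dict(nb)}
        flags = {t: None for t in GRADING_TASKS}
        if master.random() < study_flag_frac:
            flags["degeneration"] = int(any(deg.values()))
            labels["degeneration"] = {lv: UNKNOWN for lv in level_names}
        for task in GRADING_TASKS:
            for lv in level_names:
                if labels[task][lv] != UNKNOWN and master.random() < unknown_frac:
                    labels[task][lv] = UNKNOWN
        studies.append(GradingStudy(study_id=f"study-{si}", volumes=volumes,
                                    labels=labels, flags=flags, grades=grades))
    return studies
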