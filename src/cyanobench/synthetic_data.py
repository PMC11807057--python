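"""Synthetic microscopy fixtures with known ground truth.

Real benchmark movies of cyanobacteria are rarely shareable, so this module
generates the three kinds of inputs the rest of the package consumes, each
with an exact, planted answer:

* **Rod masks** — fields of non-overlapping capsule-shaped unicellular
  cells, emulating dispersed unicellular strains; **filament masks** —
  chains of touching capsule cells with distinct labels, emulating
  filamentous strains where neighboring cells share boundaries.
* **Corruptions** — split / merge / delete / add operators applied to a
  mask with known counts, plus sub-tolerance boundary jitter. The planted
  counts are constructed to be exactly what the object-level error
  evaluator must report, making them a ground-truth oracle for it.
* **Phenotype patches** — 32×32 multi-channel crops of single cells whose
  fluorescence channel follows one of four localization models (no signal,
  diffuse cytoplasmic, multiple puncta, single focus), emulating strains
  with differently localized fluorescent labels.

Every generator is bit-reproducible under a fixed seed. The corruption
operators deliberately confine all pixel edits so that no unplanned overlap
between ground-truth and corrupted objects can arise: split fragments stay
inside the parent footprint, merge bridges and jitter additions are painted
only over joint background, and spurious objects keep a 2-px clearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.segmentation import expand_labels

from .mask_model import ImageStack, LabeledMask, MaskMovie
from .object_errors import ErrorReport

__all__ = [
    "CorruptionPlan",
    "PhenotypeSpec",
    "generate_rod_mask",
    "generate_filament_mask",
    "corrupt_mask",
    "corrupt_movie",
    "default_phenotype_specs",
    "generate_phenotype_dataset",
    "generate_classified_frame",
]


class PlacementError(RuntimeError):
    """Raised when geometry cannot be placed within the attempt budget."""


# --------------------------------------------------------------------------
# mask geometry


def _capsule(center, angle, half_len, radius, shape):
    """Pixel coordinates of a capsule (segment dilated by ``radius``)."""
    cr, cc = center
    dr, dc = np.sin(angle), np.cos(angle)
    reach = half_len + radius + 1
    r0, r1 = int(max(0, cr - reach)), int(min(shape[0], cr + reach + 1))
    c0, c1 = int(max(0, cc - reach)), int(min(shape[1], cc + reach + 1))
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    # distance from each pixel to the central segment
    pr, pc = rr - cr, cc_ - cc
    t = np.clip(pr * dr + pc * dc, -half_len, half_len)
    d2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    inside = d2 <= radius**2
    return rr[inside], cc_[inside]


def _as_shape(image_size) -> tuple[int, int]:
    if np.isscalar(image_size):
        return (int(image_size), int(image_size))
    return (int(image_size[0]), int(image_size[1]))


def generate_rod_mask(
    n_cells: int,
    image_size=256,
    length_px: tuple[float, float] = (12.0, 22.0),
    width_px: tuple[float, float] = (5.0, 8.0),
    seed: int = 0,
    min_gap: int = 2,
    max_attempts: int = 2000,
) -> LabeledMask:
    """Place ``n_cells`` non-overlapping rod-shaped cells at random poses.

    Cells are capsules (rounded rectangles) with total length drawn from
    ``length_px`` and width from ``width_px``; any two cells keep at least
    ``min_gap`` pixels of background between them. Labels are 1..n in
    placement order. Raises :class:`PlacementError` when the field is too
    crowded for the attempt budget.
    """
    shape = _as_shape(image_size)
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{n_cells} cells after {max_attempts} "
                "attempts; reduce n_cells or enlarge the image"
            )
        attempts += 1
        length = rng.uniform(*length_px)
        radius = rng.uniform(*width_px) / 2.0
        half_len = max(length / 2.0 - radius, 0.5)
        margin = half_len + radius + 1
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        angle = rng.uniform(0, np.pi)
        # clearance capsule: inflate by min_gap and require empty ground
        gr, gc = _capsule(center, angle, half_len, radius + min_gap, shape)
        if gr.size == 0 or occupied[gr, gc].any():
            continue
        rr, cc = _capsule(center, angle, half_len, radius, shape)
        if rr.size == 0:
            continue
        placed += 1
        mask[rr, cc] = placed
        occupied[rr, cc] = True
    return LabeledMask(mask)


def generate_filament_mask(
    n_filaments: int,
    cells_per_filament: tuple[int, int] = (4, 8),
    image_size=256,
    seed: int = 0,
    cell_length_px: tuple[float, float] = (10.0, 14.0),
    width_px: tuple[float, float] = (6.0, 9.0),
    curvature_sd: float = 0.12,
    max_attempts: int = 400,
) -> LabeledMask:
    """Chains of touching capsule cells along smooth random curves.

    Within a filament, consecutive cells share a boundary (overlapping
    pixels are kept by the earlier cell, so labels stay distinct and the
    adjacency graph of each filament is a path). Different filaments keep
    at least 1 px of background between them.
    """
    shape = _as_shape(image_size)
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    next_label = 1
    for _ in range(n_filaments):
        n_cells = int(rng.integers(cells_per_filament[0], cells_per_filament[1] + 1))
        for attempt in range(max_attempts):
            length = rng.uniform(*cell_length_px)
            radius = rng.uniform(*width_px) / 2.0
            half_len = max(length / 2.0 - radius, 0.5)
            center = np.array(
                [rng.uniform(20, shape[0] - 20), rng.uniform(20, shape[1] - 20)]
            )
            angle = rng.uniform(0, 2 * np.pi)
            capsules = []
            ok = True
            for i in range(n_cells):
                if not (
                    5 <= center[0] < shape[0] - 5 and 5 <= center[1] < shape[1] - 5
                ):
                    ok = False
                    break
                capsules.append((center.copy(), angle, half_len, radius))
                step = 2 * half_len + 2 * radius - 1.5  # slight overlap -> touching
                angle += rng.normal(0.0, curvature_sd)
                center = center + step * np.array([np.sin(angle), np.cos(angle)])
            if not ok:
                continue
            # clearance from other filaments (not from this one)
            clear = True
            pix = []
            for c, a, h, r in capsules:
                gr, gc = _capsule(c, a, h, r + 1, shape)
                if gr.size == 0 or occupied[gr, gc].any():
                    clear = False
                    break
                rr, cc = _capsule(c, a, h, r, shape)
                pix.append((rr, cc))
            if not clear:
                continue
            for rr, cc in pix:
                fresh = mask[rr, cc] == 0
                mask[rr[fresh], cc[fresh]] = next_label
                next_label += 1
            for rr, cc in pix:
                occupied[rr, cc] = True
            break
        else:
            raise PlacementError(
                "could not place a filament within the attempt budget"
            )
    return LabeledMask(mask)


# --------------------------------------------------------------------------
# corruption with planted error counts


@dataclass(frozen=True)
class CorruptionPlan:
    """How many errors of each class to plant, plus sub-tolerance jitter.

    ``jitter_frac`` perturbs each untouched object's pixel set by strictly
    less than that fraction of its area; it must stay below the evaluation
    tolerance for the planted counts to remain exact.
    """

    n_split: int = 0
    n_merge: int = 0
    n_delete: int = 0
    n_add: int = 0
    jitter_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_split", "n_merge", "n_delete", "n_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.jitter_frac < 1.0:
            raise ValueError("jitter_frac must lie in [0, 1)")


def _split_object(pred, label, new_label, rng) -> bool:
    """Cut one object in two with a 1-px background line through its centroid."""
    ys, xs = np.nonzero(pred == label)
    if ys.size < 4:
        return False
    cr, cc = ys.mean(), xs.mean()
    for _ in range(24):
        theta = rng.uniform(0, np.pi)
        nr, nc = np.cos(theta), np.sin(theta)
        d = (ys - cr) * nr + (xs - cc) * nc
        on_line = np.abs(d) < 0.5
        pos = d >= 0.5
        neg = d <= -0.5
        if pos.any() and neg.any():
            pred[ys[on_line], xs[on_line]] = 0
            pred[ys[pos], xs[pos]] = new_label
            return True
    return False


def _merge_candidates(mask: np.ndarray, reach: float = 2.5) -> list[tuple[int, int]]:
    """Pairs of labels whose gap is bridgeable (within ~2 px of dilation each)."""
    grown = expand_labels(mask, distance=reach)
    pairs = set()
    for axis in (0, 1):
        a = np.take(grown, range(grown.shape[axis] - 1), axis=axis)
        b = np.take(grown, range(1, grown.shape[axis]), axis=axis)
        touch = (a != b) & (a > 0) & (b > 0)
        pairs |= {
            (int(min(x, y)), int(max(x, y)))
            for x, y in zip(a[touch].ravel(), b[touch].ravel())
        }
    return sorted(pairs)


def _grow_blob(free: np.ndarray, size: int, rng) -> tuple[np.ndarray, np.ndarray] | None:
    """Random-walk a small connected blob inside the free region."""
    cand = np.flatnonzero(free.ravel())
    if cand.size == 0:
        return None
    start = np.unravel_index(int(rng.choice(cand)), free.shape)
    blob = {start}
    frontier = [start]
    while len(blob) < size and frontier:
        r, c = frontier[int(rng.integers(len(frontier)))]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < free.shape[0]
            and 0 <= c + dc < free.shape[1]
            and free[r + dr, c + dc]
            and (r + dr, c + dc) not in blob
        ]
        if not nbrs:
            frontier.remove((r, c))
            continue
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        blob.add(nxt)
        frontier.append(nxt)
    ys, xs = zip(*blob)
    return np.asarray(ys), np.asarray(xs)


def _jitter_object(pred, gt, label, jitter_frac, rng) -> None:
    """Perturb one object's boundary by strictly less than jitter_frac of area."""
    ys, xs = np.nonzero(pred == label)
    area = ys.size
    k = int(np.floor(jitter_frac * area))
    if k >= jitter_frac * area:  # exact multiple: keep the change strict
        k -= 1
    if k <= 0:
        return
    k_remove = int(rng.integers(0, k + 1))
    k_add = k - k_remove
    if k_remove > 0:
        pick = rng.choice(area, size=k_remove, replace=False)
        pred[ys[pick], xs[pick]] = 0
    if k_add > 0:
        obj = pred == label
        ring = ndimage.binary_dilation(obj) & (gt == 0) & (pred == 0)
        ry, rx = np.nonzero(ring)
        if ry.size:
            pick = rng.choice(ry.size, size=min(k_add, ry.size), replace=False)
            pred[ry[pick], rx[pick]] = label


def corrupt_mask(
    mask: LabeledMask, plan: CorruptionPlan
) -> tuple[LabeledMask, ErrorReport]:
    """Apply a corruption plan and return the corrupted mask + planted counts.

    Each planted operation maps to exactly one object-level error under
    event counting: a split is one over-segmentation, a merge one
    under-segmentation, a deletion one false negative, an added spurious
    blob one false positive. Jitter plants no error. When the mask cannot
    support the full plan (too few objects, no bridgeable pair, no free
    background) the affected counts are reduced with a warning, and the
    returned report reflects what was actually planted.
    """
    rng = np.random.default_rng(plan.seed)
    gt = mask.pixels
    pred = gt.copy()
    labels = [int(l) for l in mask.labels]
    next_label = (max(labels) if labels else 0) + 1

    used: set[int] = set()

    # merges first: they are the most constrained (need near-touching pairs)
    n_merge = 0
    if plan.n_merge > 0:
        cands = _merge_candidates(gt)
        rng.shuffle(cands)
        for a, b in cands:
            if n_merge == plan.n_merge:
                break
            if a in used or b in used:
                continue
            pred[pred == b] = a
            _bridge_pair(pred, gt, a, b)
            used |= {a, b}
            n_merge += 1
        if n_merge < plan.n_merge:
            warnings.warn(
                f"only {n_merge}/{plan.n_merge} merges feasible "
                "(no more bridgeable object pairs)",
                stacklevel=2,
            )

    free_labels = [l for l in labels if l not in used]
    rng.shuffle(free_labels)

    n_split = 0
    for _ in range(plan.n_split):
        success = False
        tried: list[int] = []
        while free_labels:
            lbl = free_labels.pop()
            if _split_object(pred, lbl, next_label, rng):
                next_label += 1
                used.add(lbl)
                success = True
                break
            tried.append(lbl)  # too small to cut; still usable for delete
        free_labels = tried + free_labels
        if not success:
            break
        n_split += 1
    if n_split < plan.n_split:
        warnings.warn(
            f"only {n_split}/{plan.n_split} splits feasible", stacklevel=2
        )

    n_delete = 0
    for _ in range(plan.n_delete):
        if not free_labels:
            break
        lbl = free_labels.pop()
        pred[pred == lbl] = 0
        used.add(lbl)
        n_delete += 1
    if n_delete < plan.n_delete:
        warnings.warn(
            f"only {n_delete}/{plan.n_delete} deletions feasible", stacklevel=2
        )

    n_add = 0
    if plan.n_add > 0:
        forbidden = ndimage.binary_dilation(
            (gt > 0) | (pred > 0), iterations=2
        )
        free = ~forbidden
        free[:1, :] = free[-1:, :] = False
        free[:, :1] = free[:, -1:] = False
        for _ in range(plan.n_add):
            blob = _grow_blob(free, int(rng.integers(3, 9)), rng)
            if blob is None:
                break
            ys, xs = blob
            pred[ys, xs] = next_label
            next_label += 1
            n_add += 1
            pad = np.zeros_like(free)
            pad[ys, xs] = True
            free &= ~ndimage.binary_dilation(pad, iterations=3)
        if n_add < plan.n_add:
            warnings.warn(
                f"only {n_add}/{plan.n_add} spurious objects placed", stacklevel=2
            )

    if plan.jitter_frac > 0:
        for lbl in labels:
            if lbl not in used:
                _jitter_object(pred, gt, lbl, plan.jitter_frac, rng)

    report = ErrorReport(
        over_seg=n_split,
        under_seg=n_merge,
        false_neg=n_delete,
        false_pos=n_add,
        frame_index=mask.frame_index,
    )
    return LabeledMask(pred, frame_index=mask.frame_index), report


def _bridge_pair(pred, gt, label_keep, label_gone) -> None:
    """Bridge the two merged parts (old ``label_gone`` pixels now carry
    ``label_keep``) across any background gap so the merged object reads as
    one body. Purely cosmetic for counting: only joint-background pixels
    are painted."""
    comp, n = ndimage.label(pred == label_keep)
    if n < 2:
        return
    ay, ax = np.nonzero(comp == 1)
    by, bx = np.nonzero(comp == 2)
    tree = cKDTree(np.column_stack([ay, ax]))
    d, idx = tree.query(np.column_stack([by, bx]))
    j = int(np.argmin(d))
    i = int(idx[j])
    rr, cc = draw_line(int(by[j]), int(bx[j]), int(ay[i]), int(ax[i]))
    ok = (gt[rr, cc] == 0) & (pred[rr, cc] == 0)
    pred[rr[ok], cc[ok]] = label_keep


def corrupt_movie(
    movie: MaskMovie, plans: list[CorruptionPlan]
) -> tuple[MaskMovie, list[ErrorReport]]:
    """Apply one plan per frame; returns the corrupted movie and reports."""
    if len(plans) != len(movie):
        raise ValueError("need exactly one plan per frame")
    frames, reports = [], []
    for frame, plan in zip(movie, plans):
        corrupted, report = corrupt_mask(frame, plan)
        frames.append(corrupted)
        reports.append(report)
    return MaskMovie(tuple(frames)), reports


# --------------------------------------------------------------------------
# phenotype patches


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative model of one phenotype class's fluorescence localization.

    ``signal_model`` is one of ``none`` (no labelling), ``diffuse``
    (uniform cytoplasmic fill), ``puncta`` (``n_puncta`` Gaussian spots) or
    ``focus`` (a single brighter Gaussian spot). Intensities are in
    arbitrary camera units (ADU).
    """

    class_name: str
    signal_model: str
    n_puncta: int = 4
    intensity_mean: float = 80.0
    intensity_sd: float = 10.0
    noise_sd: float = 2.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.signal_model not in ("none", "diffuse", "puncta", "focus"):
            raise ValueError(f"unknown signal_model {self.signal_model!r}")
        if self.intensity_mean < 0:
            raise ValueError("intensity_mean must be non-negative")
        if self.signal_model == "puncta" and self.n_puncta < 1:
            raise ValueError("puncta model needs n_puncta >= 1")


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """Four classes mirroring unlabeled / diffuse / multi-punctate / single-focus
    fluorescence localization phenotypes."""
    return [
        PhenotypeSpec("wildtype", "none"),
        PhenotypeSpec("diffuse", "diffuse", intensity_mean=45.0, intensity_sd=8.0),
        PhenotypeSpec("puncta", "puncta", n_puncta=4, intensity_mean=90.0),
        PhenotypeSpec("focus", "focus", intensity_mean=160.0, intensity_sd=20.0),
    ]


def _add_spot(img: np.ndarray, r0: float, c0: float, amp: float, sigma: float) -> None:
    reach = int(np.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - reach), min(img.shape[0], int(r0) + reach + 1)
    c_lo, c_hi = max(0, int(c0) - reach), min(img.shape[1], int(c0) + reach + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def _render_brightfield(canvas: np.ndarray, footprint: np.ndarray) -> None:
    """Dark rim + near-background flat interior: the low-contrast look of
    transmitted-light images of bacteria."""
    interior = ndimage.binary_erosion(footprint)
    rim = footprint & ~interior
    canvas[rim] = 60.0
    canvas[interior] = 95.0


def _render_signal(
    canvas: np.ndarray, footprint: np.ndarray, spec: PhenotypeSpec, rng
) -> None:
    if spec.signal_model == "none":
        return
    level = max(rng.normal(spec.intensity_mean, spec.intensity_sd), 0.0)
    if spec.signal_model == "diffuse":
        canvas[footprint] += level
        return
    interior = ndimage.binary_erosion(footprint, iterations=2)
    if not interior.any():
        interior = footprint
    iy, ix = np.nonzero(interior)
    if spec.signal_model == "puncta":
        # greedy placement with a minimum pairwise separation so the class
        # genuinely shows multiple distinct spots, not one merged blob
        order = rng.permutation(iy.size)
        chosen: list[tuple[int, int]] = []
        for p in order:
            if len(chosen) == spec.n_puncta:
                break
            if all((iy[p] - r) ** 2 + (ix[p] - c) ** 2 >= 16 for r, c in chosen):
                chosen.append((int(iy[p]), int(ix[p])))
        if not chosen and iy.size:
            chosen = [(int(iy[order[0]]), int(ix[order[0]]))]
        for r, c in chosen:
            _add_spot(canvas, r + rng.uniform(-0.5, 0.5),
                      c + rng.uniform(-0.5, 0.5), level, sigma=1.3)
    else:  # focus
        p = int(rng.integers(iy.size))
        _add_spot(canvas, iy[p] + rng.uniform(-0.5, 0.5),
                  ix[p] + rng.uniform(-0.5, 0.5), level, sigma=1.8)


BF_BACKGROUND = 100.0
BF_NOISE_SD = 4.0
FLUOR_BACKGROUND = 10.0


def _finalize_channel(canvas: np.ndarray, noise_sd: float, poisson: bool, rng) -> np.ndarray:
    out = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    return np.clip(out, 0, None)


def generate_phenotype_dataset(
    n_per_class: int,
    specs: list[PhenotypeSpec] | None = None,
    n_channels: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, tuple[str, ...]]:
    """Class-balanced 32×32 patch dataset with one centered cell per patch.

    Channel 0 is brightfield-like for every class; channel 1 carries the
    class's fluorescence localization model; any further channels are
    detector noise only. Returns ``(patches, labels, truth, class_names)``
    where ``patches`` is (N, 32, 32, C) float32, ``labels`` the integer
    class per patch, and ``truth`` a table of (patch_id, true_class,
    class_name).
    """
    specs = specs if specs is not None else default_phenotype_specs()
    if not 1 <= n_channels <= 6:
        raise ValueError("n_channels must be 1-6")
    if n_channels < 2 and any(s.signal_model != "none" for s in specs):
        raise ValueError(
            "n_channels must be >= 2 when any class has a fluorescence signal"
        )
    rng = np.random.default_rng(seed)
    size = 32
    patches, labels = [], []
    for k, spec in enumerate(specs):
        for _ in range(n_per_class):
            center = (16 + rng.uniform(-2, 2), 16 + rng.uniform(-2, 2))
            angle = rng.uniform(0, np.pi)
            radius = rng.uniform(3.0, 4.5)
            half_len = rng.uniform(3.5, 6.5)
            rr, cc = _capsule(center, angle, half_len, radius, (size, size))
            footprint = np.zeros((size, size), dtype=bool)
            footprint[rr, cc] = True

            chans = []
            bf = np.full((size, size), BF_BACKGROUND)
            _render_brightfield(bf, footprint)
            chans.append(_finalize_channel(bf, BF_NOISE_SD, spec.poisson, rng))
            if n_channels >= 2:
                fl = np.full((size, size), FLUOR_BACKGROUND)
                _render_signal(fl, footprint, spec, rng)
                chans.append(_finalize_channel(fl, spec.noise_sd, spec.poisson, rng))
            for _extra in range(n_channels - 2):
                chans.append(
                    _finalize_channel(
                        np.full((size, size), FLUOR_BACKGROUND), 2.0, False, rng
                    )
                )
            patches.append(np.stack(chans, axis=-1).astype(np.float32))
            labels.append(k)
    patches_arr = np.stack(patches)
    labels_arr = np.asarray(labels, dtype=np.int64)
    truth = pd.DataFrame(
        {
            "patch_id": np.arange(labels_arr.size),
            "true_class": labels_arr,
            "class_name": [specs[i].class_name for i in labels_arr],
        }
    )
    return patches_arr, labels_arr, truth, tuple(s.class_name for s in specs)


def generate_classified_frame(
    n_cells: int,
    image_size=256,
    specs: list[PhenotypeSpec] | None = None,
    n_channels: int = 2,
    seed: int = 0,
) -> tuple[ImageStack, LabeledMask, pd.DataFrame]:
    """A full synthetic frame: rod mask + rendered channels + per-cell truth.

    Each cell is assigned a phenotype class uniformly at random and its
    fluorescence is rendered with the same models as the patch generator,
    so a classifier trained on patches transfers to centroid crops of this
    frame. Returns ``(stack, mask, truth)`` with truth columns frame,
    label, true_class, class_name.
    """
    specs = specs if specs is not None else default_phenotype_specs()
    rng = np.random.default_rng(seed)
    # consistency with the patch generator's training distribution: same
    # cell-morphology ranges, and spacing wide enough that a 32x32 centroid
    # crop contains essentially one cell (patches are single-cell by
    # contract, so dense packing is out of this fixture's scope)
    mask = generate_rod_mask(
        n_cells, image_size, length_px=(13.0, 22.0), width_px=(6.0, 9.0),
        seed=seed, min_gap=12, max_attempts=40000,
    )
    shape = mask.shape
    assignments = rng.integers(0, len(specs), size=mask.n_objects)

    bf = np.full(shape, BF_BACKGROUND)
    fl = np.full(shape, FLUOR_BACKGROUND)
    rows = []
    for lbl, k in zip(mask.labels, assignments):
        footprint = mask.pixels == lbl
        _render_brightfield(bf, footprint)
        _render_signal(fl, footprint, specs[k], rng)
        rows.append(
            {
                "frame": mask.frame_index,
                "label": int(lbl),
                "true_class": int(k),
                "class_name": specs[k].class_name,
            }
        )
    chans = [_finalize_channel(bf, BF_NOISE_SD, False, rng)]
    if n_channels >= 2:
        chans.append(_finalize_channel(fl, 2.0, False, rng))
    for _extra in range(n_channels - 2):
        chans.append(_finalize_channel(np.full(shape, FLUOR_BACKGROUND), 2.0, False, rng))
    stack = ImageStack(
        tuple(chans),
        channel_names=tuple(
            ["brightfield", "fluorescence", "extra3", "extra4", "extra5", "extra6"][
                : len(chans)
            ]
        ),
        frame_index=mask.frame_index,
    )
    return stack, mask, pd.DataFrame(rows)
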