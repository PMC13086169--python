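"""Data preparation for RNFL segmentation.

Device screenshots carry the manufacturer's segmentation as color-coded
boundary polylines drawn over the grayscale B-scan.  This module detects
those overlays by their color characteristics, records the boundary rows
as ground truth, removes the overlays by biharmonic inpainting, builds
three-category masks (above-background / RNFL / below-background),
resizes and normalizes images to the 128x128 network input, one-hot
encodes masks, and performs subject-wise train/validation/test splitting
so no patient's scans appear on both sides of a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.restoration import inpaint_biharmonic as _ski_inpaint
from skimage.transform import resize as _ski_resize

from rnflseg.types import ABOVE, BELOW, BoundarySet, N_CLASSES, RNFL

TARGET_SHAPE = (128, 128)


class DetectionFailure(RuntimeError):
    """Raised when a boundary overlay cannot be located reliably."""

    def __init__(self, message: str, match_fraction: float = 0.0):
        super().__init__(message)
        self.match_fraction = match_fraction


@dataclass
class ColorWindow:
    """Hue/saturation window identifying one overlay color.

    Hue is in degrees on the 0-360 color circle; a pixel matches when its
    circular hue distance to ``hue`` is at most ``hue_tol`` and its
    saturation is at least ``min_saturation`` (grayscale content has
    saturation 0, so any saturated threshold separates overlay from scan).
    """

    hue: float
    hue_tol: float = 20.0
    min_saturation: float = 0.3

    def match(self, hsv: np.ndarray) -> np.ndarray:
        dh = np.abs(hsv[..., 0] * 360.0 - self.hue)
        dh = np.minimum(dh, 360.0 - dh)
        return (dh <= self.hue_tol) & (hsv[..., 1] >= self.min_saturation)


#: Device-style defaults: cyan anterior (ILM) overlay, red posterior overlay.
DEFAULT_COLOR_SPEC = {"upper": ColorWindow(hue=180.0), "lower": ColorWindow(hue=0.0)}


def _fill_missing(rows: np.ndarray, found: np.ndarray) -> np.ndarray:
    """Linear interpolation over undetected columns, flat at the edges."""
    cols = np.arange(rows.shape[0])
    if found.all():
        return rows
    filled = np.interp(cols, cols[found], rows[found])
    return np.floor(filled + 0.5).astype(np.int64)


def detect_overlay_boundaries(
    rgb: np.ndarray,
    color_spec: dict[str, ColorWindow] | None = None,
) -> tuple[BoundarySet, np.ndarray]:
    """Locate the color-coded boundary overlays in a screenshot.

    Returns the per-column boundary rows (median matched row per column,
    linearly interpolated where a column has no match) and the binary
    overlay mask of all matched pixels, which is the inpainting mask used
    to remove the overlays.

    Raises :class:`DetectionFailure` if either color is found in fewer
    than half of the columns.
    """
    if color_spec is None:
        color_spec = DEFAULT_COLOR_SPEC
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = rgb2hsv(rgb)
    width = rgb.shape[1]

    overlay_mask = np.zeros(rgb.shape[:2], dtype=bool)
    rows_by_boundary: dict[str, np.ndarray] = {}
    for name, window in color_spec.items():
        matched = window.match(hsv)
        overlay_mask |= matched
        rows = np.zeros(width, dtype=np.int64)
        found = np.zeros(width, dtype=bool)
        for c in range(width):
            rr = np.nonzero(matched[:, c])[0]
            if rr.size:
                rows[c] = int(np.median(rr))
                found[c] = True
        frac = found.mean()
        if frac < 0.5:
            raise DetectionFailure(
                f"{name} boundary color matched in only {frac:.0%} of columns",
                match_fraction=float(frac),
            )
        rows_by_boundary[name] = _fill_missing(rows, found)

    return (
        BoundarySet(upper=rows_by_boundary["upper"], lower=rows_by_boundary["lower"]),
        overlay_mask,
    )


def inpaint_biharmonic(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by the biharmonic interpolant of their
    surroundings; pixels outside the mask are returned bit-identical.

    Constants and linear ramps are biharmonic, so such images pass
    through holes essentially unchanged — the property that makes the
    filled overlay/shadow regions blend seamlessly.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        warnings.warn("inpaint_biharmonic called with an empty mask; no-op")
        return image.copy()
    if mask.all():
        raise ValueError("mask covers the entire image; nothing to interpolate from")
    out = _ski_inpaint(image, mask)
    out = np.clip(out, 0.0, 1.0)
    out[~mask] = image[~mask]
    return out


def build_categorical_mask(boundaries: BoundarySet, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a boundary set into the three-category label image.

    Per column ``c``: rows ``[0, upper[c])`` are ABOVE, ``[upper[c],
    lower[c])`` are RNFL, ``[lower[c], height)`` are BELOW (half-open
    convention, so thickness in pixels equals ``lower - upper``).
    """
    height, width = shape
    if boundaries.width != width:
        raise ValueError("boundary width does not match mask shape")
    boundaries.validate_for(height)
    rows = np.arange(height)[:, None]
    mask = np.full(shape, BELOW, dtype=np.int64)
    mask[rows < boundaries.lower[None, :]] = RNFL
    mask[rows < boundaries.upper[None, :]] = ABOVE
    return mask


def resize_and_normalize(
    image: np.ndarray, target: tuple[int, int] = TARGET_SHAPE
) -> np.ndarray:
    """Scale intensities to [0, 1] (8-bit rasters divided by 255) and
    resize to the network input shape with bilinear interpolation."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / 255.0
    else:
        image = image.astype(np.float64)
    if image.shape == tuple(target):
        return image.copy()
    down = image.shape[0] > target[0] or image.shape[1] > target[1]
    out = _ski_resize(
        image, target, order=1, anti_aliasing=down, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def resize_mask(mask: np.ndarray, target: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Nearest-neighbor resize of a categorical mask (labels are never
    interpolated, so no mixed classes can appear)."""
    mask = np.asarray(mask)
    if mask.shape == tuple(target):
        return mask.copy()
    out = _ski_resize(
        mask.astype(np.float64),
        target,
        order=0,
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(mask.dtype)


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Encode a label image as a binary (H, W, n_classes) stack."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes}), got "
                         f"[{mask.min()}, {mask.max()}]")
    return (mask[..., None] == np.arange(n_classes)).astype(np.float64)


def decode_one_hot(stack: np.ndarray) -> np.ndarray:
    """Inverse of :func:`one_hot` (argmax over the channel axis)."""
    return np.argmax(stack, axis=-1).astype(np.int64)


@dataclass
class DatasetSplit:
    """Subject-wise test holdout plus k-fold cross-validation assignment."""

    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]] = field(default_factory=list)

    @property
    def pool_ids(self) -> list[str]:
        return sorted({s for train, val in self.folds for s in train + val})


def split_subject_wise(
    records,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Partition a cohort at the subject level.

    A whole-subject test set of roughly ``test_fraction`` of the subjects
    is drawn per class first; the remaining subjects are dealt into ``k``
    folds stratified by class, each subject validating in exactly one
    fold and training in the other ``k - 1``.  Deterministic under
    ``seed``.
    """
    by_class: dict[str, list[str]] = {}
    seen: set[str] = set()
    for rec in records:
        if rec.subject_id not in seen:
            seen.add(rec.subject_id)
            by_class.setdefault(rec.class_label, []).append(rec.subject_id)

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    pool_by_class: dict[str, list[str]] = {}
    for label in sorted(by_class):
        subjects = sorted(by_class[label])
        n_test = int(round(test_fraction * len(subjects)))
        order = rng.permutation(len(subjects))
        test_ids += [subjects[i] for i in order[:n_test]]
        pool = [subjects[i] for i in order[n_test:]]
        if len(pool) < k:
            raise ValueError(
                f"class {label!r} has {len(pool)} subjects after the test "
                f"holdout; at least {k} are needed for {k}-fold splitting"
            )
        pool_by_class[label] = pool

    fold_val: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(pool_by_class):
        for i, subject in enumerate(pool_by_class[label]):
            fold_val[i % k].append(subject)

    pool_all = sorted(s for pool in pool_by_class.values() for s in pool)
    folds = [
        (sorted(set(pool_all) - set(val)), sorted(val)) for val in fold_val
    ]
    return DatasetSplit(test_ids=sorted(test_ids), folds=folds)
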