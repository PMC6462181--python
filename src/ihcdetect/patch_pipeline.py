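"""Training-corpus construction: patch extraction, augmentation, splits,
and the hard-negative mining loop.

The classifier is trained on 46×46 px RGB patches: positives centered on
annotated cell centers, negatives sampled uniformly from images that
contain no positively stained cells.  The corpus is augmented by the
cross product of mirrors {identity, horizontal, vertical} and rotations
in 40° steps over the full circle (9 angles), a 27× multiplier that
preserves class balance exactly.  After a first training round, patches
are mined from false-positive peaks of the likelihood map and added to
the negative class for a second round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import ImageMetadata, PointAnnotation, RGBImage, um_to_px

logger = logging.getLogger(__name__)

#: Side length (px) of every classifier patch.
PATCH_SIZE = 46
#: Half-window: a patch centered at c spans [c-23, c+23).
PATCH_HALF = PATCH_SIZE // 2

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class LabeledPatch:
    """A 46×46×3 uint8 patch with its binary class and provenance."""

    pixels: np.ndarray
    label: str
    source_image_id: str = ""
    origin: str = "manual"  # manual | mined_hard_negative | augmented

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(
                f"patch must be {PATCH_SIZE}×{PATCH_SIZE}×3, got {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValueError(f"patch dtype must be uint8, got {px.dtype}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label}")
        self.pixels = px


@dataclass(frozen=True)
class AugmentationConfig:
    """Mirror × rotation transform set applied to every patch.

    Defaults: all three mirror states and rotations by 40° steps over
    the full circle.  The identity (identity mirror, 0° rotation) is
    always a member so originals survive augmentation.
    """

    rotations_deg: tuple[int, ...] = (0, 40, 80, 120, 160, 200, 240, 280, 320)
    mirrors: tuple[str, ...] = ("identity", "horizontal", "vertical")

    def __post_init__(self) -> None:
        if 0 not in self.rotations_deg:
            raise ValueError("rotations_deg must contain 0")
        if "identity" not in self.mirrors:
            raise ValueError("mirrors must contain 'identity'")
        bad = set(self.mirrors) - {"identity", "horizontal", "vertical"}
        if bad:
            raise ValueError(f"unknown mirror(s) {bad}")

    @property
    def multiplier(self) -> int:
        return len(self.rotations_deg) * len(self.mirrors)


@dataclass(frozen=True)
class DatasetSplit:
    """Slide/image-level train-test split; the two sides never share an image."""

    train_image_ids: frozenset[str]
    test_image_ids: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.train_image_ids & self.test_image_ids
        if overlap:
            raise ValueError(f"split is not disjoint: {sorted(overlap)}")

    def side_of(self, image_id: str) -> str:
        if image_id in self.train_image_ids:
            return "train"
        if image_id in self.test_image_ids:
            return "test"
        raise KeyError(f"image {image_id!r} not in split")


def split_by_image(
    image_ids: Sequence[str], n_test: int, seed: int
) -> DatasetSplit:
    """Random image-level split with ``n_test`` held-out images."""
    ids = list(dict.fromkeys(image_ids))
    if not 0 <= n_test <= len(ids):
        raise ValueError("n_test out of range")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = frozenset(ids[i] for i in perm[:n_test])
    train = frozenset(ids[i] for i in perm[n_test:])
    return DatasetSplit(train_image_ids=train, test_image_ids=test)


def assert_split_respected(
    patches: Iterable[LabeledPatch], split: DatasetSplit
) -> None:
    """Raise if any source image contributes patches to both sides."""
    sides = {}
    for p in patches:
        side = split.side_of(p.source_image_id)
        prev = sides.setdefault(p.source_image_id, side)
        if prev != side:  # pragma: no cover - split.side_of is a function
            raise AssertionError(f"image {p.source_image_id} crosses the split")


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_positive_patches(
    image: RGBImage, centers: Sequence[PointAnnotation]
) -> list[LabeledPatch]:
    """One positive 46×46 patch per annotated center.

    A patch centered at integer (x, y) is ``image[y-23:y+23, x-23:x+23]``.
    Centers closer than 23 px to any border are skipped with a logged
    warning rather than padded — padding would fabricate tissue.
    """
    H, W = image.height, image.width
    out: list[LabeledPatch] = []
    for c in centers:
        x, y = int(round(c.x)), int(round(c.y))
        if not (PATCH_HALF <= x <= W - PATCH_HALF and PATCH_HALF <= y <= H - PATCH_HALF):
            logger.warning(
                "skipping border-adjacent center (%d, %d) in %s",
                x, y, image.metadata.image_id,
            )
            continue
        block = image.pixels[y - PATCH_HALF : y + PATCH_HALF,
                             x - PATCH_HALF : x + PATCH_HALF]
        out.append(
            LabeledPatch(
                pixels=block.copy(),
                label=POSITIVE,
                source_image_id=image.metadata.image_id,
                origin="manual",
            )
        )
    return out


def sample_negative_patches(
    image: RGBImage, n: int, seed: int
) -> list[LabeledPatch]:
    """``n`` uniformly placed negative patches from a positive-free image."""
    if n < 0:
        raise ValueError("n must be ≥ 0")
    H, W = image.height, image.width
    if H < PATCH_SIZE or W < PATCH_SIZE:
        raise ValueError(
            f"image {H}×{W} smaller than patch size {PATCH_SIZE}"
        )
    rng = np.random.default_rng(seed)
    out: list[LabeledPatch] = []
    for _ in range(n):
        y0 = int(rng.integers(0, H - PATCH_SIZE + 1))
        x0 = int(rng.integers(0, W - PATCH_SIZE + 1))
        out.append(
            LabeledPatch(
                pixels=image.pixels[y0 : y0 + PATCH_SIZE,
                                    x0 : x0 + PATCH_SIZE].copy(),
                label=NEGATIVE,
                source_image_id=image.metadata.image_id,
                origin="manual",
            )
        )
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_MIRROR_OPS = {
    "identity": lambda a: a,
    "horizontal": lambda a: a[:, ::-1],  # flip columns
    "vertical": lambda a: a[::-1, :],  # flip rows
}


def _rotate_patch(pixels: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the patch center, keeping the 46×46 frame.

    Multiples of 90° are exact array rotations; other angles use
    bilinear interpolation with reflect padding (no black corners that
    would leak label information).
    """
    angle = angle_deg % 360
    if angle == 0:
        return pixels.copy()
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(pixels, k=int(angle // 90)))
    rot = ndimage.rotate(
        pixels.astype(np.float64),
        angle,
        axes=(1, 0),
        reshape=False,
        order=1,
        mode="reflect",
    )
    return np.clip(np.rint(rot), 0, 255).astype(np.uint8)


def augment(
    patches: Sequence[LabeledPatch],
    config: AugmentationConfig = AugmentationConfig(),
) -> list[LabeledPatch]:
    """Apply every mirror ∘ rotation combination to every patch.

    Output size is ``len(patches) * config.multiplier``; labels and the
    class balance are preserved exactly.  The (identity, 0°) copy keeps
    the input's origin tag, all others are tagged ``augmented``.
    """
    out: list[LabeledPatch] = []
    for p in patches:
        for mirror in config.mirrors:
            mirrored = np.ascontiguousarray(_MIRROR_OPS[mirror](p.pixels))
            for angle in config.rotations_deg:
                pix = _rotate_patch(mirrored, angle)
                is_identity = mirror == "identity" and angle % 360 == 0
                out.append(
                    LabeledPatch(
                        pixels=pix,
                        label=p.label,
                        source_image_id=p.source_image_id,
                        origin=p.origin if is_identity else "augmented",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# hard-negative mining
# ---------------------------------------------------------------------------


def mine_hard_negatives(
    model,
    images: Sequence[RGBImage],
    likelihood_threshold: float = 0.3,
    true_centers: dict[str, Sequence[tuple[float, float]]] | None = None,
    match_radius_um: float = 4.0,
    peak_min_distance_px: int = 9,
    map_kwargs: dict | None = None,
) -> list[LabeledPatch]:
    """Extract negative patches at false-positive likelihood peaks.

    Runs dense likelihood inference on each image, finds local maxima
    above ``likelihood_threshold`` that do not fall within
    ``match_radius_um`` of any supplied true center, and cuts a 46×46
    patch centered at each such peak (label=negative,
    origin=mined_hard_negative).  Images are expected to be free of true
    positive cells unless ``true_centers`` maps their image_id to the
    centers to exclude.
    """
    if getattr(model, "trained", True) is False:
        raise ValueError("model must be trained before mining hard negatives")
    if not hasattr(model, "predict_likelihood_map") and not callable(model):
        raise TypeError(
            "model must expose predict_likelihood_map(image) or be callable"
        )
    mined: list[LabeledPatch] = []
    for image in images:
        if hasattr(model, "predict_likelihood_map"):
            lmap = model.predict_likelihood_map(image, **(map_kwargs or {}))
        else:
            lmap = model(image)
        values = np.asarray(getattr(lmap, "values", lmap), dtype=np.float64)
        if values.shape != (image.height, image.width):
            raise ValueError("likelihood map size does not match the image")

        # local maxima above threshold; plateaus collapse to one peak via
        # greedy non-maximum suppression ordered by response
        size = 2 * peak_min_distance_px + 1
        local_max = values == ndimage.maximum_filter(values, size=size)
        raw = np.argwhere(local_max & (values > likelihood_threshold))
        order = np.lexsort((raw[:, 1], raw[:, 0], -values[raw[:, 0], raw[:, 1]]))
        candidates: list[tuple[int, int]] = []
        for idx in order:
            y, x = int(raw[idx, 0]), int(raw[idx, 1])
            if all(
                (x - ax) ** 2 + (y - ay) ** 2 > peak_min_distance_px**2
                for ay, ax in candidates
            ):
                candidates.append((y, x))

        excl = []
        if true_centers is not None:
            excl = list(true_centers.get(image.metadata.image_id, []))
        tol_px = um_to_px(match_radius_um, image.metadata)

        H, W = image.height, image.width
        for y, x in candidates:
            if excl and min(
                (x - ex) ** 2 + (y - ey) ** 2 for ex, ey in excl
            ) <= tol_px**2:
                continue
            if not (
                PATCH_HALF <= x <= W - PATCH_HALF
                and PATCH_HALF <= y <= H - PATCH_HALF
            ):
                continue
            block = image.pixels[y - PATCH_HALF : y + PATCH_HALF,
                                 x - PATCH_HALF : x + PATCH_HALF]
            mined.append(
                LabeledPatch(
                    pixels=block.copy(),
                    label=NEGATIVE,
                    source_image_id=image.metadata.image_id,
                    origin="mined_hard_negative",
                )
            )
    logger.info("mined %d hard-negative patches from %d images",
                len(mined), len(images))
    return mined


# ---------------------------------------------------------------------------
# array conversion helpers shared with the classifier
# ---------------------------------------------------------------------------


def patches_to_arrays(
    patches: Sequence[LabeledPatch],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (N, 46, 46, 3) uint8 X and binary y (1=positive)."""
    if not patches:
        return (
            np.zeros((0, PATCH_SIZE, PATCH_SIZE, 3), dtype=np.uint8),
            np.zeros((0,), dtype=np.int64),
        )
    X = np.stack([p.pixels for p in patches])
    y = np.array([1 if p.label == POSITIVE else 0 for p in patches],
                 dtype=np.int64)
    return X, y


__all__ = [
    "PATCH_SIZE",
    "PATCH_HALF",
    "POSITIVE",
    "NEGATIVE",
    "LabeledPatch",
    "AugmentationConfig",
    "DatasetSplit",
    "split_by_image",
    "assert_split_respected",
    "extract_positive_patches",
    "sample_negative_patches",
    "augment",
    "mine_hard_negatives",
    "patches_to_arrays",
]
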