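"""Synthetic IHC-like image generator with known ground truth.

Emulates the visual vocabulary of a DAB/hematoxylin-stained lung tissue
tile: brown positively stained immune cells of varying intensity and
shape on a pale hematoxylin-tinted background, with the confounders that
make the negative class hard in real slides — blue-purple unstained
nuclei, red-orange erythrocytes, near-black anthracotic pigment clumps
and faint diffuse stain traces.

The model is deliberately simple (flat shading per object, slight edge
blur, additive Gaussian noise): rich enough to exercise a color-based
patch classifier and the radial-symmetry detector end-to-end, with exact
ground-truth cell centers; it is not a physical stain-absorbance
simulation.  Key constructions:

* positive cells are ellipses whose brown chroma (R−B, with R>G>B
  spacing) sits well above every confounder;
* pigment clumps are rendered with B ≥ R so no pigment pixel ever shows
  brown chroma — a correct classifier can always separate them;
* generation is bit-deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging_io import DEFAULT_PIXEL_SIZE_UM, ImageMetadata, RGBImage

# Base colors (R, G, B) of the rendered object classes.
BACKGROUND_RGB = (233, 226, 240)  # pale lavender (hematoxylin-tinted glass)
DAB_DARK_RGB = (92, 52, 18)  # strongly stained cell
DAB_LIGHT_RGB = (201, 160, 108)  # weakly stained cell
NUCLEUS_RGB = (98, 82, 155)  # hematoxylin-only nucleus
PIGMENT_RGB = (28, 28, 34)  # anthracotic pigment: near-black, B ≥ R
ERYTHROCYTE_RGB = (205, 92, 92)  # red-orange; G = B so it never reads brown
TRACE_RGB = (196, 178, 158)  # diffuse stain trace: low-chroma brown

#: Minimum R−B excess for a pixel to count as DAB-brown; used by tests
#: and by the patch-center chroma property.  All positive-cell colors
#: clear it; every confounder fails it (or fails the R>G>B spacing).
BROWN_CHROMA_MARGIN = 40

#: Center-to-center clearance (µm) enforced among confounders; positive
#: cells additionally keep ``min_separation_um`` from everything.
CONFOUNDER_SEPARATION_UM = 4.0


class GenerationError(RuntimeError):
    """Raised when object placement cannot satisfy the separation rules."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic tissue image.

    Defaults describe a 500×500 px tile at 0.228 µm/px carrying ~50
    well-separated positive cells plus pigment, erythrocyte, unstained
    nucleus and stain-trace confounders.
    """

    image_size_px: tuple[int, int] = (500, 500)  # (H, W)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_positive_cells: int = 50
    n_pigment_clumps: int = 10
    n_negative_nuclei: int = 25
    n_erythrocytes: int = 10
    n_stain_traces: int = 3
    cell_radius_um_range: tuple[float, float] = (1.8, 3.5)
    dab_intensity_range: tuple[float, float] = (0.35, 1.0)  # 0=light, 1=dark
    min_separation_um: float = 8.0
    noise_sd: float = 4.0
    border_margin_px: int = 30
    max_attempts: int = 10_000
    seed: int = 0
    marker: str = "CD3"

    def __post_init__(self) -> None:
        H, W = self.image_size_px
        if H < 1 or W < 1:
            raise ValueError("image size must be ≥ 1×1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in (
            "n_positive_cells",
            "n_pigment_clumps",
            "n_negative_nuclei",
            "n_erythrocytes",
            "n_stain_traces",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        lo, hi = self.cell_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_um_range must satisfy 0 < lo ≤ hi")
        lo, hi = self.dab_intensity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("dab_intensity_range must lie within [0, 1]")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be ≥ 0")

    @property
    def metadata(self) -> ImageMetadata:
        return ImageMetadata(pixel_size_um=self.pixel_size_um, marker=self.marker)


@dataclass
class GroundTruth:
    """Planted object centers: positives as (x, y), confounders as (x, y, kind)."""

    positive_centers: list[tuple[int, int]] = field(default_factory=list)
    confounder_centers: list[tuple[int, int, str]] = field(default_factory=list)

    def confounders_of(self, kind: str) -> list[tuple[int, int]]:
        return [(x, y) for x, y, k in self.confounder_centers if k == kind]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: int,
    keepout: list[tuple[float, float, float]],
    self_min_dist: float,
    max_attempts: int,
    what: str,
) -> list[tuple[int, int]]:
    """Rejection-sample ``n`` integer centers respecting keep-out distances.

    ``keepout`` holds (x, y, min_dist_px) constraints; every accepted
    point is appended to it with radius ``self_min_dist`` so the batch
    is pairwise separated and later batches keep their distance too.
    """
    H, W = shape
    if W - 2 * margin < 1 or H - 2 * margin < 1:
        if n > 0:
            raise GenerationError(
                f"image {shape} too small for margin {margin} while placing {what}"
            )
        return []
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            x = int(rng.integers(margin, W - margin))
            y = int(rng.integers(margin, H - margin))
            ok = True
            for kx, ky, dmin in keepout:
                if (x - kx) ** 2 + (y - ky) ** 2 < dmin**2:
                    ok = False
                    break
            if ok:
                placed.append((x, y))
                keepout.append((x, y, self_min_dist))
                break
        else:
            raise GenerationError(
                f"could not place {what} #{len(placed) + 1} of {n} within "
                f"{max_attempts} attempts (min_separation too large for the "
                f"image size / object count)"
            )
    return placed


# ---------------------------------------------------------------------------
# rendering primitives (all paint in-place on a float RGB buffer)
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean mask of a rotated ellipse, restricted to its bounding box."""
    H, W = shape
    r = max(a, b) + 1
    y0, y1 = max(0, int(cy - r)), min(H, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r)), min(W, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (slice(y0, y1), slice(x0, x1))


def _paint(
    buf: np.ndarray,
    mask: np.ndarray,
    box: tuple[slice, slice],
    color: np.ndarray,
    alpha: float = 1.0,
) -> None:
    region = buf[box]
    region[mask] = (1.0 - alpha) * region[mask] + alpha * color


def _dab_color(intensity: float, rng: np.random.Generator) -> np.ndarray:
    """Brown of a stained cell; intensity 0 = light, 1 = dark, plus jitter."""
    light = np.array(DAB_LIGHT_RGB, dtype=np.float64)
    dark = np.array(DAB_DARK_RGB, dtype=np.float64)
    color = light + intensity * (dark - light)
    return color + rng.normal(0.0, 4.0, size=3)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_tissue_image(config: SynthConfig) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic tissue image and its ground truth.

    Placement is rejection sampling: positive cells keep
    ``min_separation_um`` from every other object, confounders keep a
    fixed 4 µm among themselves.  If placement is infeasible a
    :class:`GenerationError` is raised — counts are never silently
    truncated.  Output is bit-identical for identical configs (the seed
    is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.image_size_px
    ps = config.pixel_size_um
    sep_px = config.min_separation_um / ps
    conf_sep_px = CONFOUNDER_SEPARATION_UM / ps
    margin = min(config.border_margin_px, max(1, min(H, W) // 2 - 1))

    keepout: list[tuple[float, float, float]] = []
    positives = _place_points(
        rng,
        config.n_positive_cells,
        (H, W),
        margin,
        keepout,
        sep_px,
        config.max_attempts,
        "positive cell",
    )
    # cells stay min_separation apart from each other; confounders only
    # need clearance so they never overlap a cell body
    pos_conf_px = max(conf_sep_px, sep_px / 2)
    keepout = [(x, y, pos_conf_px) for x, y, _ in keepout]

    confounders: list[tuple[int, int, str]] = []
    for kind, n in (
        ("stain_trace", config.n_stain_traces),
        ("erythrocyte", config.n_erythrocytes),
        ("nucleus", config.n_negative_nuclei),
        ("pigment", config.n_pigment_clumps),
    ):
        pts = _place_points(
            rng, n, (H, W), margin, keepout, conf_sep_px,
            config.max_attempts, kind,
        )
        confounders.extend((x, y, kind) for x, y in pts)

    buf = np.empty((H, W, 3), dtype=np.float64)
    buf[:] = np.array(BACKGROUND_RGB, dtype=np.float64)
    # mild background texture so negatives are not a constant color
    buf += rng.normal(0.0, 1.5, size=(H, W, 1))

    r_lo, r_hi = config.cell_radius_um_range
    i_lo, i_hi = config.dab_intensity_range

    for x, y, kind in confounders:
        if kind == "stain_trace":
            r = rng.uniform(4.0, 8.0) / ps
            aspect = rng.uniform(1.0, 2.5)
            mask, box = _ellipse_mask(
                (H, W), x, y, r * aspect, r, rng.uniform(0, np.pi)
            )
            _paint(buf, mask, box, np.asarray(TRACE_RGB, float), alpha=0.55)
        elif kind == "erythrocyte":
            r = rng.uniform(2.5, 3.5) / ps
            mask, box = _ellipse_mask((H, W), x, y, r, r, 0.0)
            # luminance-only jitter preserves the G = B construction
            color = np.asarray(ERYTHROCYTE_RGB, float) + rng.normal(0.0, 4.0)
            _paint(buf, mask, box, color)
        elif kind == "nucleus":
            r = rng.uniform(1.5, 3.0) / ps
            aspect = rng.uniform(1.0, 1.4)
            mask, box = _ellipse_mask(
                (H, W), x, y, r * np.sqrt(aspect), r / np.sqrt(aspect),
                rng.uniform(0, np.pi),
            )
            color = np.asarray(NUCLEUS_RGB, float) + rng.normal(0, 5, 3)
            _paint(buf, mask, box, color)
        else:  # pigment: irregular union of near-black grains, B ≥ R kept
            base = np.asarray(PIGMENT_RGB, float)
            n_grains = int(rng.integers(3, 7))
            for g in range(n_grains):
                gr = rng.uniform(0.9, 1.8) / ps
                # the first grain anchors the nominal center so the
                # ground-truth coordinate always lies on pigment
                ox = x + (0.0 if g == 0 else rng.normal(0.0, 0.7 / ps))
                oy = y + (0.0 if g == 0 else rng.normal(0.0, 0.7 / ps))
                mask, box = _ellipse_mask((H, W), ox, oy, gr, gr, 0.0)
                # luminance-only jitter keeps the R−B ≤ 0 construction
                _paint(buf, mask, box, base + rng.normal(0.0, 3.0))

    for x, y in positives:
        r = rng.uniform(r_lo, r_hi) / ps
        aspect = rng.uniform(1.0, 1.6)
        a, b = r * np.sqrt(aspect), r / np.sqrt(aspect)
        mask, box = _ellipse_mask((H, W), x, y, a, b, rng.uniform(0, np.pi))
        intensity = rng.uniform(i_lo, i_hi)
        _paint(buf, mask, box, _dab_color(intensity, rng))

    # soften object edges, then sensor-like additive noise
    buf = ndimage.gaussian_filter(buf, sigma=(0.6, 0.6, 0.0))
    if config.noise_sd > 0:
        buf += rng.normal(0.0, config.noise_sd, size=buf.shape)
    pixels = np.clip(np.rint(buf), 0, 255).astype(np.uint8)

    image = RGBImage(pixels, config.metadata)
    truth = GroundTruth(
        positive_centers=list(positives), confounder_centers=confounders
    )
    return image, truth


def brown_chroma_mask(
    pixels: np.ndarray, margin: int = BROWN_CHROMA_MARGIN
) -> np.ndarray:
    """Pixels showing the DAB-brown signature: R−B > margin with R>G>B spacing."""
    px = np.asarray(pixels, dtype=np.int16)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (r - b > margin) & (r - g > 15) & (g - b > 15)


def generate_patch_set(config: SynthConfig, n_per_class: int):
    """Generate a balanced labeled 46×46 patch corpus.

    Positive patches are extracted centered on rendered cells from
    images generated with ``config``; negative patches are sampled
    uniformly from companion images rendered with the same confounder
    mix but **zero** positive cells, mirroring the practice of taking
    negatives only from regions without positively stained cells.
    Returns exactly ``n_per_class`` patches per label, deterministically
    for a given config (seed included).
    """
    from .patch_pipeline import (
        PATCH_SIZE,
        extract_positive_patches,
        sample_negative_patches,
    )

    if n_per_class < 1:
        raise ValueError("n_per_class must be ≥ 1")
    if config.n_positive_cells < 1:
        raise ValueError(
            "config must place at least one positive cell per image "
            "to build the positive class"
        )
    H, W = config.image_size_px
    if H < PATCH_SIZE or W < PATCH_SIZE:
        raise ValueError(f"config image size {config.image_size_px} too small")

    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = iter(seed_seq.generate_state(1_000_000))

    positives = []
    img_idx = 0
    while len(positives) < n_per_class:
        cfg = replace(
            config, seed=int(next(child_seeds)) % (2**31), marker=config.marker
        )
        image, truth = generate_tissue_image(cfg)
        image.metadata = ImageMetadata(
            pixel_size_um=cfg.pixel_size_um,
            marker=cfg.marker,
            image_id=f"synth-pos-{img_idx:04d}",
        )
        from .imaging_io import PointAnnotation

        centers = [
            PointAnnotation(x=x, y=y, label="positive",
                            image_id=image.metadata.image_id)
            for x, y in truth.positive_centers
        ]
        positives.extend(extract_positive_patches(image, centers))
        img_idx += 1
        if img_idx > 10_000:  # pragma: no cover - guards infinite loop
            raise GenerationError("could not accumulate requested positives")
    positives = positives[:n_per_class]

    negatives = []
    neg_cfg_base = replace(config, n_positive_cells=0)
    img_idx = 0
    per_image = max(1, min(200, n_per_class))
    while len(negatives) < n_per_class:
        cfg = replace(neg_cfg_base, seed=int(next(child_seeds)) % (2**31))
        image, _ = generate_tissue_image(cfg)
        image.metadata = ImageMetadata(
            pixel_size_um=cfg.pixel_size_um,
            marker=cfg.marker,
            image_id=f"synth-neg-{img_idx:04d}",
        )
        take = min(per_image, n_per_class - len(negatives))
        negatives.extend(
            sample_negative_patches(
                image, take, seed=int(next(child_seeds)) % (2**31)
            )
        )
        img_idx += 1
        if img_idx > 10_000:  # pragma: no cover
            raise GenerationError("could not accumulate requested negatives")

    return positives + negatives


__all__ = [
    "SynthConfig",
    "GroundTruth",
    "GenerationError",
    "generate_tissue_image",
    "generate_patch_set",
    "brown_chroma_mask",
    "BROWN_CHROMA_MARGIN",
    "BACKGROUND_RGB",
    "DAB_DARK_RGB",
    "DAB_LIGHT_RGB",
    "NUCLEUS_RGB",
    "PIGMENT_RGB",
    "ERYTHROCYTE_RGB",
    "TRACE_RGB",
]
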