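"""Fast radial symmetry transform (FRST) cell-center detection.

The likelihood map produced by the patch classifier is blob-shaped: a
bright plateau per stained cell.  The FRST converts those blobs into
point detections by gradient voting: every pixel with a strong gradient
casts a vote one radius ahead along its gradient direction, so the
centers of radially symmetric bright regions accumulate many coherent
votes.  Per radius ``n`` the vote count image ``O_n`` (clamped at
``κ_n``) and magnitude image ``M_n`` combine into

    F_n = (min(O_n, κ_n)/κ_n)^α · (M_n/κ_n),

which is smoothed with a Gaussian of σ = ``gaussian_sigma_factor``·n;
the final response is the mean of the smoothed ``F_n`` over all radii in
the configured physical range (0–4 µm by default, i.e. pixel radii
1..⌈4/0.228⌉ = 1..18 at scanner resolution).  Only bright (positive)
votes are cast, since cells are bright peaks of the likelihood map.

Detection then thresholds the likelihood map at 0.3, applies the
transform, thresholds the response at a fraction of its maximum, and
reports one detection per 8-connected component at its
response-weighted centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cnn_model import LikelihoodMap
from .imaging_io import Detection, ImageMetadata


@dataclass(frozen=True)
class FRSTParams:
    """Transform and detection parameters.

    α (radial strictness) 0.5, β (gradient threshold) 0.25 and the
    0–4 µm radius range with a 0.3 likelihood threshold are the
    operating point of the method; β is interpreted as a fraction of
    the maximum gradient magnitude (set ``beta_is_relative=False`` for
    an absolute threshold).  κ = 8 at radius 1 px and 9.9 at larger
    radii, and σ = radius/4 for the per-radius smoothing, are the
    published constants of the transform.
    """

    alpha: float = 0.5
    beta: float = 0.25
    r_min_um: float = 0.0
    r_max_um: float = 4.0
    likelihood_threshold: float = 0.3
    frst_response_threshold: float = 0.1  # fraction of max response
    gaussian_sigma_factor: float = 0.25
    kappa_small: float = 8.0
    kappa_large: float = 9.9
    beta_is_relative: bool = True
    min_component_px: int = 2

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.beta < 1 and self.beta_is_relative:
            raise ValueError("relative beta must lie in [0, 1)")
        if not 0 <= self.r_min_um <= self.r_max_um:
            raise ValueError("radius range must satisfy 0 ≤ r_min ≤ r_max")
        if not 0 <= self.likelihood_threshold <= 1:
            raise ValueError("likelihood_threshold must lie in [0, 1]")
        if not 0 <= self.frst_response_threshold <= 1:
            raise ValueError("frst_response_threshold must lie in [0, 1]")

    def radii_px(self, meta: ImageMetadata) -> list[int]:
        """Integer pixel radii covering [r_min_um, r_max_um].

        A physical minimum of 0 µm maps to 1 px: a zero-radius vote
        lands on the voting pixel itself and is degenerate.
        """
        n_min = max(1, math.ceil(self.r_min_um / meta.pixel_size_um))
        n_max = math.ceil(self.r_max_um / meta.pixel_size_um)
        if n_max < n_min:
            raise ValueError(
                f"empty radius set for range ({self.r_min_um}, {self.r_max_um}) µm "
                f"at {meta.pixel_size_um} µm/px"
            )
        return list(range(n_min, n_max + 1))

    def kappa(self, radius_px: int) -> float:
        return self.kappa_small if radius_px == 1 else self.kappa_large


def frst_transform(
    lmap: LikelihoodMap | np.ndarray,
    params: FRSTParams = FRSTParams(),
    meta: ImageMetadata | None = None,
) -> np.ndarray:
    """Bright-symmetry FRST response of a likelihood map.

    For each radius: central-difference gradients; pixels whose gradient
    magnitude exceeds β·max(magnitude) each cast one vote at
    ``p + rint(n·ĝ(p))`` (votes falling outside the map are discarded),
    incrementing the orientation image and adding the magnitude to the
    magnitude image; the combined ``F_n`` is Gaussian-smoothed and the
    responses are averaged over radii.  An all-zero map yields an
    all-zero response.
    """
    if isinstance(lmap, LikelihoodMap):
        values = np.asarray(lmap.values, dtype=np.float64)
        meta = lmap.metadata
    else:
        values = np.asarray(lmap, dtype=np.float64)
        if meta is None:
            meta = ImageMetadata()
    H, W = values.shape
    radii = params.radii_px(meta)

    gy, gx = np.gradient(values)
    mag = np.hypot(gy, gx)
    max_mag = mag.max()
    if params.beta_is_relative:
        tau = params.beta * max_mag
    else:
        tau = params.beta
    mask = mag > tau if tau > 0 else mag > 0
    if not mask.any():
        return np.zeros_like(values)

    ys, xs = np.nonzero(mask)
    m = mag[ys, xs]
    uy = gy[ys, xs] / m
    ux = gx[ys, xs] / m

    response = np.zeros_like(values)
    for n in radii:
        py = ys + np.rint(n * uy).astype(np.int64)
        px = xs + np.rint(n * ux).astype(np.int64)
        inb = (py >= 0) & (py < H) & (px >= 0) & (px < W)
        O = np.zeros_like(values)
        M = np.zeros_like(values)
        np.add.at(O, (py[inb], px[inb]), 1.0)
        np.add.at(M, (py[inb], px[inb]), m[inb])
        kappa = params.kappa(n)
        O = np.minimum(O, kappa)
        F = (O / kappa) ** params.alpha * (M / kappa)
        response += ndimage.gaussian_filter(
            F, sigma=params.gaussian_sigma_factor * n, mode="constant"
        )
    response /= len(radii)
    return response


def detect_cells(
    lmap: LikelihoodMap,
    params: FRSTParams = FRSTParams(),
) -> list[Detection]:
    """Cell-center detections from a likelihood map.

    Pipeline: (1) zero the map below ``likelihood_threshold``;
    (2) FRST; (3) threshold the response at
    ``frst_response_threshold``·max; (4) 8-connected component
    labeling; (5) one detection per component at its response-weighted
    centroid (score = component max response, components smaller than
    ``min_component_px`` discarded).  Detections are ordered by (y, x).
    """
    values = np.asarray(lmap.values, dtype=np.float64)
    gated = np.where(values >= params.likelihood_threshold, values, 0.0)
    response = frst_transform(gated, params, meta=lmap.metadata)
    rmax = response.max()
    if rmax <= 0:
        return []
    thresh = params.frst_response_threshold * rmax
    binary = response > thresh
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    detections: list[Detection] = []
    for comp in range(1, n_comp + 1):
        ys, xs = np.nonzero(labels == comp)
        if len(ys) < params.min_component_px:
            continue
        w = response[ys, xs]
        wsum = w.sum()
        cy = float((ys * w).sum() / wsum)
        cx = float((xs * w).sum() / wsum)
        detections.append(
            Detection(
                x=cx,
                y=cy,
                score=float(w.max()),
                component_size=int(len(ys)),
                image_id=lmap.metadata.image_id,
            )
        )
    detections.sort(key=lambda d: (d.y, d.x))
    return detections


__all__ = ["FRSTParams", "frst_transform", "detect_cells"]
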