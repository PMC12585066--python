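"""Unsupervised probabilistic thresholding and segmentation.

With a fitted background model in hand, binarization is controlled a
priori: the acceptable false-positive fraction ``p_binarize`` is turned
into an integer count threshold by inverting the background CDF, and
pixels strictly above the threshold are set white.  Connected white
components are then extracted under 8-connectivity with an
``allowed_gap``-pixel bridging rule (runs of up to that many black pixels
along a row or column, flanked by white, are bridged before labeling;
bridging pixels are not counted in region statistics).  Each region is
scored by the upper-tail probability of its summed count under the n-fold
background model, giving a per-region significance ``p_value`` compared
against ``p_seg``.

For images with non-uniform illumination, :class:`BackgroundSegmenter`
applies the whole chain tile-wise with per-tile thresholds and models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label
from sklearn.base import BaseEstimator

from .background import fit_tiles
from .noise_model import (
    CameraParams,
    CountDistribution,
    PixelModel,
    QuadratureConfig,
    DEFAULT_QUAD,
    pmf,
    sum_count_pvalue,
)

__all__ = [
    "SegmentedRegion",
    "threshold_from_pvalue",
    "binarize",
    "segment",
    "score_regions",
    "regions_table",
    "BackgroundSegmenter",
]


@dataclass
class SegmentedRegion:
    """One segmented connected component and its significance."""

    region_id: int
    pixel_coordinates: np.ndarray  # (n, 2) array of (row, col)
    summed_count: int
    n_pixels: int
    p_value: float

    @property
    def centroid(self):
        return tuple(self.pixel_coordinates.mean(axis=0))


def threshold_from_pvalue(dist: CountDistribution, p_binarize: float = 0.01) -> int:
    """Smallest count t in the support with 1 - CDF(t) <= p_binarize.

    Binarizing with the strict rule ``count > t`` then bounds the expected
    background (false-positive) white fraction by ``p_binarize`` a priori.
    """
    if not 0.0 < p_binarize < 1.0:
        raise ValueError("p_binarize must lie in (0, 1)")
    tail = 1.0 - dist.cdf
    idx = np.nonzero(tail <= p_binarize)[0]
    if idx.size == 0:
        raise ValueError(
            "tail mass beyond the tabulated support exceeds p_binarize; "
            "widen the support")
    return int(dist.support[idx[0]])


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """White (True) where the count is strictly above the threshold."""
    return np.asarray(image) > threshold


def _bridge_gaps_1d(row: np.ndarray, gap: int) -> np.ndarray:
    """Mark runs of <= gap False pixels flanked by True on both sides."""
    out = np.zeros_like(row, dtype=bool)
    n = row.size
    i = 0
    while i < n:
        if not row[i]:
            j = i
            while j < n and not row[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def bridge_gaps(binary: np.ndarray, allowed_gap: int) -> np.ndarray:
    """Binary image with row- and column-wise gaps of length
    <= ``allowed_gap`` closed (a morphological closing restricted to
    horizontal and vertical runs)."""
    if allowed_gap < 0:
        raise ValueError("allowed_gap must be >= 0")
    binary = np.asarray(binary, dtype=bool)
    if allowed_gap == 0:
        return binary.copy()
    bridged = binary.copy()
    for r in range(binary.shape[0]):
        bridged[r] |= _bridge_gaps_1d(binary[r], allowed_gap)
    for c in range(binary.shape[1]):
        bridged[:, c] |= _bridge_gaps_1d(binary[:, c], allowed_gap)
    return bridged


def segment(binary_image: np.ndarray, allowed_gap: int = 1) -> np.ndarray:
    """Label connected components of white pixels.

    8-connectivity after gap bridging; bridging pixels transmit
    connectivity but receive no label themselves (label 0 = background),
    so region statistics stay restricted to genuine white pixels.
    """
    binary_image = np.asarray(binary_image, dtype=bool)
    bridged = bridge_gaps(binary_image, allowed_gap)
    labels = _cc_label(bridged, connectivity=2)
    labels[~binary_image] = 0
    return labels


def score_regions(label_map: np.ndarray, image: np.ndarray, model: PixelModel,
                  quad: QuadratureConfig = DEFAULT_QUAD) -> list[SegmentedRegion]:
    """Summed count and background-tail p-value for every labeled region."""
    label_map = np.asarray(label_map)
    image = np.asarray(image)
    regions = []
    for rid in np.unique(label_map):
        if rid == 0:
            continue
        coords = np.argwhere(label_map == rid)
        counts = image[coords[:, 0], coords[:, 1]]
        total = int(counts.sum())
        p = sum_count_pvalue(total, len(coords), model, quad)
        regions.append(SegmentedRegion(
            region_id=int(rid), pixel_coordinates=coords,
            summed_count=total, n_pixels=len(coords), p_value=p))
    return regions


def regions_table(regions: list[SegmentedRegion]) -> pd.DataFrame:
    rows = [{"region_id": r.region_id,
             "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
             "n_pixels": r.n_pixels, "summed_count": r.summed_count,
             "p_value": r.p_value} for r in regions]
    return pd.DataFrame(rows, columns=["region_id", "centroid_row",
                                       "centroid_col", "n_pixels",
                                       "summed_count", "p_value"])


class BackgroundSegmenter(BaseEstimator):
    """Tile-wise probabilistic thresholding and segmentation pipeline.

    ``fit`` estimates a background model per tile (truncated MLE) and the
    corresponding per-tile count thresholds; ``predict`` binarizes with
    the per-tile thresholds, bridges gaps, labels components and scores
    each region with the background model of the tile containing its
    centroid.  Tiles whose background fit did not converge are skipped
    (left black) and flagged.

    Parameters mirror the pipeline defaults: ``tile_size=64``,
    ``p_gof=p_binarize=p_seg=0.01``, ``allowed_gap=1``.
    """

    def __init__(self, params: CameraParams, tile_size: int = 64,
                 p_gof: float = 0.01, p_binarize: float = 0.01,
                 p_seg: float = 0.01, allowed_gap: int = 1,
                 n_r: int = 20001, n_k: int = 2001):
        self.params = params
        self.tile_size = tile_size
        self.p_gof = p_gof
        self.p_binarize = p_binarize
        self.p_seg = p_seg
        self.allowed_gap = allowed_gap
        self.n_r = n_r
        self.n_k = n_k

    def _quad(self):
        return QuadratureConfig(n_r=self.n_r, n_k=self.n_k)

    def fit(self, image, y=None, tile_fits: dict | None = None):
        """Fit per-tile backgrounds (or adopt precomputed ``tile_fits``)."""
        image = np.asarray(image)
        if tile_fits is None:
            tile_fits = fit_tiles(image, self.params, tile_size=self.tile_size,
                                  p_gof=self.p_gof, n_r=self.n_r, n_k=self.n_k)
        self.tile_fits_ = tile_fits
        quad = self._quad()
        self.tile_models_ = {}
        self.tile_thresholds_ = {}
        self.skipped_tiles_ = []
        for lbl, f in tile_fits.items():
            if not f.converged or not np.isfinite(f.lambda_bg):
                self.skipped_tiles_.append(lbl)
                continue
            model = PixelModel(self.params, f.lambda_bg)
            dist = pmf(model, quad=quad)
            self.tile_models_[lbl] = model
            self.tile_thresholds_[lbl] = threshold_from_pvalue(dist, self.p_binarize)
        return self

    def _tile_of(self, row: float, col: float):
        return (int(row) // self.tile_size + 1, int(col) // self.tile_size + 1)

    def threshold_image(self, image) -> np.ndarray:
        """Per-tile binarization (skipped tiles stay black)."""
        image = np.asarray(image)
        binary = np.zeros(image.shape, dtype=bool)
        ts = self.tile_size
        for (i, j), t in self.tile_thresholds_.items():
            sl = (slice((i - 1) * ts, i * ts), slice((j - 1) * ts, j * ts))
            binary[sl] = image[sl] > t
        return binary

    def predict(self, image) -> np.ndarray:
        """Label map of segmented regions; also stores ``regions_`` and
        the significant subset ``objects_`` (p_value < p_seg)."""
        image = np.asarray(image)
        binary = self.threshold_image(image)
        labels = segment(binary, allowed_gap=self.allowed_gap)
        quad = self._quad()
        regions = []
        for rid in np.unique(labels):
            if rid == 0:
                continue
            coords = np.argwhere(labels == rid)
            lbl = self._tile_of(*coords.mean(axis=0))
            model = self.tile_models_.get(lbl)
            counts = image[coords[:, 0], coords[:, 1]]
            total = int(counts.sum())
            if model is None:  # centroid in an unfitted tile
                p = float("nan")
            else:
                p = sum_count_pvalue(total, len(coords), model, quad)
            regions.append(SegmentedRegion(
                region_id=int(rid), pixel_coordinates=coords,
                summed_count=total, n_pixels=len(coords), p_value=p))
        self.binary_image_ = binary
        self.regions_ = regions
        self.objects_ = [r for r in regions
                         if np.isfinite(r.p_value) and r.p_value < self.p_seg]
        return labels

    def fit_predict(self, image, y=None) -> np.ndarray:
        return self.fit(image).predict(image)
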