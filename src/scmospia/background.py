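"""Truncated maximum-likelihood estimation of the background Poisson mean.

A fluorescence image mixes background pixels (Poisson mean lambda_bg) with
brighter signal pixels.  Fitting the full count histogram would bias
lambda_bg upward, so the fit is restricted to the lower tail: with a
truncation point T, the likelihood of the counts <= T is

    prod_j  PMF(n_j | theta) / CDF(T | theta),

with theta = (chip parameters, lambda_bg) and only lambda_bg free.  The
truncation point is chosen data-driven: candidate points descend through
the empirical count quantiles (100th to 50th percentile, steps of 2.5),
and the first (i.e. largest) candidate whose maximum-likelihood fit passes
a Pearson chi-square goodness-of-fit test at level ``p_gof`` is accepted.
On pure background the very first candidate passes and no data are
discarded; with signal contamination the descent walks below the signal
mode before passing.

Images with non-uniform illumination are handled tile-wise
(:func:`fit_tiles`), one independent fit per 64x64 tile by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .noise_model import (
    PMF_FLOOR,
    CameraParams,
    CountDistribution,
    PixelModel,
    QuadratureConfig,
    DEFAULT_QUAD,
    pmf,
)

__all__ = [
    "BackgroundFit",
    "truncated_loglik",
    "fit_lambda_bg",
    "fit_tiles",
    "tile_table",
    "TruncatedBackgroundEstimator",
]


@dataclass
class BackgroundFit:
    """Result of a truncated background fit."""

    lambda_bg: float
    trunc_point: int
    gof_pvalue: float
    n_background_pixels: int
    converged: bool
    iterations: int
    message: str = ""


def truncated_loglik(counts, trunc_point: int, model: PixelModel,
                     quad: QuadratureConfig = DEFAULT_QUAD,
                     dist: CountDistribution | None = None) -> float:
    """Truncated log-likelihood of the counts <= ``trunc_point``.

    Sum over pixels with count <= trunc_point of
    ``log PMF(count) - log CDF(trunc_point)``.  The PMF is floored at
    1e-300 before the log.  ``dist`` may supply a pre-tabulated
    distribution for ``model`` to avoid re-inversion.
    """
    counts = np.asarray(counts).ravel()
    kept = counts[counts <= trunc_point]
    if kept.size == 0:
        raise ValueError("no counts at or below the truncation point")
    if dist is None:
        dist = pmf(model, quad=quad)
    cdf_t = dist.cdf_at(int(trunc_point))
    if cdf_t <= 0.0:
        raise ValueError("model CDF is zero at the truncation point")
    values, mult = np.unique(kept, return_counts=True)
    logp = np.log(np.maximum(dist.prob(values), PMF_FLOOR))
    return float(np.sum(mult * logp) - kept.size * np.log(cdf_t))


def _hist(counts: np.ndarray):
    values, mult = np.unique(counts, return_counts=True)
    return values.astype(np.int64), mult


def _neg_trunc_loglik_hist(lam: float, values, mult, trunc_point, params, quad):
    model = PixelModel(params, max(lam, 0.0))
    with warnings.catch_warnings():
        # off-basin lambda values can leave mass outside the auto support;
        # the floored likelihood handles that, no need to warn per call
        warnings.simplefilter("ignore", UserWarning)
        dist = pmf(model, quad=quad)
    cdf_t = dist.cdf_at(int(trunc_point))
    if cdf_t <= 0.0:
        return 1e30
    logp = np.log(np.maximum(dist.prob(values), PMF_FLOOR))
    n = mult.sum()
    return -(float(np.sum(mult * logp)) - n * np.log(cdf_t))


def _mle_lambda(values, mult, trunc_point, params, quad, lam_max):
    """Maximize the truncated likelihood over lambda in [1e-6, lam_max].

    The objective is flat (floored) wherever the model support misses the
    data, so a blind bounded search can stall on the plateau; a coarse
    geometric grid (seeded with the moment estimate of lambda) locates the
    basin first and a bounded Brent search refines between the best grid
    point's neighbours to absolute tolerance 1e-4.
    """
    args = (values, mult, trunc_point, params, quad)
    kept_mean = float(np.sum(values * mult) / np.sum(mult))
    lam_moment = max((kept_mean - params.offset) / params.gain, 1e-6)
    grid = np.geomspace(1e-3, lam_max, 25)
    grid = np.unique(np.clip(np.append(grid, lam_moment), 1e-6, lam_max))
    vals = [_neg_trunc_loglik_hist(l, *args) for l in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        _neg_trunc_loglik_hist, bounds=(lo, hi), args=args,
        method="bounded", options={"xatol": 1e-4})
    return float(res.x)


def _gof_pvalue(values, mult, trunc_point, model, quad, min_expected=5.0):
    """Pearson chi-square GoF of the truncated model to the kept counts.

    Count-value bins are merged left to right until every expected count
    is >= ``min_expected``; degrees of freedom = bins - 2 (one for the
    fitted lambda).  Returns (p_value, n_bins); p is nan when fewer than
    3 merged bins remain.
    """
    dist = pmf(model, quad=quad)
    cdf_t = dist.cdf_at(int(trunc_point))
    if cdf_t <= 0.0:
        return float("nan"), 0
    n = int(mult.sum())
    # all integer count values from the low edge of the model support
    # (or the smallest observed count) up to the truncation point
    lo = min(int(dist.support[0]), int(values[0]))
    allv = np.arange(lo, int(trunc_point) + 1, dtype=np.int64)
    expected = n * dist.prob(allv) / cdf_t
    observed = np.zeros_like(expected)
    observed[values - lo] = mult

    obs_bins, exp_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if o_acc > 0 or e_acc > 0:
        if exp_bins:
            obs_bins[-1] += o_acc
            exp_bins[-1] += e_acc
        else:
            obs_bins, exp_bins = [o_acc], [e_acc]
    obs_bins = np.asarray(obs_bins)
    exp_bins = np.asarray(exp_bins)
    # normalization mismatch between truncated model and sample is absorbed
    exp_bins *= obs_bins.sum() / exp_bins.sum()
    n_bins = len(obs_bins)
    if n_bins < 3:
        return float("nan"), n_bins
    stat = float(np.sum((obs_bins - exp_bins) ** 2 / exp_bins))
    dof = n_bins - 2
    return float(chi2.sf(stat, dof)), n_bins


class TruncatedBackgroundEstimator(BaseEstimator):
    """Sklearn-style estimator for the background Poisson mean lambda_bg.

    Parameters
    ----------
    params : CameraParams
        Calibrated chip parameters.
    p_gof : float
        Significance level of the truncation goodness-of-fit test.
    quantile_stop, quantile_step : float
        The truncation candidates are the descending empirical percentiles
        from 100 down to ``quantile_stop`` in steps of ``quantile_step``.
    min_pixels : int
        Abort the descent when fewer counts than this remain below the
        candidate truncation.
    n_r, n_k : int
        Quadrature resolutions of the underlying PMF inversion.

    Fitted attributes: ``lambda_bg_``, ``trunc_point_``, ``gof_pvalue_``,
    ``n_background_pixels_``, ``converged_``, ``iterations_``, ``result_``.
    """

    def __init__(self, params: CameraParams, p_gof: float = 0.01,
                 quantile_stop: float = 50.0, quantile_step: float = 2.5,
                 min_pixels: int = 100, n_r: int = 20001, n_k: int = 2001):
        self.params = params
        self.p_gof = p_gof
        self.quantile_stop = quantile_stop
        self.quantile_step = quantile_step
        self.min_pixels = min_pixels
        self.n_r = n_r
        self.n_k = n_k

    def fit(self, counts, y=None):
        counts = np.asarray(counts).ravel()
        if counts.size < self.min_pixels:
            raise ValueError(f"need at least {self.min_pixels} counts")
        params = self.params
        quad = QuadratureConfig(n_r=self.n_r, n_k=self.n_k)
        lam_max = max((counts.max() - params.offset) / params.gain, 0.0) + 5.0

        qs = np.arange(100.0, self.quantile_stop - 1e-9, -self.quantile_step)
        # descending, deduplicated integer truncation candidates
        cand = np.unique(np.floor(np.percentile(counts, qs)).astype(np.int64))[::-1]

        lam = float("nan")
        trunc = int(counts.max())
        p_val = float("nan")
        n_kept = 0
        it = 0
        converged = False
        msg = ""
        for trunc in cand:
            kept = counts[counts <= trunc]
            if kept.size < self.min_pixels:
                msg = "pixel floor reached before any truncation passed"
                break
            it += 1
            values, mult = _hist(kept)
            lam = _mle_lambda(values, mult, trunc, params, quad, lam_max)
            model = PixelModel(params, lam)
            p_val, _ = _gof_pvalue(values, mult, trunc, model, quad)
            n_kept = int(kept.size)
            if np.isfinite(p_val) and p_val >= self.p_gof:
                converged = True
                break
        if not converged and not msg:
            msg = "no truncation point passed the goodness-of-fit test"
        if converged and lam >= lam_max - 1e-3:
            warnings.warn("lambda_bg estimate sits at the optimizer bound",
                          stacklevel=2)

        self.lambda_bg_ = lam
        self.trunc_point_ = int(trunc)
        self.gof_pvalue_ = p_val
        self.n_background_pixels_ = n_kept
        self.converged_ = converged
        self.iterations_ = it
        self.result_ = BackgroundFit(
            lambda_bg=lam, trunc_point=int(trunc), gof_pvalue=p_val,
            n_background_pixels=n_kept, converged=converged,
            iterations=it, message=msg)
        return self


def fit_lambda_bg(counts, params: CameraParams, p_gof: float = 0.01,
                  **kwargs) -> BackgroundFit:
    """Truncated MLE of lambda_bg; see :class:`TruncatedBackgroundEstimator`."""
    est = TruncatedBackgroundEstimator(params, p_gof=p_gof, **kwargs).fit(counts)
    return est.result_


def fit_tiles(image: np.ndarray, params: CameraParams, tile_size: int = 64,
              p_gof: float = 0.01, min_pixels: int = 100,
              **kwargs) -> dict:
    """Independent truncated background fit per image tile.

    The image is partitioned into ``tile_size`` x ``tile_size`` tiles
    labelled ``(row, col)`` starting at (1, 1); edge tiles may be smaller
    and are fitted when they hold at least ``min_pixels`` pixels,
    otherwise flagged unconverged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(image.shape) < 1:
        raise ValueError("image is empty")
    fits = {}
    n_rows = int(np.ceil(image.shape[0] / tile_size))
    n_cols = int(np.ceil(image.shape[1] / tile_size))
    for i in range(n_rows):
        for j in range(n_cols):
            tile = image[i * tile_size:(i + 1) * tile_size,
                         j * tile_size:(j + 1) * tile_size]
            label = (i + 1, j + 1)
            if tile.size < min_pixels:
                fits[label] = BackgroundFit(
                    lambda_bg=float("nan"), trunc_point=-1,
                    gof_pvalue=float("nan"), n_background_pixels=0,
                    converged=False, iterations=0,
                    message=f"edge tile below the {min_pixels}-pixel floor")
                continue
            fits[label] = fit_lambda_bg(tile, params, p_gof=p_gof,
                                        min_pixels=min_pixels, **kwargs)
    return fits


def tile_table(fits: dict) -> pd.DataFrame:
    """Per-tile results as a table, with across-tile mean/std of lambda_bg
    (converged tiles only) available via ``df.attrs``."""
    rows = [
        {"tile_row": r, "tile_col": c, "lambda_bg": f.lambda_bg,
         "trunc_point": f.trunc_point, "gof_pvalue": f.gof_pvalue,
         "n_background_pixels": f.n_background_pixels,
         "converged": f.converged}
        for (r, c), f in sorted(fits.items())
    ]
    df = pd.DataFrame(rows)
    lam = df.loc[df["converged"], "lambda_bg"]
    df.attrs["lambda_bg_mean"] = float(lam.mean()) if len(lam) else float("nan")
    df.attrs["lambda_bg_std"] = float(lam.std(ddof=0)) if len(lam) else float("nan")
    return df
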