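"""Camera calibration: gain, offset and Tukey-Lambda read-noise parameters.

Three estimators cover the calibration experiments:

* :class:`OffsetEstimator` — the offset Delta is the mean count of a dark
  (cap-on) frame.
* :class:`GainEstimator` — photon-transfer (mean-variance) analysis: over
  the white-wall stacks the per-pixel temporal variance is linear in the
  offset-subtracted temporal mean, Var = g (mean - Delta) + d, so an
  ordinary least-squares fit yields the gain g as the slope and the
  constant d = s^2_TL + 1/12 as the intercept.
* :class:`TukeyLambdaPPCC` — probability-plot correlation coefficient fit
  of the read-noise shape and scale to offset-subtracted dark counts:
  for each candidate shape the Pearson correlation between the empirical
  quantiles and the unscaled theoretical quantiles at plotting positions
  (j - 0.5)/m is computed; the maximizing shape is kept and the scale is
  the least-squares slope of the QQ line.

All estimators follow sklearn conventions (constructor parameters, fitted
attributes with trailing underscores); the module-level functions are thin
wrappers returning small result dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .noise_model import CameraParams, tl_quantile, tl_variance

__all__ = [
    "MeanVarianceData",
    "GainFit",
    "PPCCFit",
    "mean_variance_from_stack",
    "estimate_gain",
    "estimate_offset",
    "ppcc_fit",
    "consistency_check",
    "calibrate_camera",
    "OffsetEstimator",
    "GainEstimator",
    "TukeyLambdaPPCC",
]


@dataclass
class MeanVarianceData:
    """Per-pixel temporal (mean, variance) pairs from bright stacks."""

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.variances = np.asarray(self.variances, dtype=float).ravel()
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have equal length")
        if np.any(self.variances < 0):
            raise ValueError("variances must be nonnegative")

    @property
    def pixel_count(self) -> int:
        return self.means.size

    @classmethod
    def concat(cls, parts) -> "MeanVarianceData":
        """Pool pixels from several intensity levels into one dataset."""
        return cls(np.concatenate([p.means for p in parts]),
                   np.concatenate([p.variances for p in parts]))


@dataclass
class GainFit:
    """Photon-transfer fit: slope = gain, intercept = fitted d."""

    gain: float
    intercept: float
    gain_stderr: float
    expected_intercept: float | None = None


@dataclass
class PPCCFit:
    """Result of the PPCC read-noise fit."""

    tl_shape: float
    tl_scale: float
    max_pcc: float
    qq_intercept: float
    shape_grid: np.ndarray
    pcc_curve: np.ndarray


def mean_variance_from_stack(stack: np.ndarray) -> MeanVarianceData:
    """Per-pixel temporal mean and unbiased variance of a frame stack.

    ``stack`` is a 3-D array (frames x rows x cols) with at least 2 frames.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames x rows x cols)")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames to estimate a variance")
    s = stack.astype(float)
    return MeanVarianceData(s.mean(axis=0), s.var(axis=0, ddof=1))


class OffsetEstimator(BaseEstimator):
    """Offset Delta as the mean count of a dark (cap-on) frame.

    Fitted attributes: ``offset_`` (ADU), ``stderr_`` (standard error of
    the mean), ``n_pixels_``.
    """

    def fit(self, dark_frame, y=None):
        x = np.asarray(dark_frame, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("dark frame is empty")
        self.offset_ = float(x.mean())
        self.stderr_ = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        self.n_pixels_ = int(x.size)
        return self


class GainEstimator(BaseEstimator):
    """Gain from the mean-variance (photon-transfer) line.

    Ordinary least squares of per-pixel temporal variance against the
    offset-subtracted temporal mean: Var = g (mean - offset) + d.
    Deliberately unweighted.

    Parameters
    ----------
    offset : float
        Offset Delta subtracted from the means (estimate it first from a
        dark frame).

    Fitted attributes: ``gain_``, ``intercept_``, ``gain_stderr_``.
    """

    def __init__(self, offset: float = 0.0):
        self.offset = offset

    def fit(self, means, variances=None):
        if isinstance(means, MeanVarianceData):
            data = means
        else:
            data = MeanVarianceData(means, variances)
        x = data.means - self.offset
        if np.ptp(x) == 0:
            raise ValueError("pixel means are degenerate (single intensity level)")
        res = stats.linregress(x, data.variances)
        self.gain_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.gain_stderr_ = float(res.stderr)
        return self


class TukeyLambdaPPCC(BaseEstimator):
    """PPCC fit of Tukey-Lambda read-noise shape and scale to dark counts.

    The offset-subtracted dark counts are sorted into empirical quantiles
    Q_emp; for each shape candidate L on the grid the unscaled theoretical
    quantiles F_j = Q((j - 0.5)/m; L) are correlated with Q_emp, the shape
    maximizing the Pearson correlation is selected, and the scale is the
    OLS slope of Q_emp on F at that shape (the QQ intercept is kept as a
    diagnostic, expected near 0).  Quantization noise in the dark counts
    is neglected, exactly as the estimation procedure prescribes.

    Parameters
    ----------
    offset : float
        Offset Delta to subtract before fitting.
    shape_grid : array, optional
        Shape candidates; default [-1, 1] in steps of 0.005, refined once
        with step 0.0005 around the coarse optimum.
    refine : bool
        Whether to run the local refinement pass.
    max_pixels : int
        Frames larger than this are subsampled (seeded) before sorting.
    random_state : int
    """

    #: coarse grid step over [-1, 1] and the one-pass refinement step
    COARSE_STEP = 0.005
    FINE_STEP = 0.0005

    def __init__(self, offset: float = 0.0, shape_grid=None, refine: bool = True,
                 max_pixels: int = 10**6, random_state: int = 0):
        self.offset = offset
        self.shape_grid = shape_grid
        self.refine = refine
        self.max_pixels = max_pixels
        self.random_state = random_state

    @staticmethod
    def _pcc_scan(q_emp: np.ndarray, log_u: np.ndarray, log_1mu: np.ndarray,
                  grid: np.ndarray) -> np.ndarray:
        """Pearson correlation of Q_emp with F_theory(L) for each L in grid."""
        qc = q_emp - q_emp.mean()
        q_ss = np.sqrt(np.sum(qc**2))
        rho = np.empty(grid.size)
        for i, L in enumerate(grid):
            if abs(L) < 1e-10:
                f = log_u - log_1mu
            else:
                f = (np.exp(L * log_u) - np.exp(L * log_1mu)) / L
            fc = f - f.mean()
            denom = q_ss * np.sqrt(np.sum(fc**2))
            rho[i] = np.sum(qc * fc) / denom if denom > 0 else 0.0
        return rho

    def fit(self, dark_counts, y=None):
        x = np.asarray(dark_counts, dtype=float).ravel()
        if x.size < 100:
            raise ValueError("need at least 100 pixels for a PPCC fit")
        if np.ptp(x) == 0:
            raise ValueError("all counts identical: zero variance")
        if x.size > self.max_pixels:
            rng = np.random.default_rng(self.random_state)
            x = rng.choice(x, size=self.max_pixels, replace=False)
        q_emp = np.sort(x - self.offset)
        m = q_emp.size
        u = (np.arange(1, m + 1) - 0.5) / m
        log_u, log_1mu = np.log(u), np.log1p(-u)

        if self.shape_grid is not None:
            grid = np.asarray(self.shape_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("shape grid is empty")
        else:
            n = int(round(2.0 / self.COARSE_STEP)) + 1
            grid = np.linspace(-1.0, 1.0, n)
        rho = self._pcc_scan(q_emp, log_u, log_1mu, grid)
        best = float(grid[np.argmax(rho)])

        if self.refine and self.shape_grid is None:
            lo = max(-1.0, best - self.COARSE_STEP)
            hi = min(1.0, best + self.COARSE_STEP)
            n_f = int(round((hi - lo) / self.FINE_STEP)) + 1
            fine = np.linspace(lo, hi, n_f)
            rho_f = self._pcc_scan(q_emp, log_u, log_1mu, fine)
            if rho_f.max() >= rho.max():
                best = float(fine[np.argmax(rho_f)])

        f_best = tl_quantile(u, best)
        slope, intercept = np.polyfit(f_best, q_emp, 1)
        self.tl_shape_ = best
        self.tl_scale_ = float(slope)
        self.qq_intercept_ = float(intercept)
        self.max_pcc_ = float(rho.max())
        self.shape_grid_ = grid
        self.pcc_curve_ = rho
        return self


def estimate_offset(dark_frame) -> float:
    """Mean count of a dark frame (the offset Delta, ADU)."""
    return OffsetEstimator().fit(dark_frame).offset_


def estimate_gain(data: MeanVarianceData, offset: float) -> GainFit:
    """OLS photon-transfer fit; see :class:`GainEstimator`."""
    est = GainEstimator(offset=offset).fit(data)
    return GainFit(gain=est.gain_, intercept=est.intercept_,
                   gain_stderr=est.gain_stderr_)


def ppcc_fit(dark_frame, offset: float, shape_grid=None, **kwargs) -> PPCCFit:
    """PPCC read-noise fit; see :class:`TukeyLambdaPPCC`."""
    est = TukeyLambdaPPCC(offset=offset, shape_grid=shape_grid, **kwargs).fit(dark_frame)
    return PPCCFit(tl_shape=est.tl_shape_, tl_scale=est.tl_scale_,
                   max_pcc=est.max_pcc_, qq_intercept=est.qq_intercept_,
                   shape_grid=est.shape_grid_, pcc_curve=est.pcc_curve_)


def consistency_check(params: CameraParams, fitted_intercept: float):
    """Expected photon-transfer intercept d = s^2_TL + 1/12 and the
    discrepancy of the fitted intercept from it.

    Returns ``(expected_d, fitted_intercept - expected_d)``.
    """
    expected_d = tl_variance(params.tl_shape, params.tl_scale) + 1.0 / 12.0
    return expected_d, fitted_intercept - expected_d


def calibrate_camera(dark_frames, whitewall_stacks=None) -> dict:
    """Full calibration from dark frames and (optionally) white-wall stacks.

    Each dark frame gets an independent PPCC fit; the reported shape and
    scale are the across-frame mean (with standard deviation).  The gain
    fit pools the per-pixel mean-variance points of all intensity levels
    into a single regression.

    Returns a report dict holding the :class:`CameraParams` (under
    ``"params"``, gain absent -> None) plus diagnostics.
    """
    dark_frames = [np.asarray(f) for f in _iter_frames(dark_frames)]
    off_est = OffsetEstimator().fit(np.concatenate([f.ravel() for f in dark_frames]))
    offset = off_est.offset_

    shapes, scales, pccs = [], [], []
    for f in dark_frames:
        r = ppcc_fit(f, offset)
        shapes.append(r.tl_shape)
        scales.append(r.tl_scale)
        pccs.append(r.max_pcc)
    tl_shape = float(np.mean(shapes))
    tl_scale = float(np.mean(scales))

    report = {
        "offset": offset,
        "offset_stderr": off_est.stderr_,
        "tl_shape": tl_shape,
        "tl_shape_std": float(np.std(shapes)),
        "tl_scale": tl_scale,
        "tl_scale_std": float(np.std(scales)),
        "max_pcc": float(np.mean(pccs)),
        "n_dark_frames": len(dark_frames),
    }

    if whitewall_stacks:
        data = MeanVarianceData.concat(
            [mean_variance_from_stack(s) for s in whitewall_stacks])
        gf = estimate_gain(data, offset)
        params = CameraParams(gain=gf.gain, tl_shape=tl_shape,
                              tl_scale=tl_scale, offset=offset)
        expected_d, disc = consistency_check(params, gf.intercept)
        report.update({
            "gain": gf.gain,
            "gain_stderr": gf.gain_stderr,
            "fitted_intercept": gf.intercept,
            "expected_intercept": expected_d,
            "intercept_discrepancy": disc,
            "params": params,
        })
    else:
        report.update({"gain": None, "params": None})
    return report


def _iter_frames(frames):
    """Yield 2-D frames from a 2-D array, 3-D stack, or list thereof."""
    if isinstance(frames, np.ndarray):
        if frames.ndim == 2:
            yield frames
        elif frames.ndim == 3:
            yield from frames
        else:
            raise ValueError("expected 2-D frame or 3-D stack")
    else:
        for f in frames:
            yield from _iter_frames(np.asarray(f))
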