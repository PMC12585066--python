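"""Forward-model sCMOS camera simulator.

Generates the three kinds of calibration/analysis inputs the pipeline
consumes — cap-on dark frames, multi-intensity white-wall stacks and mixed
background/signal fluorescence scenes — with exactly the statistical
structure of the noise model: Poisson photoelectrons, Tukey-Lambda read
noise drawn through the quantile transform of a uniform variable, and
quantization realised by rounding the analog sum to the nearest integer
(equivalent in distribution to adding a uniform(-1/2, 1/2) error and
rounding, so the quantization term is never double-counted).

Counts are clipped at 0 like a real ADC; with typical offsets near 100 ADU
the clip is never active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk, line as _draw_line

from .noise_model import CameraParams, tl_quantile

__all__ = [
    "Disc",
    "Rect",
    "LineSegment",
    "SceneSpec",
    "sample_counts",
    "make_capon_frames",
    "make_whitewall_stacks",
    "make_scene",
]


@dataclass(frozen=True)
class Disc:
    """Filled disc primitive (row, col center; radius in pixels)."""
    row: float
    col: float
    radius: float

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = _draw_disk((self.row, self.col), self.radius, shape=shape)
        m[rr, cc] = True
        return m


@dataclass(frozen=True)
class Rect:
    """Axis-aligned filled rectangle, inclusive pixel bounds."""
    row0: int
    col0: int
    row1: int
    col1: int

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0:self.row1 + 1, self.col0:self.col1 + 1] = True
        return m


@dataclass(frozen=True)
class LineSegment:
    """Line segment with a width, emulating stretched DNA molecules."""
    row0: int
    col0: int
    row1: int
    col1: int
    width: int = 1

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = _draw_line(self.row0, self.col0, self.row1, self.col1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        m[rr[keep], cc[keep]] = True
        if self.width > 1:
            from scipy.ndimage import binary_dilation
            m = binary_dilation(m, iterations=self.width - 1)
        return m


@dataclass
class SceneSpec:
    """Specification of a synthetic fluorescence scene.

    ``objects`` is a sequence of ``(primitive_or_mask, signal_lambda)``
    pairs; inside object masks the per-pixel Poisson mean is the signal
    value, elsewhere it is ``background_lambda``.  Overlapping objects take
    the maximum lambda.  ``exposure_scale`` multiplies every lambda,
    emulating exposure time.
    """

    shape: tuple
    background_lambda: float
    objects: list = field(default_factory=list)
    exposure_scale: float = 1.0
    seed: int = 0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_field(lam_map: np.ndarray, params: CameraParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw integer counts for a field of per-pixel Poisson means."""
    n_oe = rng.poisson(lam_map)
    u = rng.uniform(size=lam_map.shape)
    read = params.tl_scale * tl_quantile(np.clip(u, 1e-15, 1 - 1e-15), params.tl_shape)
    analog = params.gain * n_oe + read + params.offset
    counts = np.rint(analog)
    return np.clip(counts, 0, None).astype(np.int64)


def sample_counts(lam: float, params: CameraParams, n: int, seed=0) -> np.ndarray:
    """Draw ``n`` independent image counts for Poisson mean ``lam``.

    Reproducible for a given ``seed`` (an int or a numpy Generator).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return _sample_field(np.full(n, float(lam)), params, rng)


def make_capon_frames(params: CameraParams, shape=(1412, 1412),
                      n_frames: int = 1, seed=0) -> np.ndarray:
    """Dark (cap-on) frames: lambda = 0, so counts = round(read noise + offset)."""
    rng = _as_rng(seed)
    lam_map = np.zeros(shape, dtype=float)
    frames = np.stack([_sample_field(lam_map, params, rng) for _ in range(n_frames)])
    return frames


def make_whitewall_stacks(params: CameraParams, lambdas, n_frames: int = 200,
                          shape=(64, 64), seed=0) -> list[np.ndarray]:
    """Uniformly illuminated stacks, one per intensity level.

    Emulates the white-wall calibration movie: each stack holds
    ``n_frames`` frames of i.i.d. counts at a fixed Poisson mean.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas <= 0):
        raise ValueError("lambdas must be strictly positive")
    rng = _as_rng(seed)
    stacks = []
    for lam in lambdas:
        lam_map = np.full(shape, lam)
        stacks.append(np.stack(
            [_sample_field(lam_map, params, rng) for _ in range(n_frames)]))
    return stacks


def make_scene(spec: SceneSpec, params: CameraParams):
    """Render a scene to (counts image, ground-truth signal mask).

    Returns
    -------
    image : 2-D int array
    signal_mask : 2-D bool array
        True exactly where an object primitive/mask places signal.
    """
    shape = tuple(spec.shape)
    lam_map = np.full(shape, float(spec.background_lambda))
    signal_mask = np.zeros(shape, dtype=bool)
    for obj, lam_sig in spec.objects:
        if lam_sig < 0:
            raise ValueError("signal lambda must be nonnegative")
        m = obj if isinstance(obj, np.ndarray) else obj.mask(shape)
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError("object mask shape does not match scene shape")
        # overlapping objects take the maximum lambda
        lam_map[m] = np.maximum(lam_map[m], float(lam_sig))
        signal_mask |= m
    lam_map *= spec.exposure_scale
    rng = _as_rng(spec.seed)
    image = _sample_field(lam_map, params, rng)
    return image, signal_mask
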