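"""Retinex-style low-light enhancement with local overexposure correction.

The image is decomposed as reflectance x illumination.  The illumination
component L is initialized from the per-pixel channel maximum (the local
maximum prior), with a dynamic truncation that prevents over-exposed pixels
from seeding the estimate, and refined by minimizing an attention-weighted
fidelity term plus a total-variation smoothness penalty:

    loss(L) = sum A * (L - L0)^2 + lambda_tv * TV(L),

subject to channel_max(image) <= L <= 1 (keeps reflectance <= 1).
Over-exposure is detected by a multi-scale block analysis: each n x n block
(n in {2, 4, 6, 8}) receives a block exposure fitness fbc in [0, 1] and is
flagged over-exposed when fbc > 0.65; per-pixel scores fuse the scales with
weights proportional to 1/n.  The attention map A is 0.1 on over-exposed
pixels and 1.0 elsewhere; it down-weights both the refinement loss and the
final enhancement so bright regions are not boosted further.

This is a per-image, training-free optimization (no network, no data): the
same decomposition and constraints as learning-based Retinex enhancers, run
as projected gradient descent on each input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ExposureLabel",
    "ExposureBlockStats",
    "ExposureMatrix",
    "AttentionMap",
    "IlluminationEstimate",
    "EnhanceConfig",
    "normalize_image",
    "block_exposure_fitness",
    "classify_exposure",
    "exposure_matrix",
    "attention_map",
    "init_illumination",
    "tv_norm",
    "refine_illumination",
    "enhance",
]

OVEREXPOSURE_THRESHOLD = 0.65  # fbc above this marks a block over-exposed
DEFAULT_BLOCK_SIZES = (2, 4, 6, 8)


class ExposureLabel(str, Enum):
    WELL_EXPOSED = "well_exposed"
    OVER_EXPOSED = "over_exposed"


@dataclass
class ExposureBlockStats:
    block_size: int
    block_index: tuple[int, int]
    v_mean: float
    v_std: float
    fbc: float
    label: ExposureLabel


@dataclass
class ExposureMatrix:
    """Per-pixel weighted overexposure score and its binary mask."""

    map: np.ndarray
    mask: np.ndarray
    block_sizes: tuple[int, ...]
    scale_weights: tuple[float, ...]


@dataclass
class AttentionMap:
    """Binary attention weights: low on over-exposed pixels, high elsewhere."""

    a: np.ndarray
    low_weight: float = 0.1
    high_weight: float = 1.0


@dataclass
class IlluminationEstimate:
    l: np.ndarray
    iterations_run: int
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class EnhanceConfig:
    """Tunables for the full enhancement pipeline."""

    lambda_tv: float = 0.15
    iters: int = 100
    step: float = 0.05
    gamma: float = 0.8
    use_attention: bool = True
    truncation_percentile: float = 95.0
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    lambda_c: float = 0.0
    low_weight: float = 0.1
    high_weight: float = 1.0
    eps: float = 1e-4


def _value_channel(image: np.ndarray) -> np.ndarray:
    """Per-pixel channel maximum; the image itself for single-channel input."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.max(axis=-1)
    return image


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-channel min-max scaling to [0, 1]; a constant channel maps to 0."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot normalize an empty image")

    def _scale(chan: np.ndarray) -> np.ndarray:
        lo, hi = chan.min(), chan.max()
        if hi - lo == 0:
            return np.zeros_like(chan)
        return (chan - lo) / (hi - lo)

    if image.ndim == 3:
        return np.stack([_scale(image[..., c]) for c in range(image.shape[-1])], axis=-1)
    return _scale(image)


def block_exposure_fitness(block: np.ndarray, lambda_c: float = 0.0) -> float:
    """Block exposure fitness in [0, 1].

    Default is the block mean brightness (values near 0.5 read as optimal
    exposure, above 0.65 as over-exposure); ``lambda_c`` adds a local-contrast
    term, the deviation of pixels from the block mean.
    """
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise ValueError("empty block")
    fbc = block.mean() + lambda_c * block.std()
    return float(np.clip(fbc, 0.0, 1.0))


def classify_exposure(fbc: float) -> ExposureLabel:
    """Well-exposed iff fbc <= 0.65, over-exposed otherwise."""
    if not 0.0 <= fbc <= 1.0:
        raise ValueError("fbc must lie in [0, 1]")
    if fbc > OVEREXPOSURE_THRESHOLD:
        return ExposureLabel.OVER_EXPOSED
    return ExposureLabel.WELL_EXPOSED


def _block_label_map(v: np.ndarray, n: int, lambda_c: float) -> np.ndarray:
    """Binary over-exposure labels per pixel for one block size (reflect-pad
    to a multiple of n, label whole blocks, broadcast back, crop)."""
    h, w = v.shape
    ph, pw = (-h) % n, (-w) % n
    vp = np.pad(v, ((0, ph), (0, pw)), mode="reflect")
    bh, bw = vp.shape[0] // n, vp.shape[1] // n
    blocks = vp.reshape(bh, n, bw, n)
    means = blocks.mean(axis=(1, 3))
    fbc = means
    if lambda_c != 0.0:
        fbc = np.clip(means + lambda_c * blocks.std(axis=(1, 3)), 0.0, 1.0)
    labels = (fbc > OVEREXPOSURE_THRESHOLD).astype(float)
    per_pixel = np.repeat(np.repeat(labels, n, axis=0), n, axis=1)
    return per_pixel[:h, :w]


def exposure_matrix(image: np.ndarray,
                    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES,
                    scale_weights: tuple[float, ...] | None = None,
                    lambda_c: float = 0.0) -> ExposureMatrix:
    """Multi-scale per-pixel overexposure score.

    Smaller blocks get higher weight (default w proportional to 1/n,
    renormalized); per-pixel score is the weighted vote of the per-scale
    block labels and the mask thresholds it at 0.5.
    """
    v = _value_channel(image)
    block_sizes = tuple(int(n) for n in block_sizes)
    if min(v.shape) < max(block_sizes):
        raise ValueError("image is smaller than the largest block size")
    if scale_weights is None:
        raw = np.array([1.0 / n for n in block_sizes])
        scale_weights = tuple(raw / raw.sum())
    else:
        scale_weights = tuple(float(w) for w in scale_weights)
        if abs(sum(scale_weights) - 1.0) > 1e-9:
            raise ValueError("scale_weights must sum to 1")
    score = np.zeros_like(v)
    for n, w in zip(block_sizes, scale_weights):
        score += w * _block_label_map(v, n, lambda_c)
    return ExposureMatrix(score, score > 0.5, block_sizes, scale_weights)


def attention_map(matrix: ExposureMatrix, low: float = 0.1,
                  high: float = 1.0) -> AttentionMap:
    """Binary attention weights from the overexposure mask."""
    if low >= high:
        raise ValueError("low weight must be smaller than high weight")
    a = np.where(matrix.mask, low, high)
    return AttentionMap(a, low, high)


def init_illumination(image: np.ndarray, matrix: ExposureMatrix,
                      truncation_percentile: float = 95.0) -> np.ndarray:
    """Channel-max illumination prior with dynamic truncation.

    Over-exposed pixels must not seed the illumination estimate at their own
    (saturated) value, so inside the mask the prior is capped at the given
    percentile of the prior over well-exposed pixels (global percentile if
    everything is masked).
    """
    l0 = _value_channel(image).copy()
    mask = matrix.mask
    if mask.any():
        reference = l0[~mask] if (~mask).any() else l0
        cap = np.percentile(reference, truncation_percentile)
        l0[mask] = np.minimum(l0[mask], cap)
    return l0


def tv_norm(l: np.ndarray) -> float:
    """Anisotropic total variation: sum of absolute forward differences."""
    l = np.asarray(l, dtype=float)
    return float(np.abs(np.diff(l, axis=0)).sum() + np.abs(np.diff(l, axis=1)).sum())


def _tv_gradient(l: np.ndarray, delta: float = 1e-3) -> np.ndarray:
    """Smoothed subgradient of the anisotropic TV (Charbonnier slope)."""
    grad = np.zeros_like(l)
    dy = np.diff(l, axis=0)
    sy = dy / np.sqrt(dy ** 2 + delta ** 2)
    grad[1:, :] += sy
    grad[:-1, :] -= sy
    dx = np.diff(l, axis=1)
    sx = dx / np.sqrt(dx ** 2 + delta ** 2)
    grad[:, 1:] += sx
    grad[:, :-1] -= sx
    return grad


def refine_illumination(image: np.ndarray, l0: np.ndarray,
                        a: AttentionMap | None = None,
                        lambda_tv: float = 0.15, iters: int = 100,
                        step: float = 0.05, eps: float = 1e-4,
                        backtrack: bool = True) -> IlluminationEstimate:
    """Minimize sum A*(L-L0)^2 + lambda_tv*TV(L) by projected gradient descent.

    The projection clips L to [channel_max(image), 1] and then to [eps, 1], so
    the reflectance image / L never exceeds 1.  With ``backtrack`` (default)
    the step is halved whenever a move would increase the loss, which makes
    the recorded loss trace non-increasing; with ``backtrack=False`` raw steps
    are taken and more than 5 consecutive loss increases raise an error
    suggesting a smaller step.
    """
    if lambda_tv < 0:
        raise ValueError("lambda_tv must be nonnegative")
    l0 = np.asarray(l0, dtype=float)
    if np.any(l0 <= 0) or np.any(l0 > 1):
        l0 = np.clip(l0, eps, 1.0)
    weights = a.a if a is not None else np.ones_like(l0)
    floor = np.clip(_value_channel(image), eps, 1.0)

    def project(l: np.ndarray) -> np.ndarray:
        return np.clip(np.clip(l, floor, 1.0), eps, 1.0)

    def loss(l: np.ndarray) -> float:
        return float(np.sum(weights * (l - l0) ** 2) + lambda_tv * tv_norm(l))

    l = project(l0)
    current = loss(l)
    trace = [current]
    s = step
    consecutive_up = 0
    for _ in range(iters):
        grad = 2.0 * weights * (l - l0)
        if lambda_tv > 0:
            grad = grad + lambda_tv * _tv_gradient(l)
        if backtrack:
            accepted = False
            for _halving in range(30):
                candidate = project(l - s * grad)
                cand_loss = loss(candidate)
                if cand_loss <= current + 1e-15:
                    accepted = True
                    break
                s *= 0.5
            if not accepted:
                candidate, cand_loss = l, current  # converged: no descent step
        else:
            candidate = project(l - s * grad)
            cand_loss = loss(candidate)
            if cand_loss > current:
                consecutive_up += 1
                if consecutive_up > 5:
                    raise RuntimeError(
                        "illumination refinement diverged (loss increased for "
                        ">5 consecutive iterations); use a smaller step"
                    )
            else:
                consecutive_up = 0
        l, current = candidate, cand_loss
        trace.append(current)
    return IlluminationEstimate(l, len(trace) - 1, trace)


def _prepare_input(image: np.ndarray) -> np.ndarray:
    """Bring the input to float [0, 1].

    Integer images are scaled by their dtype maximum; float images already in
    [0, 1] are used as-is (so absolute brightness is preserved); anything else
    is min-max normalized.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    if arr.min() >= 0.0 and arr.max() <= 1.0:
        return arr
    return normalize_image(arr)


def enhance(image: np.ndarray, config: EnhanceConfig | None = None,
            return_details: bool = False):
    """Full low-light enhancement pipeline.

    normalize -> exposure analysis -> attention map -> truncated illumination
    init -> TV-smoothed refinement -> reflectance output x / L^gamma, with the
    attention map gating the enhancement so over-exposed regions keep close to
    their original values.  Output is in [0, 1].
    """
    cfg = config or EnhanceConfig()
    x = _prepare_input(image)
    matrix = exposure_matrix(x, cfg.block_sizes, lambda_c=cfg.lambda_c)
    if cfg.use_attention:
        amap = attention_map(matrix, cfg.low_weight, cfg.high_weight)
    else:
        amap = AttentionMap(np.full(matrix.mask.shape, cfg.high_weight),
                            cfg.low_weight, cfg.high_weight)
    l0 = init_illumination(x, matrix, cfg.truncation_percentile)
    estimate = refine_illumination(x, l0, amap, cfg.lambda_tv, cfg.iters,
                                   cfg.step, cfg.eps)
    l_gamma = np.maximum(estimate.l, cfg.eps) ** cfg.gamma
    if x.ndim == 3:
        reflectance = x / l_gamma[..., None]
        weight = (amap.a / amap.high_weight)[..., None]
    else:
        reflectance = x / l_gamma
        weight = amap.a / amap.high_weight
    out = np.clip(weight * reflectance + (1.0 - weight) * x, 0.0, 1.0)
    if return_details:
        return out, {
            "normalized_input": x,
            "exposure": matrix,
            "attention": amap,
            "l0": l0,
            "illumination": estimate,
            "gamma": cfg.gamma,
        }
    return out
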