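"""Gaussian heatmap encoding/decoding for landmark regression.

A landmark detector trained by heatmap regression predicts, for each of the
ten periocular landmarks, a likelihood raster at 1/``stride`` of the input
resolution. Ground truth maps carry a 2D Gaussian blob centred on the
landmark; training minimises the mean squared error between predicted and
ground-truth stacks, and inference takes the argmax of each predicted map
(with a quarter-pixel refinement toward the strongest neighbour) and scales
back to input coordinates.

Conventions: the Gaussian is centred at the continuous sub-cell position
x/stride (so the blob's neighbour asymmetry preserves the sub-cell offset
that the decoder's refinement step recovers), normalized so the peak value
is exactly 1 at the nearest cell, truncated to zero beyond 3 sigma; heatmap
cell (u, v) corresponds to input pixel (u * stride, v * stride).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DecodingError, EncodingError, ValidationError
from .landmarks import N_LANDMARKS, LandmarkSet

DEFAULT_STRIDE = 4
DEFAULT_SIGMA = 2.0
TRUNCATION_SIGMAS = 3.0


@dataclass
class HeatmapStack:
    """Per-landmark likelihood maps at 1/stride resolution.

    ``maps`` has shape (L, h/stride, w/stride) for an input of size (w, h).
    """

    maps: np.ndarray
    stride: int = DEFAULT_STRIDE
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 3:
            raise ValidationError(f"heatmap stack must be 3D; got ndim={m.ndim}")
        self.maps = m

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def map_size(self) -> tuple[int, int]:
        """(width, height) of each map."""
        return self.maps.shape[2], self.maps.shape[1]


def encode_heatmaps(
    landmarks: LandmarkSet,
    image_size: tuple[int, int],
    stride: int = DEFAULT_STRIDE,
    sigma: float = DEFAULT_SIGMA,
) -> HeatmapStack:
    """Encode landmark coordinates as truncated-Gaussian heatmaps.

    Parameters
    ----------
    landmarks
        The ten landmark coordinates in input-image pixels.
    image_size
        (width, height) of the input raster; both must be multiples of
        ``stride`` so the stack dimensions divide exactly.
    stride
        Downsampling factor between input and heatmap resolution.
    sigma
        Gaussian standard deviation in heatmap pixels. The blob is truncated
        to zero beyond ``3 * sigma`` and its peak is normalized to 1 at the
        quantized landmark cell.
    """
    w, h = image_size
    if w % stride or h % stride:
        raise ValidationError(
            f"image size {image_size} must be a multiple of stride {stride}"
        )
    mw, mh = w // stride, h // stride
    maps = np.zeros((N_LANDMARKS, mh, mw), dtype=float)
    radius = int(np.ceil(TRUNCATION_SIGMAS * sigma))
    for li, (x, y) in enumerate(landmarks.points):
        if not (0.0 <= x < w and 0.0 <= y < h):
            raise EncodingError(
                f"landmark {li} at ({x:.2f}, {y:.2f}) outside image {image_size}",
                landmark_index=li,
            )
        fu, fv = x / stride, y / stride  # continuous sub-cell centre
        cu = min(int(round(fu)), mw - 1)
        cv = min(int(round(fv)), mh - 1)
        u0, u1 = max(cu - radius - 1, 0), min(cu + radius + 1, mw - 1)
        v0, v1 = max(cv - radius - 1, 0), min(cv + radius + 1, mh - 1)
        uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        d2 = (uu - fu) ** 2 + (vv - fv) ** 2
        blob = np.exp(-d2 / (2.0 * sigma**2))
        blob[d2 > (TRUNCATION_SIGMAS * sigma) ** 2] = 0.0
        blob /= blob.max()  # peak exactly 1 at the quantized cell
        maps[li, v0 : v1 + 1, u0 : u1 + 1] = np.maximum(
            maps[li, v0 : v1 + 1, u0 : u1 + 1], blob
        )
    return HeatmapStack(maps, stride=stride, sigma=sigma)


def mse_heatmap_loss(predicted: HeatmapStack, truth: HeatmapStack) -> float:
    """Mean squared error between two heatmap stacks.

    The reduction is the mean over every element of every map, so the value
    is independent of batch assembly and map count.
    """
    if predicted.maps.shape != truth.maps.shape:
        raise ValidationError(
            f"shape mismatch: {predicted.maps.shape} vs {truth.maps.shape}"
        )
    diff = predicted.maps - truth.maps
    return float(np.mean(diff * diff))


def _refine_offset(m: np.ndarray, v: int, u: int) -> tuple[float, float]:
    """Quarter-pixel shift toward the larger of each 4-neighbour pair."""
    mh, mw = m.shape
    left = m[v, u - 1] if u - 1 >= 0 else -np.inf
    right = m[v, u + 1] if u + 1 < mw else -np.inf
    up = m[v - 1, u] if v - 1 >= 0 else -np.inf
    down = m[v + 1, u] if v + 1 < mh else -np.inf
    du = 0.25 * (float(right > left) - float(left > right))
    dv = 0.25 * (float(down > up) - float(up > down))
    return du, dv


def decode_heatmaps(predicted: HeatmapStack, stride: int | None = None) -> LandmarkSet:
    """Decode a predicted stack to sub-pixel input-image coordinates.

    Per map: take the argmax cell (row-major first occurrence on ties),
    shift a quarter heatmap pixel toward the strongest 4-neighbour, and
    multiply by the stride. NaNs are ignored unless a whole map is NaN,
    which raises :class:`DecodingError` with the landmark index.
    """
    if stride is None:
        stride = predicted.stride
    if predicted.n_maps != N_LANDMARKS:
        raise ValidationError(
            f"expected {N_LANDMARKS} maps, got {predicted.n_maps}"
        )
    pts = np.empty((N_LANDMARKS, 2), dtype=float)
    for li in range(N_LANDMARKS):
        m = predicted.maps[li]
        finite = np.isfinite(m)
        if not finite.any():
            raise DecodingError(f"map {li} has no finite values", landmark_index=li)
        safe = np.where(finite, m, -np.inf)
        v, u = np.unravel_index(int(np.argmax(safe)), m.shape)
        du, dv = _refine_offset(safe, v, u)
        pts[li] = ((u + du) * stride, (v + dv) * stride)
    return LandmarkSet(pts)
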