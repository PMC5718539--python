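"""Five-stage Canny edge detector producing single-pixel-wide binary edge maps.

The detector is written out stage by stage (Gaussian blur, Sobel gradient,
non-maximum suppression, double threshold, edge tracing by hysteresis) so
that each stage can be configured and tested on its own.  Portal images of
an open field containing a high-contrast phantom have only a handful of
strong, nearly straight edges, so the parameter space is forgiving; the two
knobs that matter are the gradient threshold and the blur width, held in
:class:`CannyConfig` with independent settings for AP and lateral views.

Direction quantization follows the conventional four categories of the
gradient orientation: horizontal (gradient along the column axis), +45,
vertical (gradient along the row axis) and -45.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

# gradient-orientation categories (orientation modulo 180 degrees)
DIR_HORIZONTAL = 0  # gradient along columns -> vertical edge line
DIR_PLUS_45 = 1
DIR_VERTICAL = 2  # gradient along rows -> horizontal edge line
DIR_MINUS_45 = 3
DIRECTION_NAMES = {
    DIR_HORIZONTAL: "horizontal",
    DIR_PLUS_45: "+45",
    DIR_VERTICAL: "vertical",
    DIR_MINUS_45: "-45",
}

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class EdgeDetectionError(ValueError):
    pass


@dataclass(frozen=True)
class CannyConfig:
    """Per-view Canny parameters.

    threshold_high : gradient-magnitude cutoff for strong edges, in units of
        the (plateau-normalised) pixel intensity per Sobel response.
    threshold_low : cutoff for weak edges; defaults to 0.4 * threshold_high.
    gaussian_sigma : blur width in pixels.
    view : which imaging view ("AP" or "lateral") these settings belong to.
    window, level : display-only values kept for config-file fidelity; they
        never influence detection.
    """

    threshold_high: float = 0.12
    threshold_low: float | None = None
    gaussian_sigma: float = 2.0
    view: str = "AP"
    window: float = 1.0
    level: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_low is None:
            object.__setattr__(self, "threshold_low", 0.4 * self.threshold_high)
        if not (0 < self.threshold_low <= self.threshold_high):
            raise EdgeDetectionError(
                "require 0 < threshold_low <= threshold_high, got "
                f"low={self.threshold_low} high={self.threshold_high}"
            )
        if self.gaussian_sigma <= 0:
            raise EdgeDetectionError("gaussian_sigma must be > 0")
        if self.view not in ("AP", "lateral"):
            raise EdgeDetectionError(f"view must be 'AP' or 'lateral', got {self.view!r}")

    def with_(self, **kw) -> "CannyConfig":
        return replace(self, **kw)


@dataclass
class EdgeMap:
    """Binary edge image plus the quantized gradient direction per edge pixel.

    ``gradient_direction`` holds one of the DIR_* codes where ``edges`` is
    True and -1 elsewhere.  ``blurred`` keeps the stage-1 Gaussian-blurred
    image so downstream subpixel refinement interpolates the same intensity
    profile the detector saw.
    """

    edges: np.ndarray
    gradient_direction: np.ndarray
    blurred: np.ndarray | None = None
    config: CannyConfig | None = None

    def __post_init__(self) -> None:
        if self.edges.shape != self.gradient_direction.shape:
            raise EdgeDetectionError("edges/direction shape mismatch")


def _gaussian_kernel_1d(sigma: float) -> np.ndarray:
    # truncated at 4 sigma and renormalised
    radius = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur, 4-sigma truncation, reflective boundaries."""
    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise EdgeDetectionError("non-finite pixel values")
    if sigma <= 0:
        raise EdgeDetectionError("sigma must be > 0")
    k = _gaussian_kernel_1d(sigma)
    out = ndimage.correlate1d(pixels, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return out


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def sobel_gradient(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient magnitude and quantized orientation.

    Returns ``(magnitude, direction)`` where direction holds the DIR_* code
    of the gradient orientation modulo 180 degrees for every pixel.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise EdgeDetectionError("image must be 2-D and at least 3x3")
    gx = ndimage.correlate(pixels, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(pixels, _SOBEL_Y, mode="reflect")
    magnitude = np.hypot(gx, gy)
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    direction = (np.round(angle / 45.0).astype(np.int8)) % 4
    return magnitude, direction


# per direction: the (drow, dcol) offset toward the lexicographically later
# neighbour along the gradient orientation
_NMS_OFFSETS = {
    DIR_HORIZONTAL: (0, 1),
    DIR_PLUS_45: (1, 1),
    DIR_VERTICAL: (1, 0),
    DIR_MINUS_45: (1, -1),
}


def non_max_suppression(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Zero every pixel that is not the gradient-direction local maximum.

    Plateau ties keep exactly one pixel: the comparison is strict against
    the earlier neighbour in scan order and non-strict against the later
    one, so the smaller index along the scan direction survives.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    direction = np.asarray(direction)
    if magnitude.shape != direction.shape:
        raise EdgeDetectionError("magnitude/direction shape mismatch")
    padded = np.pad(magnitude, 1, mode="constant")
    keep = np.zeros(magnitude.shape, dtype=bool)
    for d, (dr, dc) in _NMS_OFFSETS.items():
        nxt = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        prv = padded[1 - dr : padded.shape[0] - 1 - dr, 1 - dc : padded.shape[1] - 1 - dc]
        sel = (direction == d) & (magnitude > prv) & (magnitude >= nxt) & (magnitude > 0)
        keep |= sel
    return np.where(keep, magnitude, 0.0)


def hysteresis(
    magnitude: np.ndarray,
    config: CannyConfig,
    direction: np.ndarray | None = None,
    blurred: np.ndarray | None = None,
) -> EdgeMap:
    """Double threshold plus edge tracing.

    Weak pixels (between the two thresholds) survive only when 8-connected
    to at least one strong pixel.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    strong = magnitude >= config.threshold_high
    weak = magnitude >= config.threshold_low
    labels, n = ndimage.label(weak, structure=_EIGHT_CONNECTED)
    if n:
        keep_label = np.zeros(n + 1, dtype=bool)
        keep_label[np.unique(labels[strong])] = True
        keep_label[0] = False
        edges = keep_label[labels]
    else:
        edges = np.zeros(magnitude.shape, dtype=bool)
    if direction is None:
        direction = np.zeros(magnitude.shape, dtype=np.int8)
    dir_out = np.where(edges, direction.astype(np.int8), np.int8(-1))
    return EdgeMap(edges=edges, gradient_direction=dir_out, blurred=blurred, config=config)


def canny(pixels: np.ndarray, config: CannyConfig) -> EdgeMap:
    """Run the full five-stage detector on one image."""
    blurred = gaussian_blur(pixels, config.gaussian_sigma)
    magnitude, direction = sobel_gradient(blurred)
    suppressed = non_max_suppression(magnitude, direction)
    return hysteresis(suppressed, config, direction=direction, blurred=blurred)
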