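"""Color-based two-class segmentation of phantom cross-sections.

Each pixel is classified as ablated (magenta) or intact (off-white) by
its weighted Euclidean distance in HSV space to the median foreground
and background colors of the image.  The decision boundary is therefore
the color midway between the two medians — by construction it falls in
the middle of the 1–2 mm color gradient at the ablation contour.  Hue is
treated circularly; the value channel is down-weighted by default for
robustness to uneven lighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import label

from .imaging import CrossSectionImage, MAGENTA_HSV, OFFWHITE_HSV
from .profiles import ValidationError

__all__ = [
    "ColorModel",
    "DegenerateImageError",
    "estimate_color_model",
    "classify",
    "segment",
    "dice",
    "DEFAULT_WEIGHTS",
]

DEFAULT_WEIGHTS = (1.0, 1.0, 0.5)


class DegenerateImageError(ValueError):
    """Raised when an image does not contain both color classes."""


@dataclass(frozen=True)
class ColorModel:
    """Foreground/background median colors and channel weights.

    Colors are HSV triples with hue in degrees [0, 360) and saturation /
    value in [0, 1]; ``weights`` = (w_h, w_s, w_v) apply to the squared
    channel differences, with hue differences taken on the circle and
    expressed in turns (degrees / 360) so all channels share a [0, 1]
    scale.
    """

    fg_median: tuple[float, float, float] = MAGENTA_HSV
    bg_median: tuple[float, float, float] = OFFWHITE_HSV
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if tuple(self.fg_median) == tuple(self.bg_median):
            raise ValidationError("fg and bg medians must differ")
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise ValidationError("weights must be non-negative with at least one > 0")


def _to_hsv(pixels: np.ndarray) -> np.ndarray:
    """RGB [0,1] → HSV with hue in degrees."""
    hsv = rgb2hsv(pixels)
    hsv = hsv.copy()
    hsv[..., 0] *= 360.0
    return hsv


def _weighted_dist2(
    hsv: np.ndarray, color: tuple[float, float, float], weights: tuple[float, float, float]
) -> np.ndarray:
    """Squared weighted distance of each pixel to an HSV color."""
    dh = np.abs(hsv[..., 0] - color[0])
    dh = np.minimum(dh, 360.0 - dh) / 360.0  # circular hue difference, in turns
    ds = hsv[..., 1] - color[1]
    dv = hsv[..., 2] - color[2]
    w_h, w_s, w_v = weights
    return w_h * dh**2 + w_s * ds**2 + w_v * dv**2


def estimate_color_model(
    image: CrossSectionImage, priors: ColorModel | None = None
) -> ColorModel:
    """Estimate the image-specific color model from prior colors.

    Pixels are provisionally labeled by their nearest prior color; the
    channel-wise medians of each class (hue median computed on the
    circle, by rotating the prior hue to mid-range) become the model.
    A class capturing fewer than 1 % of pixels is degenerate.
    """
    priors = priors or ColorModel()
    hsv = _to_hsv(image.pixels)
    d_fg = _weighted_dist2(hsv, priors.fg_median, priors.weights)
    d_bg = _weighted_dist2(hsv, priors.bg_median, priors.weights)
    fg_lab = d_fg < d_bg
    n = fg_lab.size
    if fg_lab.sum() < 0.01 * n or (~fg_lab).sum() < 0.01 * n:
        raise DegenerateImageError(
            "one color class captures < 1% of pixels; image lacks both classes"
        )

    def _class_median(mask: np.ndarray, prior_h: float) -> tuple[float, float, float]:
        h = hsv[..., 0][mask]
        # rotate so the prior hue sits at 180° → plain median is circular-safe
        h_rot = (h - prior_h + 180.0) % 360.0
        h_med = (float(np.median(h_rot)) + prior_h - 180.0) % 360.0
        return (
            h_med,
            float(np.median(hsv[..., 1][mask])),
            float(np.median(hsv[..., 2][mask])),
        )

    return ColorModel(
        fg_median=_class_median(fg_lab, priors.fg_median[0]),
        bg_median=_class_median(~fg_lab, priors.bg_median[0]),
        weights=priors.weights,
    )


def classify(image: CrossSectionImage, model: ColorModel) -> np.ndarray:
    """Per-pixel nearest-median classification → boolean foreground mask.

    A pixel is foreground iff its weighted distance to the foreground
    median is strictly smaller than to the background median; exact ties
    go to background (conservative under-segmentation).  Equivalent to
    thresholding at the color equidistant from the two medians.
    """
    hsv = _to_hsv(image.pixels)
    d_fg = _weighted_dist2(hsv, model.fg_median, model.weights)
    d_bg = _weighted_dist2(hsv, model.bg_median, model.weights)
    return d_fg < d_bg


def segment(
    image: CrossSectionImage,
    priors: ColorModel | None = None,
    weights: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Full segmentation: median color model → classify → clean up.

    Post-processing keeps the largest 4-connected foreground component
    and fills interior holes, removing speckle from rendering noise.
    """
    priors = priors or ColorModel()
    if weights is not None:
        priors = ColorModel(priors.fg_median, priors.bg_median, tuple(weights))
    model = estimate_color_model(image, priors)
    mask = classify(image, model)
    if mask.any():
        lab = label(mask, connectivity=1)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        mask = lab == int(np.argmax(counts))
        mask = ndimage.binary_fill_holes(mask)
    return mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
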