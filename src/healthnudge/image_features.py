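"""Low-level visual features of food photographs and parametric image edits.

Five descriptors summarise an 8-bit RGB image: brightness (mean luma),
colorfulness (Hasler–Süsstrunk opponent-channel statistic), entropy
(Shannon entropy of the grayscale histogram, in bits), sharpness (mean
absolute 4-neighbour Laplacian response) and saturation (mean HSV S
channel).  Brightness, colorfulness, sharpness and saturation live in
[0, 1]; entropy lives in [0, 8].

The same module provides the parametric transform used to nudge an
image's predicted attractiveness up or down: a gain triple acting on the
HSV value channel, the HSV saturation channel and the opponent chroma
amplitude, plus a deterministic grid search that finds the gain triple
achieving a requested attractiveness change.

Grayscale conversion uses ITU-R BT.601 luma weights (0.299, 0.587,
0.114) throughout for internal consistency.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import color as _skcolor

from .exceptions import InvalidInputError, InvalidParameterError, UnreachableTargetError

__all__ = [
    "ImageFeatures",
    "LUMA_WEIGHTS",
    "MIN_SIDE",
    "validate_image",
    "load_image",
    "resize_max_side",
    "compute_brightness",
    "compute_saturation",
    "compute_colorfulness",
    "compute_entropy",
    "compute_sharpness",
    "extract_features",
    "apply_feature_shift",
    "tune_attractiveness_delta",
]

logger = logging.getLogger(__name__)

#: BT.601 luma weights used for every grayscale reduction in the package.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum accepted image side, in pixels.
MIN_SIDE = 8

#: Default maximum side for the resolution-stabilising resize.
MAX_SIDE = 512


@dataclass(frozen=True)
class ImageFeatures:
    """The five low-level descriptors of one image.

    All fields are unitless in [0, 1] except ``entropy`` (bits, [0, 8]).
    """

    brightness: float
    colorfulness: float
    entropy: float
    sharpness: float
    saturation: float

    def as_array(self) -> np.ndarray:
        """Feature vector in canonical order (brightness, colorfulness, entropy, sharpness, saturation)."""
        return np.array(
            [self.brightness, self.colorfulness, self.entropy, self.sharpness, self.saturation]
        )

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid H×W×3 8-bit RGB image and return it as uint8.

    Raises
    ------
    InvalidInputError
        If the array is not 3-dimensional with exactly three channels,
        smaller than ``MIN_SIDE`` on either side, or holds values
        outside [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"expected an H x W x 3 RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise InvalidInputError(
            f"image must be at least {MIN_SIDE}x{MIN_SIDE} pixels, got {arr.shape[0]}x{arr.shape[1]}"
        )
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("channel values must lie in [0, 255]")
    return arr.astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG file as an 8-bit RGB array; alpha channels are dropped with a warning."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            logger.warning("dropping alpha channel of %s (mode %s)", path, im.mode)
        rgb = im.convert("RGB")
        return validate_image(np.asarray(rgb))


def resize_max_side(img: np.ndarray, max_side: int = MAX_SIDE) -> np.ndarray:
    """Downscale so the longer side is at most ``max_side`` (area interpolation).

    Images already small enough are returned unchanged, so features are
    stable for typical web-sized photographs regardless of the exact
    source resolution.
    """
    arr = validate_image(img)
    h, w = arr.shape[:2]
    longest = max(h, w)
    if longest <= max_side:
        return arr
    scale = max_side / longest
    new_w = max(MIN_SIDE, round(w * scale))
    new_h = max(MIN_SIDE, round(h * scale))
    im = Image.fromarray(arr, mode="RGB").resize((new_w, new_h), Image.Resampling.BOX)
    return np.asarray(im)


def _luma(arr: np.ndarray) -> np.ndarray:
    return arr.astype(float) @ LUMA_WEIGHTS


def compute_brightness(img: np.ndarray) -> float:
    """Mean BT.601 luma over all pixels, scaled to [0, 1]."""
    arr = validate_image(img)
    return float(_luma(arr).mean() / 255.0)


def compute_saturation(img: np.ndarray) -> float:
    """Mean HSV saturation channel over all pixels, in [0, 1].

    Saturation expresses colorfulness in proportion to brightness:
    gray pixels (including black) contribute 0, pure hues contribute 1.
    """
    arr = validate_image(img)
    hsv = _skcolor.rgb2hsv(arr)
    return float(hsv[..., 1].mean())


def compute_colorfulness(img: np.ndarray) -> float:
    """Hasler–Süsstrunk colorfulness on opponent channels, normalised to [0, 1].

    With rg = R − G and yb = (R + G)/2 − B,

        M = sqrt(sigma_rg^2 + sigma_yb^2) + 0.3 * sqrt(mu_rg^2 + mu_yb^2)

    and the result is M / 255 clamped to [0, 1].
    """
    arr = validate_image(img).astype(float)
    rg = arr[..., 0] - arr[..., 1]
    yb = 0.5 * (arr[..., 0] + arr[..., 1]) - arr[..., 2]
    sigma = np.hypot(rg.std(), yb.std())
    mu = np.hypot(rg.mean(), yb.mean())
    return float(np.clip((sigma + 0.3 * mu) / 255.0, 0.0, 1.0))


def compute_entropy(img: np.ndarray) -> float:
    """Shannon entropy (base 2) of the 256-bin grayscale histogram, in bits.

    Gray levels are the luma rounded half-up, computed in exact integer
    arithmetic (per-mille weights 299/587/114) so binning at .5
    boundaries does not depend on floating-point summation order.
    Empty bins contribute 0 (the 0·log 0 convention).
    """
    arr = validate_image(img)
    a = arr.astype(np.int64)
    milli = 299 * a[..., 0] + 587 * a[..., 1] + 114 * a[..., 2]
    gray = np.clip((milli + 500) // 1000, 0, 255).astype(np.intp)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts[counts > 0] / gray.size
    return float(-(p * np.log2(p)).sum())


def compute_sharpness(img: np.ndarray) -> float:
    """Mean absolute 4-neighbour Laplacian of luma over interior pixels, in [0, 1].

    The response is normalised by its maximum attainable magnitude,
    4·255 (a pixel at one extreme surrounded by the other).
    """
    arr = validate_image(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise InvalidInputError("sharpness requires an image of at least 3x3 pixels")
    y = _luma(arr)
    lap = (
        y[:-2, 1:-1] + y[2:, 1:-1] + y[1:-1, :-2] + y[1:-1, 2:] - 4.0 * y[1:-1, 1:-1]
    )
    return float(np.clip(np.abs(lap).mean() / (4.0 * 255.0), 0.0, 1.0))


def extract_features(img: np.ndarray, resize: bool = True) -> ImageFeatures:
    """Bundle the five descriptors of one image.

    Parameters
    ----------
    img
        H×W×3 8-bit RGB array.
    resize
        If True (default), downscale to a maximum side of ``MAX_SIDE``
        pixels with area interpolation first, so features do not depend
        on the source resolution.
    """
    arr = validate_image(img)
    if resize:
        arr = resize_max_side(arr)
    return ImageFeatures(
        brightness=compute_brightness(arr),
        colorfulness=compute_colorfulness(arr),
        entropy=compute_entropy(arr),
        sharpness=compute_sharpness(arr),
        saturation=compute_saturation(arr),
    )


def apply_feature_shift(
    img: np.ndarray,
    brightness_gain: float = 1.0,
    saturation_gain: float = 1.0,
    color_gain: float = 1.0,
) -> np.ndarray:
    """Deterministic pixel transform scaling value, saturation and chroma.

    The HSV value channel is scaled by ``brightness_gain`` and the HSV
    saturation channel by ``saturation_gain`` (both clipped to [0, 1]);
    the opponent chroma amplitude (RGB minus luma) is then scaled by
    ``color_gain``.  All output channels are clamped to [0, 255].
    A gain triple of (1, 1, 1) is the identity.
    """
    for name, g in (
        ("brightness_gain", brightness_gain),
        ("saturation_gain", saturation_gain),
        ("color_gain", color_gain),
    ):
        if not np.isfinite(g) or g <= 0:
            raise InvalidParameterError(f"{name} must be a positive finite number, got {g!r}")
    arr = validate_image(img)

    hsv = _skcolor.rgb2hsv(arr)
    hsv[..., 1] = np.clip(hsv[..., 1] * saturation_gain, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * brightness_gain, 0.0, 1.0)
    rgb = _skcolor.hsv2rgb(hsv) * 255.0

    if color_gain != 1.0:
        y = rgb @ LUMA_WEIGHTS
        rgb = y[..., None] + color_gain * (rgb - y[..., None])

    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


# Gain-triple search grid: 15 points per axis on [0.4, 1.8].  The bounds keep
# transformed photographs plausibly food-like; wider gains produce obviously
# artificial images.
GAIN_GRID = np.linspace(0.4, 1.8, 15)


def _sorted_gain_triples() -> list[tuple[float, float, float]]:
    """All grid triples ordered by L2 distance from the identity (1,1,1), lexicographic on ties."""
    triples = [
        (float(b), float(s), float(c))
        for b in GAIN_GRID
        for s in GAIN_GRID
        for c in GAIN_GRID
    ]
    triples.sort(key=lambda t: (sum((g - 1.0) ** 2 for g in t), t))
    return triples


def tune_attractiveness_delta(
    img: np.ndarray,
    model,
    target_delta: float,
    direction: str = "down",
    resize: bool = True,
) -> tuple[np.ndarray, float]:
    """Search gain triples for a transform shifting predicted attractiveness by ``target_delta``.

    The candidate gain triples (brightness, saturation, chroma gains on
    a 15-point grid over [0.4, 1.8] per axis) are visited in order of
    increasing L2 distance from the identity, so the least invasive
    transform meeting the target is returned.  Predicted attractiveness
    is evaluated with ``model`` on features re-extracted from each
    candidate image.

    Parameters
    ----------
    img
        Source RGB image.
    model
        An :class:`~healthnudge.attractiveness.AttractivenessModel`.
    target_delta
        Required attractiveness change, in model score units; must be >= 0.
    direction
        ``"down"`` to reduce predicted attractiveness, ``"up"`` to raise it.

    Returns
    -------
    (transformed image, achieved delta)
        ``achieved_delta`` is the magnitude of the attained change, >= ``target_delta``.

    Raises
    ------
    UnreachableTargetError
        If no grid triple achieves the target; the error carries the
        best delta found and its gain triple.
    """
    if direction not in ("up", "down"):
        raise InvalidParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    if not np.isfinite(target_delta) or target_delta < 0:
        raise InvalidParameterError(f"target_delta must be >= 0, got {target_delta!r}")
    arr = validate_image(img)
    base_pred = model.predict(extract_features(arr, resize=resize))
    if target_delta == 0:
        return arr, 0.0

    sign = 1.0 if direction == "up" else -1.0
    best_delta = 0.0
    best_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    for gains in _sorted_gain_triples():
        cand = apply_feature_shift(arr, *gains)
        delta = sign * (model.predict(extract_features(cand, resize=resize)) - base_pred)
        if delta >= target_delta:
            return cand, float(delta)
        if delta > best_delta:
            best_delta, best_gains = float(delta), gains
    raise UnreachableTargetError(
        f"no gain triple reaches a {direction}ward delta of {target_delta} "
        f"(best achieved: {best_delta:.4f} at gains {best_gains})",
        best_delta=best_delta,
        best_gains=best_gains,
    )
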