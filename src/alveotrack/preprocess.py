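"""Per-channel noise suppression and binary mask formation.

Two denoising stages precede segmentation.  Non-local means (NLM) removes
sensor noise across the whole frame; a classic Gaussian-blur + intensity
threshold + dilation chain then produces the binary feature mask.  Alveoli
are segmented as DARK regions of the interstitial channel (the dextran labels
the interstitium, airspaces are unlabeled), neutrophils as BRIGHT regions of
their own channel.

Default NLM filter strengths are 35 (interstitial/alveoli) and 45
(neutrophils) with a 7-px template window and 21-px search window; feature
masking uses an 11-px blur kernel and a 4-px dilation kernel.  The intensity
cutoffs (50 dark / 60 bright) are exposed hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means

from .imaging_io import ChannelRole


class Polarity(str, Enum):
    """Whether the feature of interest is darker or brighter than background."""

    DARK_FEATURES = "dark_features"
    BRIGHT_FEATURES = "bright_features"


@dataclass(frozen=True)
class PreprocessParams:
    """Denoising and masking parameters for one channel.

    Attributes
    ----------
    nlm_strength
        NLM filter strength ``h`` on the 0-255 intensity scale; 0 disables
        denoising (identity).
    nlm_template
        Odd patch (template window) size in px.
    nlm_search
        Odd search window size in px; must be >= ``nlm_template``.
    blur_kernel
        Odd Gaussian blur kernel size in px; sigma follows the conventional
        ``0.3*((k-1)/2 - 1) + 0.8`` rule.
    intensity_threshold
        0-255 cutoff applied after blurring.
    dilate_kernel
        Side of the square dilation structuring element, px.
    polarity
        Select pixels BELOW the threshold (``dark_features``) or ABOVE it
        (``bright_features``).
    """

    nlm_strength: float
    nlm_template: int
    nlm_search: int
    blur_kernel: int
    intensity_threshold: float
    dilate_kernel: int
    polarity: Polarity

    def __post_init__(self) -> None:
        for name in ("nlm_template", "nlm_search", "blur_kernel"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.nlm_template > self.nlm_search:
            raise ValueError("nlm_template must not exceed nlm_search")
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must be in [0, 255]")
        if self.dilate_kernel < 1:
            raise ValueError("dilate_kernel must be >= 1")
        if self.nlm_strength < 0:
            raise ValueError("nlm_strength must be >= 0")
        object.__setattr__(self, "polarity", Polarity(self.polarity))


def default_params(role: ChannelRole | str) -> PreprocessParams:
    """Published default parameters for a channel role.

    Interstitial/alveoli: NLM h=35, template 7, search 21, dark features,
    threshold 50.  Neutrophils: NLM h=45, template 7, search 21, bright
    features, threshold 60.  Both: blur kernel 11, dilate kernel 4.
    """
    role = ChannelRole(role)
    if role is ChannelRole.INTERSTITIAL:
        return PreprocessParams(
            nlm_strength=35, nlm_template=7, nlm_search=21,
            blur_kernel=11, intensity_threshold=50, dilate_kernel=4,
            polarity=Polarity.DARK_FEATURES,
        )
    return PreprocessParams(
        nlm_strength=45, nlm_template=7, nlm_search=21,
        blur_kernel=11, intensity_threshold=60, dilate_kernel=4,
        polarity=Polarity.BRIGHT_FEATURES,
    )


def gaussian_sigma(kernel_size: int) -> float:
    """Blur sigma derived from an odd kernel size."""
    return 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8


def denoise_nlm(frame: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Non-local means denoising of an 8-bit frame.

    Deterministic; ``nlm_strength == 0`` returns the input unchanged.  The
    search window of size ``nlm_search`` maps to a patch-center search radius
    of ``(nlm_search - 1) // 2`` px.
    """
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError("frame must be 8-bit (uint8)")
    if params.nlm_strength == 0:
        return frame.copy()
    out = denoise_nl_means(
        frame.astype(np.float64),
        patch_size=params.nlm_template,
        patch_distance=(params.nlm_search - 1) // 2,
        h=float(params.nlm_strength),
        fast_mode=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def feature_mask(frame: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Binary feature mask: Gaussian blur -> intensity threshold -> dilation.

    The threshold selects pixels strictly below ``intensity_threshold`` for
    dark features and strictly above it for bright features; dilation uses a
    square structuring element of side ``dilate_kernel``.

    Returns a ``{0, 1}`` uint8 mask with the frame's dimensions.
    """
    frame = np.asarray(frame, dtype=np.float64)
    sigma = gaussian_sigma(params.blur_kernel)
    radius = (params.blur_kernel - 1) // 2
    blurred = ndimage.gaussian_filter(frame, sigma=sigma, radius=radius,
                                      mode="nearest")
    if params.polarity is Polarity.DARK_FEATURES:
        mask = blurred < params.intensity_threshold
    else:
        mask = blurred > params.intensity_threshold
    k = params.dilate_kernel
    if k > 1:
        mask = ndimage.binary_dilation(mask, structure=np.ones((k, k), bool))
    return mask.astype(np.uint8)


def preprocess_series(frames: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Denoise and mask every frame of a stack; returns a mask stack."""
    return np.stack([feature_mask(denoise_nlm(f, params), params) for f in frames])
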