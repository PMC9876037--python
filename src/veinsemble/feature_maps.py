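"""The six per-image feature maps.

From one grayscale vein image: (1) the original, (2) a binary vein
segmentation, (3) LBP codes of the original, (4) LBP codes of the
segmentation, (5) a fused Gabor-bank response of the original, and (6) of
the segmentation.  All maps share the input's shape so they stay
co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as spfft
from scipy import ndimage

__all__ = [
    "LbpParams",
    "GaborParams",
    "GaborBank",
    "FeatureMapSet",
    "compute_lbp",
    "gabor_kernel",
    "gabor_feature",
    "segment_veins",
    "build_feature_maps",
]


# --------------------------------------------------------------------------
# Local binary patterns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LbpParams:
    """Code parameters: 8 neighbors on a ring of radius ``radius``.

    Neighbors are the pixels of the surrounding grid ring (no subpixel
    interpolation); neighbor 0 sits at ``start_angle_deg`` from the
    positive column axis and the ring is walked counter-clockwise (in
    image coordinates, i.e. towards negative rows) unless
    ``counter_clockwise`` is False.
    """

    radius: int = 1
    neighbors: int = 8
    start_angle_deg: float = 0.0
    counter_clockwise: bool = True

    def __post_init__(self) -> None:
        if self.neighbors != 8:
            raise ValueError("only 8-neighbor codes are supported")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def offsets(self) -> list[tuple[int, int]]:
        """(dy, dx) of neighbors p = 0..7 on the grid ring."""
        sign = 1.0 if self.counter_clockwise else -1.0
        out = []
        for p in range(self.neighbors):
            ang = np.deg2rad(self.start_angle_deg) + sign * 2 * np.pi * p / 8
            dx = int(np.rint(self.radius * np.cos(ang)))
            dy = int(np.rint(-self.radius * np.sin(ang)))
            out.append((dy, dx))
        return out


def compute_lbp(image: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """Per-pixel binary code comparing each ring neighbor to the center.

    The code is ``sum_p s(g_p - g_c) 2^p`` with ``s(x) = 1`` iff
    ``x >= 0``.  The image is replicate-padded so the output has the
    input's shape.  Returns a uint8 map of codes in [0, 255].
    """
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {image.shape}")
    r = params.radius
    padded = np.pad(image.astype(np.int64), r, mode="edge")
    h, w = image.shape
    center = image.astype(np.int64)
    codes = np.zeros((h, w), dtype=np.uint8)
    for p, (dy, dx) in enumerate(params.offsets()):
        neighbor = padded[r + dy : r + dy + h, r + dx : r + dx + w]
        codes |= ((neighbor - center >= 0).astype(np.uint8)) << p
    return codes


# --------------------------------------------------------------------------
# Gabor filters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborParams:
    """One real Gabor kernel: cosine carrier of wavelength ``wavelength``
    along orientation ``theta``, Gaussian envelope of spread ``sigma`` and
    aspect ratio ``gamma``, sampled on an odd square grid."""

    wavelength: float
    theta: float = 0.0
    psi: float = 0.0
    sigma: float = 2.0
    gamma: float = 0.5
    kernel_size: int = 7

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.wavelength <= 0 or self.sigma <= 0:
            raise ValueError("wavelength and sigma must be positive")


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Real part of the Gabor function on the integer grid centered at 0.

    ``G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
    * cos(2 pi x' / wavelength + psi)`` with ``x' = x cos t + y sin t``,
    ``y' = -x sin t + y cos t``.  Rows index y (downward), columns x.
    """
    half = params.kernel_size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xp = x * np.cos(params.theta) + y * np.sin(params.theta)
    yp = -x * np.sin(params.theta) + y * np.cos(params.theta)
    envelope = np.exp(
        -(xp**2 + (params.gamma**2) * yp**2) / (2.0 * params.sigma**2)
    )
    carrier = np.cos(2.0 * np.pi * xp / params.wavelength + params.psi)
    return envelope * carrier


#: default odd kernel side lengths of the bank
DEFAULT_SCALES = (7, 9, 11, 13, 15, 17)
#: default orientations (radians)
DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
#: base wavelength at the smallest scale
BASE_WAVELENGTH = np.pi / 2


@dataclass(frozen=True)
class GaborBank:
    """A scale x orientation family of real Gabor kernels.

    The wavelength grows linearly with the kernel side (``base_wavelength``
    at the smallest scale) and the envelope spread follows the common
    ``sigma = 0.56 * wavelength`` bandwidth rule.
    """

    scales: tuple[int, ...] = DEFAULT_SCALES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    base_wavelength: float = BASE_WAVELENGTH
    gamma: float = 0.5
    psi: float = 0.0
    sigma_factor: float = 0.56

    def members(self) -> list[GaborParams]:
        if not self.scales or not self.orientations:
            raise ValueError("bank must have at least one scale and orientation")
        base = min(self.scales)
        out = []
        for size in self.scales:
            wavelength = self.base_wavelength * size / base
            sigma = self.sigma_factor * wavelength
            for theta in self.orientations:
                out.append(
                    GaborParams(
                        wavelength=wavelength,
                        theta=theta,
                        psi=self.psi,
                        sigma=sigma,
                        gamma=self.gamma,
                        kernel_size=size,
                    )
                )
        return out


@lru_cache(maxsize=8)
def _bank_kernel_ffts(
    bank: GaborBank, shape: tuple[int, int]
) -> tuple[np.ndarray, tuple[int, int], list[int]]:
    """Precompute rfft2 of every zero-mean bank kernel at padded shape."""
    members = bank.members()
    pad = max(bank.scales) // 2
    ph, pw = shape[0] + 2 * pad, shape[1] + 2 * pad
    ffts = []
    halves = []
    for m in members:
        k = gabor_kernel(m)
        k = k - k.mean()  # remove DC so flat regions respond zero
        kp = np.zeros((ph, pw))
        kp[: k.shape[0], : k.shape[1]] = k
        ffts.append(spfft.rfft2(kp))
        halves.append(m.kernel_size // 2)
    return np.stack(ffts), (ph, pw), halves


def _bank_responses(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """FFT convolution of the image with every bank member.

    Returns an array of shape (n_members, H, W) of 'same'-sized responses
    with reflective boundary handling.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ffts, (ph, pw), halves = _bank_kernel_ffts(bank, (h, w))
    pad = max(bank.scales) // 2
    padded = np.pad(image, pad, mode="reflect")
    img_fft = spfft.rfft2(padded)
    out = np.empty((len(halves), h, w))
    for i, half in enumerate(halves):
        full = spfft.irfft2(img_fft * ffts[i], s=(ph, pw))
        # 'same' region of the convolution of the reflect-padded image
        r0 = pad + half
        c0 = pad + half
        out[i] = full[r0 : r0 + h, c0 : c0 + w]
    return out


def gabor_feature(image: np.ndarray, bank: GaborBank = GaborBank()) -> np.ndarray:
    """Fused texture-energy map of the bank: per-pixel maximum response
    magnitude over all scale/orientation members, min-max normalized to
    8-bit.  A constant image maps to all zeros."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    responses = _bank_responses(image, bank)
    energy = np.abs(responses).max(axis=0)
    lo, hi = energy.min(), energy.max()
    if hi - lo < 1e-12:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.rint(255.0 * (energy - lo) / (hi - lo)).astype(np.uint8)


# --------------------------------------------------------------------------
# Vein segmentation (classical stand-in)
# --------------------------------------------------------------------------

def segment_veins(
    image: np.ndarray,
    bank: GaborBank = GaborBank(),
    window: int = 21,
    offset_factor: float = 0.0,
    min_size: int = 20,
) -> np.ndarray:
    """Deterministic classical vein segmentation.

    Vessels are dark lines, so the image is inverted, enhanced with the
    Gabor bank (signed maximum response), thresholded against a local
    mean (window x window boxcar) plus ``offset_factor`` times the global
    response spread, cleaned by a cross-shaped 3x3 opening (a full-square
    opening severs the thinnest vessels) and small-component removal.
    Returns a uint8 {0, 1} map with vein = 1.
    """
    image = np.asarray(image, dtype=float)
    inverted = image.max() - image
    responses = _bank_responses(inverted, bank)
    # dark lines produce strongly positive responses of the matched
    # orientation on the inverted image; keep the signed maximum
    energy = responses.max(axis=0)
    spread = energy.max() - energy.min()
    if spread < 1e-9:
        return np.zeros(image.shape, dtype=np.uint8)
    local_mean = ndimage.uniform_filter(energy, size=window, mode="reflect")
    fg = energy > local_mean + offset_factor * energy.std()
    fg = ndimage.binary_opening(
        fg, structure=ndimage.generate_binary_structure(2, 1)
    )
    labels, n_comp = ndimage.label(fg)
    if n_comp:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = sizes[labels] >= min_size
    return fg.astype(np.uint8)


# --------------------------------------------------------------------------
# The six-map set
# --------------------------------------------------------------------------

@dataclass
class FeatureMapSet:
    """Ordered six maps of one image; ``maps[k]`` is the (k+1)-th map."""

    maps: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.maps) != 6:
            raise ValueError(f"expected 6 maps, got {len(self.maps)}")
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValueError(f"maps must share one shape, got {shapes}")

    def __getitem__(self, index: int) -> np.ndarray:
        return self.maps[index]

    def __iter__(self):
        return iter(self.maps)

    def as_float_stack(self) -> np.ndarray:
        """Stack the maps as float32 in [0, 1] for classifier input.

        Intensity-valued maps (1, 3, 4, 5, 6) are divided by 255; the
        binary map 2 is kept in {0, 1}.
        """
        out = np.empty((6,) + self.maps[0].shape, dtype=np.float32)
        for k, m in enumerate(self.maps):
            if k == 1:
                out[k] = m.astype(np.float32)
            else:
                out[k] = m.astype(np.float32) / 255.0
        return out


def build_feature_maps(
    image: np.ndarray,
    lbp: LbpParams = LbpParams(),
    bank: GaborBank = GaborBank(),
) -> FeatureMapSet:
    """Compose the six maps of one image.

    1. original; 2. segmentation; 3. LBP(original); 4. LBP(segmentation);
    5. Gabor(original); 6. Gabor(segmentation).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    segmented = segment_veins(image, bank=bank)
    seg255 = segmented * np.uint8(255)
    return FeatureMapSet(
        maps=[
            image.astype(np.uint8),
            segmented,
            compute_lbp(image, lbp),
            compute_lbp(seg255, lbp),
            gabor_feature(image, bank),
            gabor_feature(seg255, bank),
        ]
    )
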