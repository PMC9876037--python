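"""Phase congruency, gradient magnitude, FSIM, and feature-map similarity.

FSIM scores the structural agreement of two co-registered grayscale
images from a phase-congruency similarity and a gradient-magnitude
similarity, weighted by the pointwise maximum phase congruency.  The
dataset-level similarity ``St`` of two feature maps averages FSIM over
pairs of maps derived from the same source image; it drives the
shared-learning schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy import ndimage

from veinsemble.feature_maps import (
    FeatureMapSet,
    GaborBank,
    LbpParams,
    build_feature_maps,
)

__all__ = [
    "PhaseCongruencyParams",
    "FsimParams",
    "SimilarityMatrix",
    "phase_congruency",
    "gradient_magnitude",
    "fsim",
    "feature_map_similarity",
    "similarity_matrix",
    "similarity_matrix_from_maps",
]


@dataclass(frozen=True)
class PhaseCongruencyParams:
    """Log-Gabor quadrature filter family used for phase congruency."""

    n_scales: int = 4
    n_orientations: int = 4
    epsilon: float = 1e-4
    min_wavelength: float = 3.0
    mult: float = 2.1
    sigma_onf: float = 0.55
    angular_sigma_factor: float = 1.2

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("need at least one scale and orientation")


@dataclass(frozen=True)
class FsimParams:
    """Constants of the similarity index.

    ``t1``/``t2`` stabilize the phase-congruency and gradient terms
    (``t2`` assumes an 8-bit dynamic range); ``alpha``/``beta`` weight the
    two terms.
    """

    t1: float = 0.85
    t2: float = 160.0
    alpha: float = 1.0
    beta: float = 1.0
    gradient_operator: str = "scharr"

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gradient_operator not in ("scharr", "sobel"):
            raise ValueError(f"unknown gradient operator {self.gradient_operator!r}")


@lru_cache(maxsize=16)
def _log_gabor_filters(
    params: PhaseCongruencyParams, shape: tuple[int, int]
) -> np.ndarray:
    """Frequency-domain filters, shape (n_orient, n_scale, H, W).

    Each filter is the product of a radial log-Gabor transfer function and
    a one-sided angular Gaussian spread, so its inverse FFT yields the
    even (real) and odd (imaginary) quadrature responses.
    """
    h, w = shape
    fy = spfft.fftfreq(h)[:, None]
    fx = spfft.fftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    log_sig = np.log(params.sigma_onf) ** 2
    radial = []
    for s in range(params.n_scales):
        f0 = 1.0 / (params.min_wavelength * params.mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sig))
        lg[0, 0] = 0.0
        radial.append(lg)

    theta_sigma = (
        np.pi / params.n_orientations / params.angular_sigma_factor
    )
    filters = np.empty((params.n_orientations, params.n_scales, h, w))
    for o in range(params.n_orientations):
        angle = o * np.pi / params.n_orientations
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))
        for s in range(params.n_scales):
            filters[o, s] = radial[s] * spread
    return filters


def phase_congruency(
    image: np.ndarray, params: PhaseCongruencyParams = PhaseCongruencyParams()
) -> np.ndarray:
    """Dimensionless local-structure significance map in [0, 1].

    Per orientation the even/odd responses ``e_n``/``o_n`` of each scale
    are summed into ``F``/``H`` and the local energy ``E = sqrt(F^2 +
    H^2)`` is computed; the map is the orientation-summed energy divided
    by ``epsilon`` plus the total amplitude ``sum_n sqrt(e_n^2 + o_n^2)``
    over all scales and orientations.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError(
            f"image must be 2-D and at least 16x16, got shape {image.shape}"
        )
    filters = _log_gabor_filters(params, image.shape)
    img_fft = spfft.fft2(image)
    energy_total = np.zeros(image.shape)
    amplitude_total = np.zeros(image.shape)
    for o in range(params.n_orientations):
        even_sum = np.zeros(image.shape)
        odd_sum = np.zeros(image.shape)
        for s in range(params.n_scales):
            eo = spfft.ifft2(img_fft * filters[o, s])
            even, odd = eo.real, eo.imag
            even_sum += even
            odd_sum += odd
            amplitude_total += np.hypot(even, odd)
        energy_total += np.hypot(even_sum, odd_sum)
    pc = energy_total / (params.epsilon + amplitude_total)
    return np.clip(pc, 0.0, 1.0)


_GRADIENT_KERNELS = {
    "scharr": np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]])
    / 16.0,
    "sobel": np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]])
    / 4.0,
}


def gradient_magnitude(image: np.ndarray, operator: str = "scharr") -> np.ndarray:
    """``sqrt(Gh^2 + Gv^2)`` with the chosen 3x3 derivative kernels.

    Both kernels are normalized so a ramp of unit slope yields a uniform
    interior response of 2 (taps sit two pixels apart).
    """
    if operator not in _GRADIENT_KERNELS:
        raise ValueError(f"unknown gradient operator {operator!r}")
    image = np.asarray(image, dtype=float)
    kx = _GRADIENT_KERNELS[operator]
    gh = ndimage.correlate(image, kx, mode="nearest")
    gv = ndimage.correlate(image, kx.T, mode="nearest")
    return np.hypot(gh, gv)


def _resize_to(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zoom = (shape[0] / image.shape[0], shape[1] / image.shape[1])
    return ndimage.zoom(image.astype(float), zoom, order=1, grid_mode=True,
                        mode="nearest")


def _fsim_from_features(
    pc1: np.ndarray,
    g1: np.ndarray,
    pc2: np.ndarray,
    g2: np.ndarray,
    params: FsimParams,
) -> float:
    s_pc = (2.0 * pc1 * pc2 + params.t1) / (pc1**2 + pc2**2 + params.t1)
    s_g = (2.0 * g1 * g2 + params.t2) / (g1**2 + g2**2 + params.t2)
    s_l = (s_pc**params.alpha) * (s_g**params.beta)
    pc_m = np.maximum(pc1, pc2)
    denom = pc_m.sum()
    if denom <= 1e-12:
        # neither image carries any phase structure; nothing to weight
        return 1.0
    return float((s_l * pc_m).sum() / denom)


def fsim(
    image1: np.ndarray,
    image2: np.ndarray,
    params: FsimParams = FsimParams(),
    pc_params: PhaseCongruencyParams = PhaseCongruencyParams(),
    allow_resize: bool = True,
) -> float:
    """Feature-similarity index of two grayscale images, in (0, 1].

    Images are expected on a [0, 255] intensity scale.  A shape mismatch
    is resolved by bilinear-resizing the second image when
    ``allow_resize`` is set, and rejected otherwise.
    """
    i1 = np.asarray(image1, dtype=float)
    i2 = np.asarray(image2, dtype=float)
    if i1.shape != i2.shape:
        if not allow_resize:
            raise ValueError(f"shape mismatch: {i1.shape} vs {i2.shape}")
        i2 = _resize_to(i2, i1.shape)
    pc1 = phase_congruency(i1, pc_params)
    pc2 = phase_congruency(i2, pc_params)
    g1 = gradient_magnitude(i1, params.gradient_operator)
    g2 = gradient_magnitude(i2, params.gradient_operator)
    return _fsim_from_features(pc1, g1, pc2, g2, params)


@dataclass
class SimilarityMatrix:
    """Symmetric 6x6 matrix of dataset-level feature-map similarities."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6, 6):
            raise ValueError(f"expected a 6x6 matrix, got {self.values.shape}")

    def __getitem__(self, key):
        return self.values[key]

    def pair(self, map_i: int, map_j: int) -> float:
        """Similarity of 1-based maps ``map_i`` and ``map_j``."""
        return float(self.values[map_i - 1, map_j - 1])

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"f{k}" for k in range(1, 7)]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def _map_as_intensity(map_set: FeatureMapSet, index0: int) -> np.ndarray:
    """Feature map ``index0`` (0-based) on a [0, 255] scale."""
    m = map_set[index0].astype(float)
    if index0 == 1:  # binary segmentation map
        m = m * 255.0
    return m


def _check_map_index(k: int) -> None:
    if not 1 <= k <= 6:
        raise ValueError(f"feature-map index must be in 1..6, got {k}")


def feature_map_similarity(
    train_images: Sequence[np.ndarray],
    map_i: int,
    map_j: int,
    lbp: LbpParams = LbpParams(),
    bank: GaborBank = GaborBank(),
    params: FsimParams = FsimParams(),
    pc_params: PhaseCongruencyParams = PhaseCongruencyParams(),
) -> float:
    """Average FSIM of 1-based maps ``map_i`` vs ``map_j`` over all
    training images (maps of each pair derive from the same image)."""
    _check_map_index(map_i)
    _check_map_index(map_j)
    if len(train_images) == 0:
        raise ValueError("need at least one training image")
    total = 0.0
    for image in train_images:
        maps = build_feature_maps(image, lbp=lbp, bank=bank)
        total += fsim(
            _map_as_intensity(maps, map_i - 1),
            _map_as_intensity(maps, map_j - 1),
            params=params,
            pc_params=pc_params,
        )
    return total / len(train_images)


def similarity_matrix_from_maps(
    map_sets: Sequence[FeatureMapSet],
    params: FsimParams = FsimParams(),
    pc_params: PhaseCongruencyParams = PhaseCongruencyParams(),
) -> SimilarityMatrix:
    """6x6 similarity matrix from precomputed per-image map sets.

    Phase congruency and gradient magnitude are computed once per map and
    reused across the 15 unordered pairs.
    """
    if len(map_sets) == 0:
        raise ValueError("need at least one training image")
    values = np.eye(6)
    features = []
    for ms in map_sets:
        per_map = []
        for k in range(6):
            img = _map_as_intensity(ms, k)
            per_map.append(
                (
                    phase_congruency(img, pc_params),
                    gradient_magnitude(img, params.gradient_operator),
                )
            )
        features.append(per_map)
    for i in range(6):
        for j in range(i + 1, 6):
            total = 0.0
            for per_map in features:
                pc_i, g_i = per_map[i]
                pc_j, g_j = per_map[j]
                total += _fsim_from_features(pc_i, g_i, pc_j, g_j, params)
            values[i, j] = values[j, i] = total / len(map_sets)
    return SimilarityMatrix(values=values, n=len(map_sets))


def similarity_matrix(
    train_images: Sequence[np.ndarray],
    lbp: LbpParams = LbpParams(),
    bank: GaborBank = GaborBank(),
    params: FsimParams = FsimParams(),
    pc_params: PhaseCongruencyParams = PhaseCongruencyParams(),
) -> SimilarityMatrix:
    """Build the six feature maps of every training image and average the
    FSIM of all 15 unordered map pairs."""
    if len(train_images) == 0:
        raise ValueError("need at least one training image")
    map_sets = [build_feature_maps(im, lbp=lbp, bank=bank) for im in train_images]
    return similarity_matrix_from_maps(map_sets, params=params, pc_params=pc_params)
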