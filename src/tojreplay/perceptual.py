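"""Image-pair perceptual similarity metrics for the across-context regressor.

Three measures of how perceptually distinct two probe frames are:

* RGB-histogram sum-of-square-difference (SSD) over 256 intensity bins per
  channel (smaller = more similar);
* HOG similarity: Pearson correlation of concatenated
  histogram-of-oriented-gradients cell vectors;
* keypoint-descriptor distance: mean Euclidean distance between matched
  descriptor vectors from a pluggable scale/rotation-tolerant detector
  backend (ORB by default; patent-encumbered detectors such as SURF can be
  registered by the caller when an implementation is available).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .exceptions import CapabilityError, DegenerateDataError, NoFeaturesError

__all__ = [
    "rgb_histogram_ssd",
    "hog_similarity",
    "keypoint_descriptor_distance",
    "register_backend",
    "available_backends",
    "perceptual_similarity_score",
]


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB images, got shape {a.shape}")
    return a, b


def rgb_histogram_ssd(image_a, image_b) -> float:
    """Sum-of-square-difference between per-channel 256-bin pixel-count histograms.

    Intensities are 8-bit (0-255); the score sums, over the three channels
    and all 256 bins, the squared difference in pixel counts.  Zero for
    identical images (and for any permutation of pixel positions); smaller
    means more similar.
    """
    a, b = _check_pair(image_a, image_b)
    total = 0.0
    for ch in range(3):
        ha = np.bincount(a[..., ch].ravel().astype(np.int64), minlength=256)[:256]
        hb = np.bincount(b[..., ch].ravel().astype(np.int64), minlength=256)[:256]
        total += float(np.sum((ha - hb) ** 2))
    return total


def hog_similarity(image_a, image_b, cell_px: int = 16, n_orientations: int = 8) -> float:
    """Pearson correlation of HOG feature vectors of the two images.

    Gradient-orientation histograms are computed over fixed ``cell_px`` x
    ``cell_px`` cells across the whole (grayscale) image and concatenated;
    the score is the correlation between the two images' vectors, in
    [-1, 1].  A constant (zero-gradient) image has an undefined correlation
    and raises :class:`DegenerateDataError`.
    """
    from skimage.color import rgb2gray
    from skimage.feature import hog

    a, b = _check_pair(image_a, image_b)
    if a.shape[0] < cell_px or a.shape[1] < cell_px:
        raise ValueError(f"images must contain at least one full {cell_px}px cell")
    feats = []
    for img in (a, b):
        v = hog(
            rgb2gray(img),
            orientations=n_orientations,
            pixels_per_cell=(cell_px, cell_px),
            cells_per_block=(1, 1),
            feature_vector=True,
        )
        if np.std(v) == 0:
            raise DegenerateDataError("zero-gradient image: HOG correlation undefined")
        feats.append(v)
    return float(np.corrcoef(feats[0], feats[1])[0, 1])


def _orb_backend(image: np.ndarray):
    from skimage.color import rgb2gray
    from skimage.feature import ORB

    orb = ORB(n_keypoints=200)
    try:
        orb.detect_and_extract(rgb2gray(image))
    except RuntimeError:  # skimage raises when no keypoints survive
        return np.empty((0, 2)), np.empty((0, 256))
    return orb.keypoints, orb.descriptors.astype(float)


_BACKENDS: dict[str, Callable] = {"orb": _orb_backend}


def register_backend(name: str, fn: Callable) -> None:
    """Register a keypoint backend: ``fn(image) -> (keypoints, descriptors)``."""
    _BACKENDS[name] = fn


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def keypoint_descriptor_distance(image_a, image_b, backend: str = "orb") -> tuple[float, int]:
    """Mean Euclidean distance between nearest-neighbour-matched descriptors.

    Keypoints and descriptor vectors come from the named backend; matching is
    mutual nearest neighbour and the score is the mean Euclidean distance over
    matches (lower = more similar), returned with the match count.
    """
    from skimage.feature import match_descriptors

    if backend not in _BACKENDS:
        raise CapabilityError(
            f"keypoint backend '{backend}' is not registered (available: "
            f"{available_backends()}); SURF-style backends require installing "
            "opencv-contrib-python and registering a wrapper via register_backend()"
        )
    a, b = _check_pair(image_a, image_b)
    _, desc_a = _BACKENDS[backend](a)
    _, desc_b = _BACKENDS[backend](b)
    if len(desc_a) == 0 or len(desc_b) == 0:
        raise NoFeaturesError("no keypoints detected in at least one image")
    matches = match_descriptors(desc_a, desc_b, cross_check=True)
    if len(matches) == 0:
        raise NoFeaturesError("no descriptor matches between the images")
    d = np.linalg.norm(desc_a[matches[:, 0]] - desc_b[matches[:, 1]], axis=1)
    return float(d.mean()), int(len(matches))


def perceptual_similarity_score(image_a, image_b, backend: str | None = "orb") -> tuple[float, str]:
    """Default perceptual-similarity regressor value, with the method used.

    Prefers the keypoint-descriptor distance when a backend is available,
    falling back to HOG correlation otherwise; returns ``(score, method)``.
    """
    if backend is not None and backend in _BACKENDS:
        try:
            score, _ = keypoint_descriptor_distance(image_a, image_b, backend)
            return score, f"keypoint:{backend}"
        except NoFeaturesError:
            pass
    return hog_similarity(image_a, image_b), "hog"
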