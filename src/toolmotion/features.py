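"""Per-frame visual feature extraction (128-d vector per 252x252 crop).

The extractor is a pluggable contract: anything mapping a clip of
``(T, 252, 252, 3)`` uint8 crops to ``(T, 128)`` float features.  The
built-in backend downsamples each crop to grayscale 32x32 and applies a
fixed, seeded Gaussian random projection to 128 dimensions — a frozen
embedding in the random-features tradition.  It is deterministic,
dependency-light and preserves enough spatial information that hand/tool
pose differences between frames survive; the class signal in this pipeline
is temporal, so the per-frame embedding itself carries no label information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from PIL import Image

from .sequencing import ClipWindow

FEATURE_DIM = 128


class FeatureExtractor(Protocol):
    feature_dim: int

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """(T, 252, 252, 3) uint8 -> (T, feature_dim) float64."""
        ...


class RandomProjectionExtractor:
    """Downsample to 32x32 grayscale, flatten, project with a fixed seeded matrix.

    The projection matrix has i.i.d. N(0, 1/n_pixels) entries so feature
    magnitudes are input-scale independent of the downsample size.
    """

    def __init__(self, feature_dim: int = FEATURE_DIM, downsample: int = 32, seed: int = 0):
        self.feature_dim = feature_dim
        self.downsample = d = downsample
        rng = np.random.default_rng(seed)
        self.projection = rng.normal(0.0, 1.0 / np.sqrt(d * d), size=(d * d, feature_dim))

    def _downsample(self, images: np.ndarray) -> np.ndarray:
        d = self.downsample
        out = np.empty((images.shape[0], d * d))
        for t, img in enumerate(images):
            gray = Image.fromarray(img).convert("L").resize((d, d), Image.BILINEAR)
            out[t] = np.asarray(gray, dtype=np.float64).ravel() / 255.0
        return out

    def __call__(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError(f"expected (T, H, W, 3) crops, got {images.shape}")
        pixels = self._downsample(images)
        feats = pixels @ self.projection
        if feats.shape[1] != self.feature_dim:
            raise ValueError("projection produced wrong feature dimension")
        return feats


@dataclass
class FeatureSequence:
    """Per-frame features psi (T, d) and, once aggregated, psi_hat (T, 128)."""

    psi: np.ndarray
    psi_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.psi)):
            raise ValueError("non-finite feature values")

    @property
    def T(self) -> int:
        return self.psi.shape[0]


def extract_features(clip: ClipWindow, extractor: FeatureExtractor) -> FeatureSequence:
    """Apply the extractor to each crop of a clip; one d-vector per frame."""
    psi = extractor(clip.images)
    if psi.shape[0] != clip.T:
        raise ValueError("extractor returned wrong number of frames")
    return FeatureSequence(psi=psi)
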