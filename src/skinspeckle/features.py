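"""Color and texture features of 65x65 visible-imaging ROI patches.

Four feature families are extracted, with fixed lengths per ROI:

========  ======  =====================================================
family    length  content
========  ======  =====================================================
color       6     per-channel RGB means and standard deviations
glcm        8     mean and SD over 4 directions of ASM, ENT, INE, COR
gabor      108    12 Gabor filters (3 scales x 4 orientations) x 3x3
                  block grid, mean response magnitude per block
dtcwt       12    mean |real| and mean |imag| of the 6 oriented
                  level-1 DT-CWT subbands
========  ======  =====================================================

All extractors are scikit-learn transformers operating on stacks of RGB
patches; single-patch convenience functions wrap them.  Gray conversion is
ITU-R BT.601 luminance throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.feature import graycomatrix
from skimage.filters import gabor
from sklearn.base import BaseEstimator, TransformerMixin

from ._dtcwt import ORIENTATIONS, dtcwt_level1
from .simulate import GRAY_WEIGHTS, RGBPatch

__all__ = [
    "FeatureVector",
    "ColorFeatures",
    "GLCMFeatures",
    "GaborFeatures",
    "DTCWTFeatures",
    "gray_convert",
    "color_features",
    "glcm_features",
    "gabor_features",
    "dtcwt_features",
    "extract_features",
    "contrast_con",
    "FAMILY_LENGTHS",
]

FAMILY_LENGTHS = {"color": 6, "glcm": 8, "gabor": 108, "dtcwt": 12}

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GABOR_THETAS_DEG = (0, 45, 90, 135)


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered feature values for one ROI."""

    names: tuple[str, ...]
    values: np.ndarray
    family: str

    def __len__(self) -> int:
        return len(self.names)


def _as_pixel_array(patch: RGBPatch | np.ndarray) -> np.ndarray:
    pixels = patch.pixels if isinstance(patch, RGBPatch) else np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB patch")
    return pixels


def gray_convert(patch: RGBPatch | np.ndarray) -> np.ndarray:
    """BT.601 luminance, float in [0, 255]."""
    pixels = _as_pixel_array(patch).astype(np.float64)
    return pixels @ GRAY_WEIGHTS


def _stack(X: Iterable[RGBPatch | np.ndarray]) -> list[np.ndarray]:
    return [_as_pixel_array(p) for p in X]


class _PatchTransformer(TransformerMixin, BaseEstimator):
    """Base class: stateless per-patch feature extraction."""

    family: str = ""

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray([self._extract(p) for p in _stack(X)], dtype=float)

    def _extract(self, pixels: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ColorFeatures(_PatchTransformer):
    """Per-channel means and population standard deviations of RGB."""

    family = "color"

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        flat = pixels.reshape(-1, 3).astype(np.float64)
        return np.concatenate([flat.mean(axis=0), flat.std(axis=0)])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            ["mean_R", "mean_G", "mean_B", "sd_R", "sd_G", "sd_B"], dtype=object
        )


class GLCMFeatures(_PatchTransformer):
    """Haralick statistics of symmetric distance-1 co-occurrence matrices.

    The gray image is quantized to ``levels`` bins; a symmetric, normalized
    GLCM is built for each of the four directions 0/45/90/135 degrees; for
    each of ASM, ENT (natural log), INE (contrast) and COR, the mean and the
    population SD across the four directions are reported.  The correlation
    of a zero-variance image is defined as 0.
    """

    family = "glcm"

    def __init__(self, levels: int = 32, distance: int = 1):
        self.levels = levels
        self.distance = distance

    @staticmethod
    def _stats(p: np.ndarray) -> tuple[float, float, float, float]:
        """ASM, ENT, INE, COR of one normalized GLCM."""
        g = p.shape[0]
        i = np.arange(g, dtype=float)
        asm = float((p**2).sum())
        nz = p[p > 0]
        ent = float(-(nz * np.log(nz)).sum())
        diff2 = (i[:, None] - i[None, :]) ** 2
        ine = float((p * diff2).sum())
        mu_i = float((p.sum(axis=1) * i).sum())
        mu_j = float((p.sum(axis=0) * i).sum())
        var_i = float((p.sum(axis=1) * (i - mu_i) ** 2).sum())
        var_j = float((p.sum(axis=0) * (i - mu_j) ** 2).sum())
        if var_i <= 1e-15 or var_j <= 1e-15:
            cor = 0.0
        else:
            cov = float((p * np.outer(i - mu_i, i - mu_j)).sum())
            cor = cov / np.sqrt(var_i * var_j)
        return asm, ent, ine, cor

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        gray = gray_convert(pixels)
        q = np.floor(gray * self.levels / 256.0).astype(np.intp)
        q = np.clip(q, 0, self.levels - 1).astype(np.uint8)
        glcm = graycomatrix(
            q,
            distances=[self.distance],
            angles=list(_GLCM_ANGLES),
            levels=self.levels,
            symmetric=True,
            normed=True,
        )
        per_dir = np.asarray(
            [self._stats(glcm[:, :, 0, a]) for a in range(len(_GLCM_ANGLES))]
        )  # (4 directions, 4 stats)
        means = per_dir.mean(axis=0)
        sds = per_dir.std(axis=0)
        out = np.empty(8)
        out[0::2] = means
        out[1::2] = sds
        return out

    def get_feature_names_out(self, input_features=None):
        names = []
        for stat in ("asm", "ent", "ine", "cor"):
            names += [f"{stat}_mean", f"{stat}_sd"]
        return np.asarray(names, dtype=object)


def _gabor_sigma(wavelength: float, bandwidth: float = 1.0) -> float:
    """Gaussian envelope scale along the wave axis for a given octave bandwidth."""
    b = 2.0**bandwidth
    return wavelength / np.pi * np.sqrt(np.log(2) / 2) * (b + 1) / (b - 1)


class GaborFeatures(_PatchTransformer):
    """Block-wise mean magnitude of a 12-filter Gabor bank.

    Wavelengths {4, 8, 16} px span the 65-px ROI at 1-octave bandwidth and
    spatial aspect ratio 0.5; four orientations at 45-degree steps.  The ROI
    is split into a 3x3 block grid (blocks as equal as integer division
    allows) and the mean response magnitude per (filter, block) gives
    3 scales x 4 orientations x 9 blocks = 108 features in fixed
    (scale, orientation, block-row, block-col) order.
    """

    family = "gabor"

    def __init__(
        self,
        wavelengths: Sequence[float] = (4.0, 8.0, 16.0),
        bandwidth: float = 1.0,
        aspect_ratio: float = 0.5,
        grid: int = 3,
    ):
        self.wavelengths = wavelengths
        self.bandwidth = bandwidth
        self.aspect_ratio = aspect_ratio
        self.grid = grid

    def _block_means(self, magnitude: np.ndarray) -> np.ndarray:
        out = []
        for rows in np.array_split(magnitude, self.grid, axis=0):
            for block in np.array_split(rows, self.grid, axis=1):
                out.append(block.mean())
        return np.asarray(out)

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        if min(pixels.shape[:2]) < 3 * self.grid:
            raise ValueError(
                f"patch too small for a {self.grid}x{self.grid} block grid"
            )
        gray = gray_convert(pixels)
        feats = []
        for lam in self.wavelengths:
            sigma_x = _gabor_sigma(lam, self.bandwidth)
            sigma_y = sigma_x / self.aspect_ratio
            for deg in _GABOR_THETAS_DEG:
                real, imag = gabor(
                    gray,
                    frequency=1.0 / lam,
                    theta=np.deg2rad(deg),
                    sigma_x=sigma_x,
                    sigma_y=sigma_y,
                )
                feats.append(self._block_means(np.hypot(real, imag)))
        return np.concatenate(feats)

    def get_feature_names_out(self, input_features=None):
        names = []
        for lam in self.wavelengths:
            for deg in _GABOR_THETAS_DEG:
                for r in range(self.grid):
                    for c in range(self.grid):
                        names.append(f"gabor_w{lam:g}_o{deg}_b{r}{c}")
        return np.asarray(names, dtype=object)


class DTCWTFeatures(_PatchTransformer):
    """Mean |real| and |imag| of the six level-1 DT-CWT subbands.

    Odd-sized patches are symmetrically padded to even dimensions before the
    transform.  Order: (+15, +45, +75, -75, -45, -15 degrees) x (real, imag).
    """

    family = "dtcwt"

    min_size = 16

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        if min(pixels.shape[:2]) < self.min_size:
            raise ValueError(f"dtcwt features need at least a {self.min_size}-px patch")
        gray = gray_convert(pixels)
        pad_r = gray.shape[0] % 2
        pad_c = gray.shape[1] % 2
        if pad_r or pad_c:
            gray = np.pad(gray, ((0, pad_r), (0, pad_c)), mode="symmetric")
        bands = dtcwt_level1(gray)
        feats = []
        for k in range(6):
            feats.append(np.abs(bands[:, :, k].real).mean())
            feats.append(np.abs(bands[:, :, k].imag).mean())
        return np.asarray(feats)

    def get_feature_names_out(self, input_features=None):
        names = []
        for deg in ORIENTATIONS:
            for part in ("real", "imag"):
                names.append(f"dtcwt_{deg:+d}_{part}")
        return np.asarray(names, dtype=object)


_TRANSFORMERS = {
    "color": ColorFeatures,
    "glcm": GLCMFeatures,
    "gabor": GaborFeatures,
    "dtcwt": DTCWTFeatures,
}


def _extract_one(patch, transformer_cls) -> FeatureVector:
    t = transformer_cls()
    values = t.fit([patch]).transform([patch])[0]
    if not np.all(np.isfinite(values)):  # pragma: no cover - defensive
        raise ValueError("non-finite feature value")
    return FeatureVector(
        names=tuple(t.get_feature_names_out()), values=values, family=t.family
    )


def color_features(patch: RGBPatch | np.ndarray) -> FeatureVector:
    return _extract_one(patch, ColorFeatures)


def glcm_features(patch: RGBPatch | np.ndarray) -> FeatureVector:
    return _extract_one(patch, GLCMFeatures)


def gabor_features(patch: RGBPatch | np.ndarray) -> FeatureVector:
    return _extract_one(patch, GaborFeatures)


def dtcwt_features(patch: RGBPatch | np.ndarray) -> FeatureVector:
    return _extract_one(patch, DTCWTFeatures)


def extract_features(
    patch: RGBPatch | np.ndarray, families: Sequence[str] = ("color",)
) -> FeatureVector:
    """Concatenate the requested feature families for one patch."""
    parts = []
    for fam in families:
        if fam not in _TRANSFORMERS:
            raise ValueError(f"unknown feature family {fam!r}")
        parts.append(_extract_one(patch, _TRANSFORMERS[fam]))
    if len(parts) == 1:
        return parts[0]
    return FeatureVector(
        names=tuple(n for p in parts for n in p.names),
        values=np.concatenate([p.values for p in parts]),
        family="combined",
    )


def contrast_con(ss: RGBPatch | np.ndarray, is_: RGBPatch | np.ndarray) -> float:
    """Signed contrast: mean gray of the sound patch minus the injured patch.

    Negative values mean the injured skin is the brighter region, as happens
    within the first hour after wounding when the fresh wound is wet and
    reflective.
    """
    return float(gray_convert(ss).mean() - gray_convert(is_).mean())
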