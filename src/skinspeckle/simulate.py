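"""Synthetic dynamic-speckle stacks and two-class skin patches.

Every downstream stage (activity quantification, feature extraction,
classification) is exercised on data from this module, so the generators are
first-class, tested code.  The speckle generator produces fully developed
dynamic speckle whose temporal decorrelation is controlled by a single
parameter ``rho``; the patch generator produces paired sound-skin (SS) and
injured-skin (IS) RGB patches whose mean-gray contrast ``con`` is controlled
exactly (up to 8-bit quantization).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SpeckleSimParams",
    "PatchSimParams",
    "SpeckleSequence",
    "RGBPatch",
    "LabeledSample",
    "simulate_speckle_sequence",
    "simulate_skin_patch_pair",
    "generate_dataset",
    "GRAY_WEIGHTS",
]

# ITU-R BT.601 luminance weights, the fixed gray-conversion convention of the
# whole package (see features.gray_convert).
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SpeckleSimParams:
    """Parameters of the dynamic-speckle simulator.

    ``rho`` is the frame-to-frame correlation coefficient of the underlying
    complex field (an AR(1) process): ``rho=1`` freezes the field (a static
    stack, zero activity), ``rho=0`` decorrelates frames completely.
    ``grain_sigma`` is the spatial Gaussian smoothing scale of the field in
    pixels and sets the speckle grain size.
    """

    height: int = 64
    width: int = 64
    n_frames: int = 512
    frame_rate: float = 12.5
    rho: float = 0.9
    grain_sigma: float = 1.0
    bit_depth: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("speckle frames must be at least 8x8 pixels")
        if self.n_frames < 2:
            raise ValueError("a speckle sequence needs at least 2 frames")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 2 <= self.bit_depth <= 65536:
            raise ValueError("bit_depth must be in [2, 65536]")
        if self.grain_sigma < 0:
            raise ValueError("grain_sigma must be non-negative")


@dataclass(frozen=True)
class PatchSimParams:
    """Parameters of the paired SS/IS patch simulator.

    ``con`` is the target signed contrast: mean gray value of the SS patch
    minus mean gray value of the IS patch.  A fresh injury reflects more
    light than sound skin, so that regime has negative ``con``; suberized
    older injuries darken and have positive ``con``.  ``n_lenticels`` dark
    disks emulate the lenticel spots scattered over injured areas.
    """

    size: int = 65
    mean_rgb_ss: tuple[float, float, float] = (150.0, 120.0, 90.0)
    con: float = 30.9
    channel_sd: tuple[float, float, float] = (8.0, 8.0, 8.0)
    n_lenticels: int = 5
    lenticel_radius: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.size < 16:
            raise ValueError("patch size must be at least 16 pixels")
        if abs(self.con) > 128:
            raise ValueError("target contrast |con| must be at most 128")
        if any(sd < 0 for sd in self.channel_sd):
            raise ValueError("channel_sd must be non-negative")
        if self.n_lenticels < 0 or self.lenticel_radius < 0:
            raise ValueError("lenticel parameters must be non-negative")
        for m in self.mean_rgb_ss:
            if not 0 <= m <= 255:
                raise ValueError("mean_rgb_ss must lie in [0, 255]")
            if not 0 <= m - self.con <= 255:
                raise ValueError(
                    "requested contrast pushes an IS channel mean outside "
                    f"[0, 255]: SS mean {m}, con {self.con}"
                )


@dataclass(frozen=True)
class SpeckleSequence:
    """Ordered stack of monochrome speckle frames with frame-rate metadata."""

    frames: np.ndarray  # (T, H, W) unsigned integers
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a speckle sequence needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class RGBPatch:
    """A square 8-bit RGB region of interest."""

    pixels: np.ndarray  # (H, W, 3) uint8
    roi_origin: tuple[int, int] = (0, 0)
    label: str = "unknown"  # SS | IS | unknown

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")


@dataclass(frozen=True)
class LabeledSample:
    """Unit of classification: raw data plus class label and storage tag."""

    data: object  # SpeckleSequence or RGBPatch
    label: str  # "SS" or "IS"
    storage_time: str = "sound"
    seed: int = 0


def _smoothed_complex_field(rng: np.random.Generator, shape, grain_sigma: float) -> np.ndarray:
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    if grain_sigma > 0:
        re = gaussian_filter(re, grain_sigma, mode="wrap")
        im = gaussian_filter(im, grain_sigma, mode="wrap")
    f = re + 1j * im
    # Unit mean intensity so the AR(1) recursion is variance-stationary.
    f /= np.sqrt(np.mean(np.abs(f) ** 2))
    return f


def simulate_speckle_sequence(params: SpeckleSimParams) -> SpeckleSequence:
    """Simulate a fully developed dynamic-speckle stack.

    The complex scattered field ``E_t`` evolves as an order-1 autoregressive
    process, ``E_t = rho E_{t-1} + sqrt(1 - rho^2) W_t``, with spatially
    smoothed circular-Gaussian innovations ``W_t``.  Recorded intensity is
    ``|E_t|^2``, linearly rescaled once per stack and quantized to
    ``bit_depth`` gray levels.  Per-stack (not per-frame) rescaling matters:
    rescaling each frame separately would inject artificial frame-to-frame
    gray-level transitions and bias the inertia moment.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)

    field = _smoothed_complex_field(rng, shape, params.grain_sigma)
    intensity = np.empty((params.n_frames,) + shape, dtype=np.float64)
    intensity[0] = np.abs(field) ** 2
    innov_scale = np.sqrt(1.0 - params.rho**2)
    for t in range(1, params.n_frames):
        if innov_scale > 0:
            w = _smoothed_complex_field(rng, shape, params.grain_sigma)
            field = params.rho * field + innov_scale * w
        intensity[t] = np.abs(field) ** 2

    levels = params.bit_depth
    peak = intensity.max()
    if peak <= 0:  # pragma: no cover - circular Gaussian field is never all-zero
        peak = 1.0
    quantized = np.round(intensity * (levels - 1) / peak)
    dtype = np.uint8 if levels <= 256 else np.uint16
    return SpeckleSequence(frames=quantized.astype(dtype), frame_rate=params.frame_rate)


def _render_lenticels(
    patch: np.ndarray, rng: np.random.Generator, n: int, radius: float, darken: float = 0.45
) -> None:
    """Stamp dark disks (lenticels) into ``patch`` in place."""
    if n <= 0 or radius <= 0:
        return
    size = patch.shape[0]
    rows, cols = np.mgrid[0:size, 0:size]
    for _ in range(n):
        cr, cc = rng.uniform(radius, size - radius, size=2)
        mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
        patch[mask] *= darken


def simulate_skin_patch_pair(params: PatchSimParams) -> tuple[RGBPatch, RGBPatch]:
    """Simulate one (sound skin, injured skin) patch pair.

    The IS patch's channel means are shifted by ``-con`` relative to the SS
    patch so the luminance contrast equals ``con``; after lenticel rendering
    the IS patch is re-centred so the realized float contrast is exact (the
    only residual error is 8-bit quantization).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.size, params.size, 3)
    means = np.asarray(params.mean_rgb_ss, dtype=float)
    sds = np.asarray(params.channel_sd, dtype=float)

    ss = means + rng.standard_normal(shape) * sds
    is_ = (means - params.con) + rng.standard_normal(shape) * sds
    _render_lenticels(is_, rng, params.n_lenticels, params.lenticel_radius)

    # Re-centre IS so gray(SS) - gray(IS) == con exactly before quantization.
    gray_ss = float((ss * GRAY_WEIGHTS).sum(axis=2).mean())
    gray_is = float((is_ * GRAY_WEIGHTS).sum(axis=2).mean())
    is_ += (gray_ss - params.con) - gray_is

    ss_q = np.clip(np.round(ss), 0, 255).astype(np.uint8)
    is_q = np.clip(np.round(is_), 0, 255).astype(np.uint8)
    return (
        RGBPatch(pixels=ss_q, label="SS"),
        RGBPatch(pixels=is_q, label="IS"),
    )


def generate_dataset(
    n_per_class: int,
    mode: str,
    params: SpeckleSimParams | PatchSimParams | None = None,
    seed: int = 0,
    rho_by_class: tuple[float, float] = (0.95, 0.5),
    storage_time: str = "1h",
) -> list[LabeledSample]:
    """Generate a reproducible labeled two-class collection.

    ``mode="speckle"``: SS samples use ``rho_by_class[0]`` (low activity of
    intact periderm), IS samples ``rho_by_class[1]`` (high activity of a
    fresh wound).  ``mode="rgb"``: each pair call yields one SS and one IS
    patch at the configured contrast.  Per-sample seeds are spawned
    deterministically from ``seed`` via ``np.random.SeedSequence``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if mode not in ("speckle", "rgb"):
        raise ValueError(f"mode must be 'speckle' or 'rgb', got {mode!r}")

    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    samples: list[LabeledSample] = []
    if mode == "speckle":
        base = params if params is not None else SpeckleSimParams(n_frames=125)
        assert isinstance(base, SpeckleSimParams)
        rho_ss, rho_is = rho_by_class
        for i in range(n_per_class):
            for label, rho, s in (
                ("SS", rho_ss, child_seeds[2 * i]),
                ("IS", rho_is, child_seeds[2 * i + 1]),
            ):
                p = replace(base, rho=rho, seed=s)
                samples.append(
                    LabeledSample(
                        data=simulate_speckle_sequence(p),
                        label=label,
                        storage_time="sound" if label == "SS" else storage_time,
                        seed=s,
                    )
                )
    else:
        base = params if params is not None else PatchSimParams()
        assert isinstance(base, PatchSimParams)
        for i in range(n_per_class):
            s = child_seeds[2 * i]
            p = replace(base, seed=s)
            ss, is_ = simulate_skin_patch_pair(p)
            samples.append(LabeledSample(data=ss, label="SS", storage_time="sound", seed=s))
            samples.append(LabeledSample(data=is_, label="IS", storage_time=storage_time, seed=s))
    return samples
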