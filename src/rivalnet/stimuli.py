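"""Gray-scale image inputs driving the competing pools.

Every stimulus is a nonnegative pixel matrix.  A pixel matrix of shape
``(rows, cols)`` is flattened row-major into a length-``n`` vector, and
vector index ``j`` is identified with 1-based integer grid coordinates
``(row, col)`` on the ``[1, rows] x [1, cols]`` Cartesian grid.  The same
convention is used by the localized feedforward builder, so receptive-field
centers and pixel locations live on one shared grid.

Images are stored as floats; 8-bit raster files are mapped to ``[0, 1]``
on read (``/255``) and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

__all__ = [
    "ImageInput",
    "StimulusSet",
    "make_grating",
    "make_synthetic_scene",
    "make_complementary_pair",
    "normalize_mean_set",
    "load_image",
    "save_image",
    "rivalry_gratings",
    "fusion_gratings",
    "interocular_grouping_set",
]


@dataclass(frozen=True)
class ImageInput:
    """A nonnegative gray-scale image together with its vectorized view."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("pixel values must be finite and nonnegative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n(self) -> int:
        return self.pixels.size

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening of the pixel matrix."""
        return self.pixels.ravel()

    def grid_coords(self, j: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """1-based (row, col) grid coordinates of vector index ``j``."""
        j = np.asarray(j)
        ncols = self.pixels.shape[1]
        return j // ncols + 1, j % ncols + 1

    @classmethod
    def from_vector(cls, vector: np.ndarray, shape: tuple[int, int]) -> "ImageInput":
        return cls(np.asarray(vector, dtype=float).reshape(shape))

    def mean(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class StimulusSet:
    """Ordered images for the ``q`` pools, after equal-mean normalization."""

    images: tuple[ImageInput, ...]
    normalization_record: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if len(self.images) < 1:
            raise ValueError("need at least one image")
        dims = {im.shape for im in self.images}
        if len(dims) != 1:
            raise ValueError("all images must share dimensions")

    @property
    def q(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def n(self) -> int:
        return self.images[0].n

    def vectors(self) -> np.ndarray:
        """(q, n) array of flattened images."""
        return np.stack([im.vector for im in self.images])


def make_grating(
    orientation: str,
    period: int,
    dims: tuple[int, int],
    low: float = 0.25,
    high: float = 0.75,
) -> ImageInput:
    """Square-wave grating.

    ``horizontal`` stripes are constant along rows and alternate with the row
    index (the first ``period/2`` rows take ``high``); ``vertical`` is its
    transpose.  Defaults render a moderate-contrast grating about mid-gray,
    the standard presentation in rivalry experiments.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    if period < 2:
        raise ValueError("period must be >= 2 pixels")
    if dims[0] <= 0 or dims[1] <= 0:
        raise ValueError("dims must be positive")
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    rows, cols = dims
    if orientation == "horizontal":
        phase = np.arange(rows) % period < period / 2
        img = np.where(phase[:, None], high, low) * np.ones((1, cols))
    else:
        phase = np.arange(cols) % period < period / 2
        img = np.ones((rows, 1)) * np.where(phase[None, :], high, low)
    return ImageInput(img)


def make_synthetic_scene(
    dims: tuple[int, int],
    spectral_exponent: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> ImageInput:
    """Synthetic natural-scene stand-in: 1/f^exponent filtered Gaussian noise.

    White noise is filtered in the Fourier domain with amplitude
    ``|f|**(-exponent/2)`` (so the power spectrum falls as ``1/f^exponent``),
    then min-max scaled to ``[0, 1]``.  ``spectral_exponent = 0`` leaves the
    noise white; ``~2`` mimics the spatial statistics of natural scenes.
    Deterministic given the seed.
    """
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = dims
    noise = rng.standard_normal((rows, cols))
    F = np.fft.fft2(noise)
    fx = np.fft.fftfreq(rows)[:, None]
    fy = np.fft.fftfreq(cols)[None, :]
    f = np.hypot(fx, fy)
    amp = np.ones_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-spectral_exponent / 2.0)
    amp[~nonzero] = 0.0  # remove DC; re-centered by the [0,1] rescale below
    img = np.real(np.fft.ifft2(F * amp))
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img) + 0.5
    return ImageInput(img)


def make_complementary_pair(
    imgA: ImageInput, imgB: ImageInput, block: int | None = None
) -> tuple[ImageInput, ImageInput]:
    """Complementary rearranged versions of two images.

    Blocks of size ``block`` are swapped between the two images on a
    checkerboard of tiles (tiles with odd ``i+j`` parity are exchanged), so
    each output combines complementary pieces of both inputs.  Applying the
    operation to the outputs restores the original pair.  ``block`` defaults
    to half the image side (quadrant swap).
    """
    if imgA.shape != imgB.shape:
        raise ValueError("images must share dimensions")
    rows, cols = imgA.shape
    if block is None:
        block = rows // 2
    if block <= 0 or rows % block or cols % block:
        raise ValueError("block must divide both image dimensions")
    A, B = imgA.pixels.copy(), imgB.pixels.copy()
    for bi in range(rows // block):
        for bj in range(cols // block):
            if (bi + bj) % 2 == 1:
                sl = (slice(bi * block, (bi + 1) * block), slice(bj * block, (bj + 1) * block))
                A[sl], B[sl] = imgB.pixels[sl], imgA.pixels[sl]
    return ImageInput(A), ImageInput(B)


def normalize_mean_set(images: list[ImageInput]) -> StimulusSet:
    """Rescale images multiplicatively so all means equal the first image's mean.

    Equal mean pixel values make the expected feedforward drive into each
    pool comparable, so no pool is trivially favored by overall luminance.
    """
    if len(images) < 1:
        raise ValueError("need at least one image")
    means = np.array([im.mean() for im in images])
    if np.any(means == 0):
        raise ValueError("cannot normalize a zero-mean image")
    factors = means[0] / means
    out = tuple(ImageInput(im.pixels * f) for im, f in zip(images, factors))
    return StimulusSet(out, tuple(factors))


def load_image(path) -> ImageInput:
    """Read a gray-scale PNG/PGM raster; 8/16-bit integers are scaled to [0, 1]."""
    raw = iio.imread(path)
    arr = raw.astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return ImageInput(arr)


def save_image(path, image: ImageInput) -> None:
    """Write an image as an 8-bit gray-scale raster (values clipped to [0, 1])."""
    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


# ---------------------------------------------------------------------------
# Standard fixtures: the stimulus sets used throughout the experiments.

def rivalry_gratings(
    dims: tuple[int, int] = (100, 100), period: int = 20,
    low: float = 0.25, high: float = 0.75,
) -> StimulusSet:
    """Orthogonal (horizontal vs. vertical) gratings, equal-mean normalized.

    The canonical binocular-rivalry condition: two maximally dissimilar
    monocular stimuli of identical mean luminance.
    """
    h = make_grating("horizontal", period, dims, low, high)
    v = make_grating("vertical", period, dims, low, high)
    return normalize_mean_set([h, v])


def fusion_gratings(
    dims: tuple[int, int] = (100, 100), period: int = 20,
    low: float = 0.25, high: float = 0.75,
) -> StimulusSet:
    """Identical horizontal gratings in both pools (binocular fusion)."""
    h = make_grating("horizontal", period, dims, low, high)
    return normalize_mean_set([h, ImageInput(h.pixels.copy())])


def interocular_grouping_set(
    dims: tuple[int, int] = (100, 100),
    spectral_exponent: float = 2.0,
    seed: int = 0,
    block: int | None = None,
) -> StimulusSet:
    """Four-percept set: two synthetic scenes plus their complementary rearrangement."""
    a = make_synthetic_scene(dims, spectral_exponent, seed=np.random.default_rng([seed, 0]))
    b = make_synthetic_scene(dims, spectral_exponent, seed=np.random.default_rng([seed, 1]))
    c, d = make_complementary_pair(a, b, block)
    return normalize_mean_set([a, b, c, d])
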