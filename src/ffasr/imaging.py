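"""Core image representation, bicubic degradation, patch geometry and quality metrics.

Everything downstream works on :class:`Image` — a normalized float64 grayscale
raster — and on :class:`PatchPairSet`, the paired LR/HR patch matrices that are
the training currency of every patch-regression method. The degradation model is
``x_l = G x_h`` with ``G`` a bicubic downsampler: the same separable Catmull-Rom
kernel (a = -0.5, antialiased when shrinking) is used both to synthesize LR
images from HR ground truth and as the interpolation baseline, so the two are
mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Image",
    "ImagePair",
    "PatchPairSet",
    "QualityMetrics",
    "load_image",
    "save_image",
    "bicubic_resize",
    "degrade",
    "psnr",
    "ssim",
    "extract_patches",
    "extract_training_patches",
    "assemble_image",
]

#: Luminance weights (ITU-R BT.601) used when collapsing RGB rasters.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Image:
    """2-D intensity raster with values normalized to [0, 1].

    Parameters
    ----------
    pixels
        Float array of shape ``(height, width)``; row-major, origin top-left.
    source_bit_depth
        Bit depth of the raster the image was loaded from (8 by default);
        informational — all arithmetic happens on the [0, 1] scale.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Image requires a non-empty 2-D pixel array")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("Image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImagePair:
    """An HR image with its bicubically degraded LR counterpart at factor M."""

    hr: Image
    lr: Image
    factor: int

    def __post_init__(self) -> None:
        m = self.factor
        if m not in (2, 4):
            raise ValueError(f"upscaling factor must be 2 or 4, got {m}")
        if self.hr.height != m * self.lr.height or self.hr.width != m * self.lr.width:
            raise ValueError("HR dimensions must be factor x LR dimensions")


@dataclass
class PatchPairSet:
    """Column-aligned LR/HR training patch matrices.

    ``X_l`` is ``(S_l, N)`` and ``X_h`` is ``(S_h, N)``; column ``n`` of each
    holds the vectorized (row-major) LR and HR patch of the same training pair,
    both with the LR patch's DC mean removed (stored in ``lr_means`` so
    reconstruction can re-add it). HR anchors are ``factor`` times the LR grid
    anchors in ``positions``.
    """

    X_l: np.ndarray
    X_h: np.ndarray
    positions: np.ndarray  # (N, 2) LR-grid (row, col) anchors
    lr_means: np.ndarray  # (N,)
    factor: int
    lr_patch_size: int = 3
    lr_stride: int = 2

    def __post_init__(self) -> None:
        if self.X_l.ndim != 2 or self.X_h.ndim != 2:
            raise ValueError("patch matrices must be 2-D")
        if self.X_l.shape[1] != self.X_h.shape[1] or self.X_l.shape[1] < 1:
            raise ValueError("X_l and X_h must hold the same positive number of columns")
        if self.X_l.shape[0] != self.lr_patch_size**2:
            raise ValueError("S_l must equal lr_patch_size^2")
        if self.X_h.shape[0] != (self.lr_patch_size * self.factor) ** 2:
            raise ValueError("S_h must equal (factor * lr_patch_size)^2")

    @property
    def n_pairs(self) -> int:
        return self.X_l.shape[1]

    @property
    def hr_patch_size(self) -> int:
        return self.lr_patch_size * self.factor

    @property
    def hr_stride(self) -> int:
        return self.lr_stride * self.factor

    def save(self, path) -> None:
        np.savez(
            path,
            X_l=self.X_l,
            X_h=self.X_h,
            positions=self.positions,
            lr_means=self.lr_means,
            factor=self.factor,
            lr_patch_size=self.lr_patch_size,
            lr_stride=self.lr_stride,
        )

    @classmethod
    def load(cls, path) -> "PatchPairSet":
        with np.load(path) as z:
            return cls(
                X_l=z["X_l"],
                X_h=z["X_h"],
                positions=z["positions"],
                lr_means=z["lr_means"],
                factor=int(z["factor"]),
                lr_patch_size=int(z["lr_patch_size"]),
                lr_stride=int(z["lr_stride"]),
            )


@dataclass(frozen=True)
class QualityMetrics:
    """PSNR (dB, ``inf`` for identical images) and SSIM in [-1, 1]."""

    psnr_db: float
    ssim: float


# ---------------------------------------------------------------------------
# raster I/O


def load_image(path) -> Image:
    """Load a PNG/TIFF raster as a grayscale :class:`Image` in [0, 1].

    Multi-channel inputs are collapsed to luminance before normalization;
    8- and 16-bit integer rasters are divided by their full-scale value.
    """
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.size == 0:
        raise ValueError(f"zero-sized raster: {path}")
    arr = raw.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA if arr.shape[2] >= 3 else arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"unsupported raster layout with shape {raw.shape}")
    if np.issubdtype(raw.dtype, np.integer):
        depth = 8 * raw.dtype.itemsize
        arr = arr / float(2**depth - 1)
    else:
        depth = 8  # float rasters assumed already on [0, 1]
    return Image(np.clip(arr, 0.0, 1.0), source_bit_depth=depth)


def save_image(img: Image, path) -> None:
    """Write an :class:`Image` as an 8-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    iio.imwrite(path, np.round(img.pixels * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# bicubic resampling


def _cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (Catmull-Rom for a = -0.5)."""
    ax = np.abs(x)
    ax2 = ax * ax
    ax3 = ax2 * ax
    out = np.where(
        ax <= 1,
        (a + 2) * ax3 - (a + 3) * ax2 + 1,
        np.where(ax < 2, a * ax3 - 5 * a * ax2 + 8 * a * ax - 4 * a, 0.0),
    )
    return out


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) row-stochastic bicubic interpolation matrix.

    When shrinking, the kernel support is stretched by the scale factor
    (antialiasing), matching the convention of MATLAB's imresize.
    """
    scale = n_in / n_out
    kwidth = max(scale, 1.0)
    centers = (np.arange(n_out) + 0.5) * scale - 0.5
    support = 2 * kwidth
    left = np.floor(centers - support).astype(int) + 1
    n_taps = int(np.ceil(2 * support)) + 2
    taps = left[:, None] + np.arange(n_taps)[None, :]
    weights = _cubic_kernel((centers[:, None] - taps) / kwidth)
    weights /= weights.sum(axis=1, keepdims=True)
    # replicate-pad edge handling: clamp tap indices into range
    taps = np.clip(taps, 0, n_in - 1)
    mat = np.zeros((n_out, n_in))
    rows = np.repeat(np.arange(n_out), n_taps)
    np.add.at(mat, (rows, taps.ravel()), weights.ravel())
    return mat


def bicubic_resize(img: Image, out_height: int, out_width: int) -> Image:
    """Resample with the shared Catmull-Rom bicubic kernel; clipped to [0, 1]."""
    if out_height < 1 or out_width < 1:
        raise ValueError("target dimensions must be positive")
    px = img.pixels
    if (out_height, out_width) == px.shape:
        return Image(px.copy(), img.source_bit_depth)
    w_r = _resize_matrix(px.shape[0], out_height)
    w_c = _resize_matrix(px.shape[1], out_width)
    out = w_r @ px @ w_c.T
    return Image(np.clip(out, 0.0, 1.0), img.source_bit_depth)


def degrade(hr: Image, factor: int) -> ImagePair:
    """Apply the degradation model: crop HR to a multiple of M, bicubic-downsample."""
    if factor not in (2, 4):
        raise ValueError(f"factor must be 2 or 4, got {factor}")
    if hr.height < factor or hr.width < factor:
        raise ValueError("image smaller than the downsampling factor")
    h = (hr.height // factor) * factor
    w = (hr.width // factor) * factor
    hr_c = Image(hr.pixels[:h, :w], hr.source_bit_depth)
    lr = bicubic_resize(hr_c, h // factor, w // factor)
    return ImagePair(hr=hr_c, lr=lr, factor=factor)


# ---------------------------------------------------------------------------
# quality metrics


def psnr(ref: Image, test: Image) -> float:
    """Peak signal-to-noise ratio in dB with peak 1.0; ``inf`` when identical."""
    if ref.shape != test.shape:
        raise ValueError(f"dimension mismatch: {ref.shape} vs {test.shape}")
    mse = float(np.mean((ref.pixels - test.pixels) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def ssim(ref: Image, test: Image) -> float:
    """Mean local SSIM, standard reference parameterization.

    Gaussian window (sigma 1.5, 11x11), K1 = 0.01, K2 = 0.03, dynamic range 1.0.
    """
    from skimage.metrics import structural_similarity

    if ref.shape != test.shape:
        raise ValueError(f"dimension mismatch: {ref.shape} vs {test.shape}")
    if min(ref.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            ref.pixels,
            test.pixels,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def metrics(ref: Image, test: Image) -> QualityMetrics:
    return QualityMetrics(psnr_db=psnr(ref, test), ssim=ssim(ref, test))


# ---------------------------------------------------------------------------
# patch geometry


def _grid_1d(size: int, patch: int, stride: int) -> np.ndarray:
    """Stride-grid anchors plus one flush-to-border anchor when needed."""
    anchors = list(range(0, size - patch + 1, stride))
    if anchors[-1] != size - patch:
        anchors.append(size - patch)
    return np.asarray(anchors, dtype=np.intp)


def patch_grid(height: int, width: int, patch: int = 3, stride: int = 2) -> np.ndarray:
    """All (row, col) anchors of the dense overlapping patch grid."""
    rows = _grid_1d(height, patch, stride)
    cols = _grid_1d(width, patch, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def extract_patches(pixels: np.ndarray, positions: np.ndarray, patch: int) -> np.ndarray:
    """Vectorized patches as columns of an (patch^2, N) matrix."""
    windows = sliding_window_view(pixels, (patch, patch))
    pats = windows[positions[:, 0], positions[:, 1]]  # (N, patch, patch)
    return pats.reshape(len(positions), patch * patch).T


def extract_training_patches(pair: ImagePair) -> PatchPairSet:
    """Dense 3x3/stride-2 LR patches paired with 3Mx3M HR patches at Mx anchors.

    The LR patch's DC mean is removed from both vectors of a pair and kept in
    ``lr_means``; trailing rows/cols not hit by the stride grid are covered by
    one extra patch flush with the border.
    """
    m = pair.factor
    lp, ls = 3, 2
    lr_px, hr_px = pair.lr.pixels, pair.hr.pixels
    if pair.lr.height < lp or pair.lr.width < lp:
        raise ValueError("LR image smaller than the 3x3 patch")
    pos = patch_grid(pair.lr.height, pair.lr.width, lp, ls)
    x_l = extract_patches(lr_px, pos, lp)
    x_h = extract_patches(hr_px, pos * m, lp * m)
    means = x_l.mean(axis=0)
    return PatchPairSet(
        X_l=x_l - means,
        X_h=x_h - means,
        positions=pos,
        lr_means=means,
        factor=m,
        lr_patch_size=lp,
        lr_stride=ls,
    )


def concatenate_patch_sets(sets: list[PatchPairSet]) -> PatchPairSet:
    """Pool patch pairs from several images into one training set."""
    if not sets:
        raise ValueError("no patch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.factor != first.factor or s.lr_patch_size != first.lr_patch_size:
            raise ValueError("patch sets with mismatched geometry")
    return PatchPairSet(
        X_l=np.concatenate([s.X_l for s in sets], axis=1),
        X_h=np.concatenate([s.X_h for s in sets], axis=1),
        positions=np.concatenate([s.positions for s in sets], axis=0),
        lr_means=np.concatenate([s.lr_means for s in sets]),
        factor=first.factor,
        lr_patch_size=first.lr_patch_size,
        lr_stride=first.lr_stride,
    )


def assemble_image(
    patches: np.ndarray,
    positions: np.ndarray,
    lr_means: np.ndarray,
    out_shape: tuple[int, int],
    factor: int,
) -> Image:
    """Overlap-average vectorized HR patches back into an image.

    Each column gets its stored DC mean re-added, lands at ``factor`` times its
    LR anchor, and overlapping pixels are averaged with equal weights; the
    result is clipped to [0, 1].
    """
    s_h, n = patches.shape
    hp = int(round(np.sqrt(s_h)))
    if hp * hp != s_h:
        raise ValueError("patch vectors must be square patches")
    acc = np.zeros(out_shape)
    cnt = np.zeros(out_shape)
    pats = (patches + lr_means[None, :]).T.reshape(n, hp, hp)
    for (r, c), p in zip(positions * factor, pats):
        acc[r : r + hp, c : c + hp] += p
        cnt[r : r + hp, c : c + hp] += 1.0
    if (cnt == 0).any():
        r, c = np.argwhere(cnt == 0)[0]
        raise ValueError(f"output pixel ({r}, {c}) covered by no patch")
    return Image(np.clip(acc / cnt, 0.0, 1.0))
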