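"""Paired LR/HR grayscale data: phantoms, bicubic degradation, augmentation, I/O.

Everything downstream of this module consumes :class:`ImageGray`, a 2-D
float image canonicalized to [0, 1].  Synthetic short-axis cardiac phantoms
stand in for real cine MR acquisitions so the whole pipeline is exercisable
without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import FormatError, IOPathError, ParameterError, ShapeError

__all__ = [
    "ImageGray",
    "PhantomParams",
    "PatchPair",
    "generate_phantom",
    "phantom_corpus",
    "bicubic_resize",
    "augment_corpus",
    "extract_patch_pairs",
    "load_image",
    "load_images",
    "load_manifest",
    "save_image",
]

#: BT.601 luma weights used to collapse RGB inputs to one channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Augmentation grid: scales are the outer loop, rotations the inner loop.
AUGMENT_SCALES = (1.0, 0.9, 0.8, 0.7)
AUGMENT_ROTATIONS = (0, 1, 2, 3)  # multiples of 90 degrees, CCW


@dataclass(frozen=True)
class ImageGray:
    """Canonical 2-D grayscale image with values in [0, 1].

    Parameters
    ----------
    pixels : ndarray
        2-D float array; values must be finite and inside [0, 1].
    source_depth : int
        Bits per sample of the originating format (8 or 16).
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ShapeError(f"ImageGray expects a 2-D array, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ParameterError("ImageGray pixels must be finite")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ParameterError(
                f"ImageGray pixels outside [0,1]: min={px.min():.4g} max={px.max():.4g}"
            )
        if self.source_depth not in (8, 16):
            raise ParameterError(f"source_depth must be 8 or 16, got {self.source_depth}")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def quantized(self) -> np.ndarray:
        """Pixels rounded onto the integer grid of ``source_depth`` bits."""
        levels = 2**self.source_depth - 1
        return np.rint(self.pixels * levels)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry/appearance parameters for one synthetic short-axis phantom."""

    seed: int = 0
    size: int = 128
    ring_center: tuple[float, float] = (0.5, 0.5)
    outer_radius: float = 0.30
    inner_radius: float = 0.18
    blood_intensity: float = 0.9
    myocardium_intensity: float = 0.35
    background_intensity: float = 0.15
    texture_amplitude: float = 0.05
    noise_sigma: float = 0.01
    rician: bool = False

    def __post_init__(self):
        if not (0.0 < self.inner_radius < self.outer_radius < 0.5):
            raise ParameterError(
                "radii must satisfy 0 < inner_radius < outer_radius < 0.5 "
                f"(got inner={self.inner_radius}, outer={self.outer_radius})"
            )
        if self.blood_intensity <= self.myocardium_intensity:
            raise ParameterError("bright-blood convention requires blood > myocardium")
        for name in ("blood_intensity", "myocardium_intensity", "background_intensity",
                     "texture_amplitude"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0,1], got {v}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.size < 8:
            raise ParameterError("phantom size must be >= 8")


@dataclass(frozen=True)
class PatchPair:
    """One aligned LR/HR training patch; hr is exactly ``scale`` x lr."""

    lr: ImageGray
    hr: ImageGray
    scale: int
    hr_origin: tuple[int, int]

    def __post_init__(self):
        if (self.hr.height, self.hr.width) != (
            self.scale * self.lr.height,
            self.scale * self.lr.width,
        ):
            raise ShapeError("hr patch dimensions must equal scale x lr dimensions")
        if self.hr_origin[0] % self.scale or self.hr_origin[1] % self.scale:
            raise ShapeError("hr_origin must be a multiple of scale in both coordinates")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams) -> ImageGray:
    """Render one synthetic short-axis cardiac phantom.

    A bright elliptical blood pool sits inside a darker myocardial ring over a
    textured background; smooth multiplicative texture and additive noise are
    drawn from independent, seed-derived streams so that disabling one leaves
    the other untouched.
    """
    n = params.size
    # pixel centres in units of the image side
    coords = (np.arange(n) + 0.5) / n
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    dr = rr - params.ring_center[0]
    dc = cc - params.ring_center[1]
    rho = np.sqrt(dr * dr + dc * dc)

    img = np.full((n, n), params.background_intensity, dtype=np.float64)
    img[rho < params.outer_radius] = params.myocardium_intensity
    img[rho < params.inner_radius] = params.blood_intensity

    if params.texture_amplitude > 0:
        tex_rng = np.random.default_rng([params.seed, 1])
        field = tex_rng.standard_normal((n, n))
        # low-pass the field so the texture is smooth at roughly 1/8 image scale
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(field, sigma=max(n / 32.0, 1.0), mode="reflect")
        peak = np.abs(field).max()
        if peak > 0:
            field /= peak
        img = img + params.texture_amplitude * field

    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng([params.seed, 2])
        if params.rician:
            re = img + params.noise_sigma * noise_rng.standard_normal((n, n))
            im = params.noise_sigma * noise_rng.standard_normal((n, n))
            img = np.sqrt(re * re + im * im)
        else:
            img = img + params.noise_sigma * noise_rng.standard_normal((n, n))

    return ImageGray(np.clip(img, 0.0, 1.0))


def phantom_corpus(n_images: int, size: int, seed: int) -> list[ImageGray]:
    """Generate ``n_images`` phantoms with seed-derived varied geometry."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        outer = rng.uniform(0.22, 0.38)
        inner = outer * rng.uniform(0.45, 0.75)
        p = PhantomParams(
            seed=int(rng.integers(0, 2**31 - 1)),
            size=size,
            ring_center=(rng.uniform(0.4, 0.6), rng.uniform(0.4, 0.6)),
            outer_radius=float(outer),
            inner_radius=float(inner),
            blood_intensity=float(rng.uniform(0.75, 0.95)),
            myocardium_intensity=float(rng.uniform(0.25, 0.45)),
            background_intensity=float(rng.uniform(0.05, 0.2)),
            texture_amplitude=float(rng.uniform(0.02, 0.08)),
            noise_sigma=float(rng.uniform(0.005, 0.02)),
        )
        out.append(generate_phantom(p))
    return out


# ---------------------------------------------------------------------------
# bicubic resampling
# ---------------------------------------------------------------------------

def _cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Separable cubic interpolation kernel (Catmull-Rom family, a = -0.5)."""
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax <= 1
    m2 = (ax > 1) & (ax < 2)
    out[m1] = (a + 2) * ax[m1] ** 3 - (a + 3) * ax[m1] ** 2 + 1
    out[m2] = a * ax[m2] ** 3 - 5 * a * ax[m2] ** 2 + 8 * a * ax[m2] - 4 * a
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) bicubic interpolation matrix with reflect padding."""
    factor = n_out / n_in
    dst = np.arange(n_out)
    src = (dst + 0.5) / factor - 0.5  # align pixel centres
    base = np.floor(src).astype(int)
    frac = src - base
    mat = np.zeros((n_out, n_in))
    for tap in range(-1, 3):
        idx = base + tap
        w = _cubic_kernel(frac - tap)
        # reflect indices into range (symmetric, edge pixels not repeated twice
        # beyond the mirror: classic 'reflect' on pixel centres)
        idx = np.abs(idx)
        idx = np.where(idx >= n_in, 2 * (n_in - 1) - idx, idx)
        idx = np.clip(idx, 0, n_in - 1)
        np.add.at(mat, (dst, idx), w)
    return mat


def bicubic_resize(img: ImageGray, factor: float) -> ImageGray:
    """Separable bicubic resampling by ``factor`` (Catmull-Rom kernel, a=-0.5).

    Output dimensions are ``round(dim * factor)`` with round-half-away-from-zero;
    borders use reflect padding; the result is clipped back to [0, 1].
    """
    if factor <= 0:
        raise ParameterError(f"resize factor must be positive, got {factor}")
    h_out = _round_half_away(img.height * factor)
    w_out = _round_half_away(img.width * factor)
    if h_out < 1 or w_out < 1:
        raise ParameterError("resize output dimensions must be >= 1")
    rows = _resize_matrix(img.height, h_out)
    cols = _resize_matrix(img.width, w_out)
    out = rows @ img.pixels @ cols.T
    return ImageGray(np.clip(out, 0.0, 1.0), source_depth=img.source_depth)


# ---------------------------------------------------------------------------
# augmentation & patch extraction
# ---------------------------------------------------------------------------

def augment_corpus(images: Sequence[ImageGray]) -> list[ImageGray]:
    """Expand a corpus 16x: {identity, rot90, rot180, rot270} x {1.0, 0.9, 0.8, 0.7}.

    Emission order is deterministic: input order outermost, then scales, then
    rotations innermost.  Scaling uses :func:`bicubic_resize`.
    """
    out: list[ImageGray] = []
    for img in images:
        for scale in AUGMENT_SCALES:
            scaled = img if scale == 1.0 else bicubic_resize(img, scale)
            for k in AUGMENT_ROTATIONS:
                if k == 0:
                    out.append(scaled)
                else:
                    out.append(
                        ImageGray(np.rot90(scaled.pixels, k).copy(), scaled.source_depth)
                    )
    return out


def extract_patch_pairs(
    hr: ImageGray, scale: int, lr_patch: int, stride: int
) -> list[PatchPair]:
    """Tile an HR image into aligned LR/HR patch pairs.

    The HR image is first cropped to the largest size divisible by ``scale``;
    the LR image is its bicubic downscale by ``1/scale``; patches tile the LR
    grid row-major at ``stride`` and each HR patch is the co-located
    ``scale * lr_patch`` square.
    """
    if scale < 1 or lr_patch < 1 or stride < 1:
        raise ParameterError("scale, lr_patch and stride must be positive")
    h = (hr.height // scale) * scale
    w = (hr.width // scale) * scale
    if h == 0 or w == 0:
        return []
    cropped = ImageGray(hr.pixels[:h, :w], hr.source_depth)
    lr = bicubic_resize(cropped, 1.0 / scale)
    hl, wl = lr.height, lr.width
    if lr_patch > hl or lr_patch > wl:
        return []
    pairs = []
    for r in range(0, hl - lr_patch + 1, stride):
        for c in range(0, wl - lr_patch + 1, stride):
            lp = ImageGray(lr.pixels[r : r + lr_patch, c : c + lr_patch], hr.source_depth)
            hr0 = (r * scale, c * scale)
            hp = ImageGray(
                cropped.pixels[
                    hr0[0] : hr0[0] + scale * lr_patch,
                    hr0[1] : hr0[1] + scale * lr_patch,
                ],
                hr.source_depth,
            )
            pairs.append(PatchPair(lr=lp, hr=hp, scale=scale, hr_origin=hr0))
    return pairs


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _from_array(arr: np.ndarray, depth: int) -> ImageGray:
    return ImageGray(arr.astype(np.float64) / (2**depth - 1), source_depth=depth)


def load_images(path: str | Path) -> list[ImageGray]:
    """Load a PNG (one image) or a NIfTI volume (one image per axial slice)."""
    path = Path(path)
    if not path.exists():
        raise IOPathError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".png"):
        return [_load_png(path)]
    if suffixes.endswith((".nii", ".nii.gz")):
        return _load_nifti(path)
    raise FormatError(f"unsupported image extension: {path}")


def load_manifest(path: str | Path) -> list[ImageGray]:
    """Load every image listed (one path per line) in a plain-text manifest.

    Relative entries are resolved against the manifest's directory; blank
    lines and ``#`` comments are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise IOPathError(f"no such manifest: {path}")
    out: list[ImageGray] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        entry = Path(line)
        if not entry.is_absolute():
            entry = path.parent / entry
        out.extend(load_images(entry))
    return out


def load_image(path: str | Path) -> ImageGray:
    """Load a single image; a multi-slice NIfTI volume is an error here."""
    imgs = load_images(path)
    if len(imgs) != 1:
        raise FormatError(f"{path} holds {len(imgs)} slices; use load_images")
    return imgs[0]


def _load_png(path: Path) -> ImageGray:
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("I;16", "I;16B", "I"):
                arr = np.asarray(im, dtype=np.float64)
                return _from_array(arr, 16)
            if mode == "L":
                return _from_array(np.asarray(im, dtype=np.float64), 8)
            if mode in ("RGB", "RGBA"):
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                luma = (
                    LUMA_WEIGHTS[0] * rgb[..., 0]
                    + LUMA_WEIGHTS[1] * rgb[..., 1]
                    + LUMA_WEIGHTS[2] * rgb[..., 2]
                )
                return ImageGray(luma / 255.0, source_depth=8)
            return _from_array(np.asarray(im.convert("L"), dtype=np.float64), 8)
    except OSError as exc:
        raise IOPathError(f"cannot read PNG {path}: {exc}") from exc


def _load_nifti(path: Path) -> list[ImageGray]:
    import nibabel as nib

    try:
        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises several exception types
        raise IOPathError(f"cannot read NIfTI {path}: {exc}") from exc
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise FormatError(f"NIfTI volume must be 2-D or 3-D, got ndim={vol.ndim}")
    lo, hi = float(vol.min()), float(vol.max())
    scale = hi - lo
    if scale == 0:
        scale = 1.0
    return [
        ImageGray((vol[:, :, k] - lo) / scale, source_depth=16)
        for k in range(vol.shape[2])
    ]


def save_image(img: ImageGray, path: str | Path, depth: int = 8) -> None:
    """Write an ImageGray as an 8- or 16-bit grayscale PNG."""
    if depth not in (8, 16):
        raise ParameterError(f"depth must be 8 or 16, got {depth}")
    path = Path(path)
    levels = 2**depth - 1
    arr = np.rint(np.clip(img.pixels, 0, 1) * levels)
    try:
        if depth == 8:
            Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
        else:
            Image.fromarray(arr.astype(np.uint16)).save(path)
    except OSError as exc:
        raise IOPathError(f"cannot write PNG {path}: {exc}") from exc
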