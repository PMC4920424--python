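"""Global appearance descriptors for elytra fragments (210 elements).

Five descriptor families summarize a whole fragment and are concatenated in
a fixed order:

==============================  ======  ==========================================
family                          length  content
==============================  ======  ==========================================
statistical (spatial texture)   13      histogram statistics + 7 Hu moments
radial spectra                  80      radial sums of the centred FFT magnitude,
                                        radii r = 1..80, dc excluded
colour                          30      10-bin RGB histograms, per-channel sum 1
Gabor                           19      sum/mean/std of 6 oriented responses +
                                        max-response angle
key objects (hair/hole/line)    68      per DoG polarity: 30-bin colour histogram
                                        over segmented object pixels, number and
                                        area density, mean and median object size
==============================  ======  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import fft2, ifft2
from skimage import filters, measure, transform

from .segment import FragmentImage

LUMA = np.array([0.2125, 0.7154, 0.0721])

N_STATISTICAL = 13
N_SPECTRA = 80
N_COLOR = 30
N_GABOR = 19
N_KEY_OBJECT = 68
N_GLOBAL = N_STATISTICAL + N_SPECTRA + N_COLOR + N_GABOR + N_KEY_OBJECT


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luma grayscale in [0, 255] (float)."""
    return np.asarray(rgb, dtype=float) @ LUMA


def _as_rgb(fragment) -> np.ndarray:
    if isinstance(fragment, FragmentImage):
        return np.asarray(fragment.pixels)
    return np.asarray(fragment)


@dataclass(frozen=True)
class GaborBankConfig:
    """Oriented complex Gabor bank: 6 orientations, 0 <= theta < 180 in 30-deg steps.

    ``lambda_px`` is the sinusoidal wavelength, ``sigma`` the Gaussian
    envelope scale, ``gamma`` the spatial aspect ratio and ``psi`` the phase
    offset; the kernel is sampled on a square ``kernel_size`` grid.
    """

    orientations_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    lambda_px: float = 8.0
    sigma: float = 4.0
    gamma: float = 0.5
    psi: float = 0.0
    kernel_size: int = 31

    def __post_init__(self) -> None:
        if len(self.orientations_deg) != 6:
            raise ValueError("the bank uses exactly 6 orientations")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


@dataclass(frozen=True)
class DoGConfig:
    """Difference-of-Gaussian variances; the default scales are 100 and 1."""

    variance_large: float = 100.0
    variance_small: float = 1.0

    def __post_init__(self) -> None:
        if not self.variance_large > self.variance_small > 0:
            raise ValueError("need variance_large > variance_small > 0")


# ---------------------------------------------------------------------------
# statistical features

STATISTICAL_NAMES = (
    ["stat_mean", "stat_std", "stat_uniformity", "stat_entropy",
     "stat_smoothness", "stat_third_moment"]
    + [f"stat_hu{i}" for i in range(1, 8)]
)


def statistical_features(gray: np.ndarray) -> np.ndarray:
    """13 spatial-texture statistics of a grayscale image.

    Mean and standard deviation are on the raw [0, 255] intensity scale.
    Uniformity, entropy (bits), smoothness and the third moment come from
    the 256-bin normalized histogram p(z), with z rescaled to [0, 1] for
    the moment-based measures (so smoothness lies in [0, 1)).  The last
    seven entries are the Hu moment invariants of the intensity image.
    """
    g = np.asarray(gray, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    vals = np.clip(np.rint(g), 0, 255).astype(int)
    p = np.bincount(vals.ravel(), minlength=256).astype(float)
    p /= p.sum()
    z = np.arange(256) / 255.0
    mz = (z * p).sum()
    var_z = ((z - mz) ** 2 * p).sum()
    nz = p > 0
    features = [
        (np.arange(256) * p).sum(),            # mean intensity
        np.sqrt(var_z) * 255.0,                # std, intensity units
        (p ** 2).sum(),                        # uniformity
        float(-(p[nz] * np.log2(p[nz])).sum()),  # entropy (bits)
        1.0 - 1.0 / (1.0 + var_z),             # smoothness
        ((z - mz) ** 3 * p).sum(),             # third moment (skewness)
    ]
    mu = measure.moments_central(g)
    hu = measure.moments_hu(measure.moments_normalized(mu))
    return np.concatenate([features, hu])


# ---------------------------------------------------------------------------
# radial spectra

SPECTRA_NAMES = [f"spec_r{r:03d}" for r in range(1, N_SPECTRA + 1)]


def spectra_features(gray: np.ndarray, resample: tuple[int, int] | None = (256, 256)) -> np.ndarray:
    """Radial sums of the centred 2-D FFT magnitude for radii 1..80.

    The image is bilinearly resampled to a fixed size so that radii are
    comparable across fragments of different sizes, then the magnitude of
    the centred spectrum (Euclidean norm of real and imaginary parts) is
    summed over frequency coordinates whose distance from the origin rounds
    to each integer radius.  The dc component (r = 0) is excluded.
    """
    g = np.asarray(gray, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    if resample is not None and g.shape != tuple(resample):
        g = transform.resize(g, resample, order=1, anti_aliasing=False,
                             preserve_range=True)
    mag = np.abs(np.fft.fftshift(fft2(g)))
    h, w = g.shape
    u = np.arange(h) - h // 2
    v = np.arange(w) - w // 2
    r = np.rint(np.hypot(u[:, None], v[None, :])).astype(int)
    sums = np.bincount(r.ravel(), weights=mag.ravel(),
                       minlength=N_SPECTRA + 1)
    out = np.zeros(N_SPECTRA)
    avail = min(N_SPECTRA, sums.size - 1)
    out[:avail] = sums[1:avail + 1]
    return out


# ---------------------------------------------------------------------------
# colour histogram

COLOR_NAMES = [f"col_{ch}{b:02d}" for ch in "RGB" for b in range(1, 11)]


def _channel_histogram(values: np.ndarray, bins: int) -> np.ndarray:
    hist, _ = np.histogram(values, bins=bins, range=(0, 256))
    total = hist.sum()
    return hist / total if total else hist.astype(float)


def color_features(rgb: np.ndarray, bins: int = 10) -> np.ndarray:
    """Concatenated per-channel RGB histograms, each normalized to sum 1."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    return np.concatenate([
        _channel_histogram(arr[..., ch].ravel(), bins) for ch in range(3)
    ])


# ---------------------------------------------------------------------------
# Gabor

GABOR_NAMES = (
    [f"gab_{stat}{int(th):03d}"
     for th in (0, 30, 60, 90, 120, 150)
     for stat in ("sum", "mean", "std")]
    + ["gab_max_angle"]
)


def gabor_kernel(theta_deg: float, cfg: GaborBankConfig) -> np.ndarray:
    """Complex oriented Gabor kernel.

    G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) exp(i(2 pi x'/lambda + psi))
    with x' = x cos(theta) + y sin(theta), x along columns and y along rows,
    so theta = 0 responds maximally to vertical stripes (variation along x).
    """
    half = cfg.kernel_size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    th = np.deg2rad(theta_deg)
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    envelope = np.exp(-(xp ** 2 + cfg.gamma ** 2 * yp ** 2) / (2.0 * cfg.sigma ** 2))
    carrier = np.exp(1j * (2.0 * np.pi * xp / cfg.lambda_px + cfg.psi))
    return envelope * carrier


def _fft_convolve_reflect(gray: np.ndarray, kernels: list[np.ndarray]) -> list[np.ndarray]:
    """Convolve with several same-sized complex kernels, reflect boundary.

    The padded image is transformed once; each kernel costs one forward and
    one inverse FFT.
    """
    half = kernels[0].shape[0] // 2
    gp = np.pad(np.asarray(gray, dtype=float), half, mode="reflect")
    H, W = gp.shape
    Fimg = fft2(gp)
    out = []
    for k in kernels:
        kp = np.zeros((H, W), dtype=complex)
        ks = k.shape[0]
        kp[:ks, :ks] = k
        kp = np.roll(kp, (-half, -half), axis=(0, 1))
        resp = ifft2(Fimg * fft2(kp))
        out.append(resp[half:H - half, half:W - half])
    return out


def gabor_features(gray: np.ndarray, bank: GaborBankConfig | None = None) -> np.ndarray:
    """19-element oriented-edge descriptor.

    For each of the six orientations the image is convolved with the complex
    Gabor kernel and the pixelwise response magnitude is summarized by its
    sum, mean and standard deviation; the final element is the orientation
    (degrees) of the greatest summed response.
    """
    if bank is None:
        bank = GaborBankConfig()
    g = np.asarray(gray, dtype=float)
    if min(g.shape) < bank.kernel_size:
        raise ValueError("image must be at least as large as the Gabor kernel")
    kernels = [gabor_kernel(th, bank) for th in bank.orientations_deg]
    responses = _fft_convolve_reflect(g, kernels)
    out = []
    sums = []
    for resp in responses:
        mag = np.abs(resp)
        s = mag.sum()
        sums.append(s)
        out.extend([s, mag.mean(), mag.std()])
    out.append(bank.orientations_deg[int(np.argmax(sums))])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# key objects (hair/hole/line) via Difference-of-Gaussian

KEY_OBJECT_NAMES = [
    f"dog_{pol}_{name}"
    for pol in ("sl", "ls")  # small-minus-large blur, and the reverse
    for name in ([f"col_{ch}{b:02d}" for ch in "RGB" for b in range(1, 11)]
                 + ["number_density", "area_density", "mean_size", "median_size"])
]


def _rescale_255(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def _polarity_features(dog: np.ndarray, rgb: np.ndarray, otsu_gray: float | None) -> np.ndarray:
    scaled = _rescale_255(dog)
    if otsu_gray is None or scaled.max() == scaled.min():
        binary = np.zeros(dog.shape, dtype=bool)
    else:
        thr = (otsu_gray + float(filters.threshold_otsu(scaled))) / 2.0
        binary = scaled > thr
    labels, n_objects = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    npx = dog.size
    if n_objects == 0:
        return np.zeros(34)
    sizes = np.bincount(labels.ravel())[1:]
    obj_pixels = rgb[binary]
    hist = np.concatenate([
        _channel_histogram(obj_pixels[:, ch], 10) for ch in range(3)
    ])
    return np.concatenate([hist, [
        n_objects / npx,
        binary.sum() / npx,
        float(sizes.mean()),
        float(np.median(sizes)),
    ]])


def key_object_features(rgb: np.ndarray, gray: np.ndarray | None = None,
                        cfg: DoGConfig | None = None) -> np.ndarray:
    """68-element hair/hole/line descriptor from two DoG polarities.

    The grayscale image is blurred at the two DoG scales; both differences
    (less-blurred minus largely-blurred, and the reverse) are rescaled to
    [0, 255] and binarized at the mean of the Otsu thresholds of the
    original grayscale image and of the rescaled DoG image.  Connected
    components (8-connectivity) are the key objects; each polarity emits a
    30-bin RGB histogram over object pixels, number and area densities and
    the mean and median object pixel size.  With no objects the 34 entries
    for that polarity are zero.
    """
    if cfg is None:
        cfg = DoGConfig()
    arr = np.asarray(rgb)
    if gray is None:
        gray = to_gray(arr)
    g = np.asarray(gray, dtype=float)
    s1 = np.sqrt(cfg.variance_large)
    s2 = np.sqrt(cfg.variance_small)
    large = ndimage.gaussian_filter(g, s1, truncate=3.0)
    small = ndimage.gaussian_filter(g, s2, truncate=3.0)
    d_sl = small - large
    otsu_gray = None
    if g.max() > g.min():
        otsu_gray = float(filters.threshold_otsu(np.clip(np.rint(g), 0, 255)))
    return np.concatenate([
        _polarity_features(d_sl, arr, otsu_gray),
        _polarity_features(-d_sl, arr, otsu_gray),
    ])


# ---------------------------------------------------------------------------
# concatenation

GLOBAL_NAMES = (STATISTICAL_NAMES + SPECTRA_NAMES + COLOR_NAMES
                + GABOR_NAMES + KEY_OBJECT_NAMES)
assert len(GLOBAL_NAMES) == N_GLOBAL


def global_features(fragment, bank: GaborBankConfig | None = None,
                    dog: DoGConfig | None = None,
                    resample: tuple[int, int] | None = (256, 256)) -> pd.Series:
    """The 210-element global feature vector of a (preprocessed) fragment.

    Fixed concatenation order: statistical (13), spectra (80), colour (30),
    Gabor (19), key objects (68).  Returns a named pandas Series.
    """
    rgb = _as_rgb(fragment)
    gray = to_gray(rgb)
    vec = np.concatenate([
        statistical_features(gray),
        spectra_features(gray, resample),
        color_features(rgb),
        gabor_features(gray, bank),
        key_object_features(rgb, gray, dog),
    ])
    return pd.Series(vec, index=GLOBAL_NAMES)


class GlobalFeatureExtractor:
    """Sklearn-style transformer mapping fragments to the 210-column matrix."""

    def __init__(self, bank: GaborBankConfig | None = None,
                 dog: DoGConfig | None = None,
                 resample: tuple[int, int] | None = (256, 256)):
        self.bank = bank
        self.dog = dog
        self.resample = resample

    def get_params(self, deep: bool = True) -> dict:
        return {"bank": self.bank, "dog": self.dog, "resample": self.resample}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):  # stateless
        self.feature_names_out_ = list(GLOBAL_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [global_features(frag, self.bank, self.dog, self.resample) for frag in X]
        return pd.DataFrame(rows).reset_index(drop=True)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
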