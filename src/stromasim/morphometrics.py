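"""Image-side quantification.

Wrinkle ridge extraction and the wrinkle index, FFT-feature stump-ensemble
wavelength importance, pairwise orientation alignment percentage,
focal-adhesion polarity, and ratiometric FRET images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "ImageStack",
    "WrinkleLine",
    "SpectralFeatures",
    "WavelengthImportanceResult",
    "fit_wrinkle_line",
    "wrinkle_index",
    "line_spectrum",
    "wavelength_importance",
    "alignment_percentage",
    "polarity",
    "fret_ratio_image",
]


@dataclass
class ImageStack:
    """Grayscale stack: axis 0 slices (y), axis 1 depth (z), axis 2 width (x)."""

    data: np.ndarray
    pixel_size: float = 1.0  # um / px
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, ...]
        if self.data.ndim != 3:
            raise ValueError("ImageStack expects a 2D slice or 3D (y, z, x) stack")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def depth(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


@dataclass
class WrinkleLine:
    """Single-valued ridge polyline: one z per x column."""

    z: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if len(self.z) < 2:
            raise ValueError("a ridge line needs at least two columns")

    @property
    def width(self) -> int:
        return len(self.z)

    def arc_length(self) -> float:
        """Polyline length in pixels (unit x spacing)."""
        dz = np.diff(self.z)
        return float(np.sum(np.sqrt(1.0 + dz**2)))


@dataclass
class SpectralFeatures:
    """One-sided FFT magnitude spectra of ridge lines with class labels."""

    spectra: np.ndarray  # (n_lines, width // 2 + 1)
    labels: np.ndarray
    width: int

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.spectra.shape[1] != self.width // 2 + 1:
            raise ValueError("spectrum length must be width // 2 + 1")


class EmptySliceError(ValueError):
    """A slice contains no foreground after binarisation."""


def _subpixel_refine(col: np.ndarray, k: int) -> float:
    """Parabolic (log-domain) refinement of a peak index.

    Exact for a Gaussian intensity cross-section; clipped to +-0.5 px.
    """
    if k <= 0 or k >= len(col) - 1:
        return float(k)
    lo, mid, hi = col[k - 1], col[k], col[k + 1]
    if lo <= 0 or hi <= 0 or mid <= 0:
        return float(k)
    lo, mid, hi = np.log(lo), np.log(mid), np.log(hi)
    denom = lo - 2.0 * mid + hi
    if denom >= 0:
        return float(k)
    return float(k + np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))


def fit_wrinkle_line(
    stack: ImageStack, threshold: float | None = None, subpixel: bool = True
) -> list[WrinkleLine]:
    """Extract one ridge polyline per y-slice.

    Each slice is binarised (Otsu by default, threshold overridable); per x
    column the strongest intensity peak along z is taken (ties break toward
    the smaller z index), optionally refined to sub-pixel precision, and
    the per-column values are connected along x.  Columns without a peak
    are linearly interpolated from their neighbours.  An all-background
    slice raises :class:`EmptySliceError`.
    """
    lines = []
    for s in range(stack.n_slices):
        img = np.asarray(stack.data[s], dtype=float)
        thr = threshold_otsu(img) if threshold is None else threshold
        fg = img > thr
        if not fg.any():
            raise EmptySliceError(f"slice {s} is entirely background")
        width = img.shape[1]
        z = np.full(width, np.nan)
        for x in range(width):
            col = np.where(fg[:, x], img[:, x], 0.0)
            peaks, _ = find_peaks(np.concatenate([[0.0], col, [0.0]]))
            peaks -= 1
            if len(peaks) == 0:
                continue
            # strongest peak; np.argmax takes the first (smallest z) on ties
            k = int(peaks[np.argmax(col[peaks])])
            z[x] = _subpixel_refine(img[:, x], k) if subpixel else k
        if np.all(np.isnan(z)):
            raise EmptySliceError(f"slice {s} has no ridge peaks")
        missing = np.isnan(z)
        if missing.any():
            xs = np.arange(width)
            z[missing] = np.interp(xs[missing], xs[~missing], z[~missing])
        lines.append(WrinkleLine(z, pixel_size=stack.pixel_size))
    return lines


def wrinkle_index(line: WrinkleLine) -> float:
    """Ridge arc length divided by the straight projection width.

    1.0 for a flat ridge, larger for wrinkled ones.
    """
    return line.arc_length() / (line.width - 1)


def line_spectrum(line: WrinkleLine) -> np.ndarray:
    """One-sided FFT magnitude spectrum of a ridge line (no windowing)."""
    return np.abs(np.fft.rfft(line.z))


@dataclass
class WavelengthImportanceResult:
    """Per-wavelength feature importance and held-out accuracy."""

    frequency_index: np.ndarray
    wavelength_px: np.ndarray
    wavelength_um: np.ndarray
    importance: np.ndarray
    accuracy: float
    model: RandomForestClassifier = field(repr=False, default=None)

    def top_wavelengths(self, k: int = 2) -> np.ndarray:
        order = np.argsort(self.importance)[::-1]
        return self.wavelength_px[order[:k]]


def wavelength_importance(
    features: SpectralFeatures,
    pixel_size: float = 1.0,
    seed: int = 0,
    n_splits: int = 5,
) -> WavelengthImportanceResult:
    """Stump-ensemble classification of ridge spectra by wavelength.

    An ensemble of 100 depth-1 trees is trained on the one-sided FFT
    magnitudes; feature importances are re-indexed by wavelength
    (width / frequency index, in px and um) and accuracy is estimated by
    stratified k-fold cross-validation with a fixed seed.
    """
    labels = np.asarray(features.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("wavelength importance needs at least two classes")
    counts = min(np.sum(labels == c) for c in classes)
    if counts < n_splits:
        raise ValueError(f"need at least {n_splits} lines per class")
    X = features.spectra
    y = labels
    clf = RandomForestClassifier(n_estimators=100, max_depth=1, random_state=seed)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accuracy = float(cross_val_score(clf, X, y, cv=cv).mean())
    clf.fit(X, y)
    idx = np.arange(X.shape[1])
    with np.errstate(divide="ignore"):
        wl_px = np.where(idx > 0, features.width / np.maximum(idx, 1), np.inf)
    return WavelengthImportanceResult(
        frequency_index=idx,
        wavelength_px=wl_px,
        wavelength_um=wl_px * pixel_size,
        importance=clf.feature_importances_,
        accuracy=accuracy,
        model=clf,
    )


def alignment_percentage(
    orientation_a: float, orientation_b: float, axial: bool = False
) -> float:
    """Percent alignment ``(1 - D / 180) * 100`` of two orientations (deg).

    ``D`` is the absolute orientation difference folded into [0, 180].
    With ``axial=True`` the difference folds at 90 deg instead (undirected
    orientations), keeping the printed 180 denominator.
    """
    d = abs(float(orientation_a) - float(orientation_b)) % 360.0
    d = min(d, 360.0 - d)
    if axial:
        d = min(d, 180.0 - d)
    return (1.0 - d / 180.0) * 100.0


def polarity(pax_whole: float, pax_dapi: float) -> float:
    """Peripheral-signal polarity ``(whole - center) / center``."""
    if pax_dapi <= 0:
        raise ValueError("central (DAPI-region) intensity must be positive")
    return (float(pax_whole) - float(pax_dapi)) / float(pax_dapi)


def fret_ratio_image(
    da: np.ndarray, dd: np.ndarray, floor: float | None = None
) -> np.ma.MaskedArray:
    """Pixel-wise acceptor/donor ratio ``DA / DD``.

    Pixels with donor signal at or below ``floor`` (default: 1e-6 of the
    donor maximum) are masked.
    """
    da = np.asarray(da, dtype=float)
    dd = np.asarray(dd, dtype=float)
    if da.shape != dd.shape:
        raise ValueError("DA and DD images must have identical shapes")
    if floor is None:
        floor = 1e-6 * (dd.max() if dd.size else 1.0)
    mask = dd <= floor
    ratio = np.divide(da, dd, out=np.zeros_like(da), where=~mask)
    return np.ma.MaskedArray(ratio, mask=mask)
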