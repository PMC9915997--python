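"""Synthetic stand-ins for microscope data.

Every generator takes an explicit seed, returns its own ground truth, and
can write 16-bit grayscale TIFFs; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphometrics import ImageStack, WrinkleLine

__all__ = [
    "SynthSpec",
    "synth_wrinkle_stack",
    "synth_two_class_dataset",
    "synth_fret_pair",
    "synth_cell_regions",
    "write_tiff",
]

_U16_MAX = 65535


@dataclass
class SynthSpec:
    """Parameters of a synthetic wrinkle ridge image.

    ``ridge``: "flat", "sinusoid", "triangle", or "mixture".
    Amplitude and wavelength in px; the ridge is rendered as a bright band
    with a Gaussian cross-section of the given width.
    """

    width: int = 256
    depth: int = 64
    n_slices: int = 1
    pixel_size: float = 0.5
    ridge: str = "sinusoid"
    wavelength: float = 50.0
    amplitude: float = 10.0
    phase: float = 0.0
    extra_wavelengths: tuple[float, ...] = ()
    extra_amplitudes: tuple[float, ...] = ()
    cross_section_px: float = 2.0
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge not in ("flat", "sinusoid", "triangle", "mixture"):
            raise ValueError(f"unknown ridge model {self.ridge!r}")
        if self.ridge != "flat" and self.wavelength >= self.width:
            raise ValueError("wavelength must be smaller than the image width")
        if self.amplitude >= self.depth / 2:
            raise ValueError("amplitude must fit within the depth extent")


def _ridge_profile(spec: SynthSpec) -> np.ndarray:
    x = np.arange(spec.width, dtype=float)
    mid = spec.depth / 2.0
    if spec.ridge == "flat":
        return np.full(spec.width, mid)
    if spec.ridge == "sinusoid":
        return mid + spec.amplitude * np.sin(
            2.0 * np.pi * x / spec.wavelength + spec.phase
        )
    if spec.ridge == "triangle":
        t = (x / spec.wavelength + spec.phase / (2 * np.pi)) % 1.0
        tri = 4.0 * np.abs(t - 0.5) - 1.0
        return mid + spec.amplitude * tri
    z = np.full(spec.width, mid)
    comps = [(spec.wavelength, spec.amplitude)] + list(
        zip(spec.extra_wavelengths, spec.extra_amplitudes)
    )
    for lam, amp in comps:
        z += amp * np.sin(2.0 * np.pi * x / lam + spec.phase)
    return z


def synth_wrinkle_stack(spec: SynthSpec) -> tuple[ImageStack, WrinkleLine]:
    """Render the ridge as a Gaussian-profile bright band plus noise.

    Returns the image stack and the ground-truth ridge line.
    """
    rng = np.random.default_rng(spec.seed)
    z_true = _ridge_profile(spec)
    zz = np.arange(spec.depth, dtype=float)[:, None]
    band = np.exp(-0.5 * ((zz - z_true[None, :]) / spec.cross_section_px) ** 2)
    img = 0.8 * band
    data = np.empty((spec.n_slices, spec.depth, spec.width))
    for s in range(spec.n_slices):
        noisy = img.copy()
        if spec.poisson_scale > 0:
            noisy = rng.poisson(noisy * spec.poisson_scale) / spec.poisson_scale
        if spec.noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        data[s] = np.clip(noisy, 0.0, 1.0)
    stack = ImageStack(
        (data * _U16_MAX).astype(np.uint16), pixel_size=spec.pixel_size
    )
    return stack, WrinkleLine(z_true, pixel_size=spec.pixel_size)


def synth_two_class_dataset(
    lambda1: float,
    lambda2: float,
    n_per_class: int = 100,
    noise: float = 0.1,
    seed: int = 0,
    width: int = 256,
    amplitude: float = 10.0,
) -> tuple[list[WrinkleLine], np.ndarray]:
    """Labelled ridge lines with class-specific dominant wavelengths.

    ``noise`` is the amplitude-relative standard deviation of additive
    Gaussian roughness on each line.  Returns (lines, labels).
    """
    if lambda1 == lambda2:
        raise ValueError("the two class wavelengths must differ")
    rng = np.random.default_rng(seed)
    x = np.arange(width, dtype=float)
    lines: list[WrinkleLine] = []
    labels = np.repeat([0, 1], n_per_class)
    for label in (0, 1):
        lam = (lambda1, lambda2)[label]
        for _ in range(n_per_class):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            z = amplitude * np.sin(2.0 * np.pi * x / lam + phase)
            if noise > 0:
                z = z + rng.normal(0.0, noise * amplitude, size=width)
            lines.append(WrinkleLine(z))
    return lines, labels


def synth_fret_pair(
    strain_map: np.ndarray,
    law=None,
    seed: int = 0,
    baseline: float = 0.8,
    dd_level: float = 0.6,
    noise_sigma: float = 0.01,
) -> tuple[ImageStack, ImageStack, np.ndarray]:
    """Donor/acceptor image pair encoding a strain field.

    ``law`` maps strain to the acceptor/donor ratio and must be monotone
    decreasing (default ``baseline / (1 + strain)``).  DD is constant plus
    noise; DA is ``law(strain) * DD`` before noise.  Returns
    (DA stack, DD stack, ground-truth ratio).
    """
    strain = np.asarray(strain_map, dtype=float)
    if np.any(strain < 0):
        raise ValueError("strain must be non-negative")
    if law is None:
        law = lambda s: baseline / (1.0 + s)  # noqa: E731
    ratio_true = np.asarray(law(strain), dtype=float)
    lo, hi = float(strain.min()), float(strain.max())
    if hi > lo and law(hi) >= law(lo):
        raise ValueError("ratio-vs-strain law must be monotone decreasing")
    rng = np.random.default_rng(seed)
    dd = np.full_like(strain, dd_level)
    da = ratio_true * dd
    if noise_sigma > 0:
        dd = dd + rng.normal(0.0, noise_sigma, size=strain.shape)
        da = da + rng.normal(0.0, noise_sigma, size=strain.shape)
    dd = np.clip(dd, 0.0, 1.0)
    da = np.clip(da, 0.0, 1.0)
    to_stack = lambda a: ImageStack((a * _U16_MAX).astype(np.uint16))  # noqa: E731
    return to_stack(da), to_stack(dd), ratio_true


def synth_cell_regions(
    polarized_fraction: float,
    seed: int = 0,
    size: int = 128,
    cell_radius: int = 48,
    nucleus_radius: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested cell/nucleus masks and an intensity image.

    Exactly ``polarized_fraction`` of the integrated signal falls outside
    the nucleus mask (inside the cell mask).  Returns
    (intensity image, whole-cell mask, nucleus mask).
    """
    if not 0.0 <= polarized_fraction < 1.0:
        raise ValueError("polarized fraction must be in [0, 1)")
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - size / 2) ** 2 + (xx - size / 2) ** 2
    cell = r2 <= cell_radius**2
    nucleus = r2 <= nucleus_radius**2
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size))
    ring = cell & ~nucleus
    # random non-negative texture, then scale the two regions to the target
    img[nucleus] = rng.uniform(0.5, 1.0, size=int(nucleus.sum()))
    img[ring] = rng.uniform(0.5, 1.0, size=int(ring.sum()))
    total = 1.0
    inner_target = total * (1.0 - polarized_fraction)
    outer_target = total * polarized_fraction
    img[nucleus] *= inner_target / img[nucleus].sum()
    if outer_target > 0:
        img[ring] *= outer_target / img[ring].sum()
    else:
        img[ring] = 0.0
    return img, cell, nucleus


def write_tiff(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), stack.data.astype(np.uint16))
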