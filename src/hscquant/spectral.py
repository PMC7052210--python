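"""Emission-spectrum extraction and two-component linear spectral unmixing.

Retinoid droplets have a characteristic emission spectrum (excitation 480 nm,
detection 490-790 nm in 5 nm windows); tissue autofluorescence has another.
Each pixel of a spectral stack is modelled as a non-negative combination

    pixel(lambda) = c_ret * ref_retinoid(lambda) + c_bg * ref_background(lambda)

and the coefficients are recovered by per-pixel non-negative least squares,
separating the retinoid image from the background image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .mosaic import ChannelImage

__all__ = [
    "SpectralStack",
    "EmissionSpectrum",
    "UnmixResult",
    "extract_spectrum",
    "unmix",
    "retinoid_map",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectral_stack",
    "write_spectral_stack",
]


@dataclass
class EmissionSpectrum:
    """An emission spectrum sampled on a wavelength axis.

    Normalized spectra have unit maximum, matching how reference spectra of
    retinoid droplets and tissue background are reported and stored.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities lengths differ")
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("spectrum must be 1D")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")

    @property
    def is_normalized(self) -> bool:
        return bool(np.isclose(self.intensities.max(), 1.0))

    def normalized(self) -> "EmissionSpectrum":
        """Scale to unit maximum."""
        peak = self.intensities.max()
        if peak <= 0:
            raise ValueError("cannot normalize a non-positive spectrum")
        return EmissionSpectrum(
            self.wavelengths_nm, self.intensities / peak, self.label
        )


@dataclass
class SpectralStack:
    """Per-pixel emission over a wavelength axis: cube of shape (y, x, n_bins).

    ``start_nm``/``stop_nm`` delimit the detection range and ``step_nm`` the
    spectral window width; bin wavelengths are window centers.
    """

    cube: np.ndarray
    start_nm: float
    stop_nm: float
    step_nm: float
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be 3D (y, x, n_bins)")
        if self.step_nm <= 0 or self.stop_nm <= self.start_nm:
            raise ValueError("invalid wavelength axis")
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm))
        if self.cube.shape[2] != n:
            raise ValueError(
                f"cube has {self.cube.shape[2]} bins but the axis implies {n}"
            )

    @property
    def n_bins(self) -> int:
        return self.cube.shape[2]

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Window-center wavelengths."""
        return self.start_nm + self.step_nm * (np.arange(self.n_bins) + 0.5)


@dataclass
class UnmixResult:
    """Per-pixel unmixing coefficients (non-negative) and RMS fit residual."""

    coeff_retinoid: np.ndarray
    coeff_background: np.ndarray
    residual_rms: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.coeff_retinoid < 0) or np.any(self.coeff_background < 0):
            raise ValueError("coefficients must be non-negative")


def extract_spectrum(
    stack: SpectralStack, roi: np.ndarray, label: str = ""
) -> EmissionSpectrum:
    """Mean spectrum over an ROI, normalized to unit maximum.

    This is how reference spectra are measured: select a region on the
    background or on retinoid droplets and average the per-pixel spectra.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.cube.shape[:2]:
        raise ValueError("ROI must align with the stack's spatial shape")
    if not roi.any():
        raise ValueError("ROI is empty")
    mean = stack.cube[roi].mean(axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("ROI spectrum is non-positive; cannot normalize")
    return EmissionSpectrum(stack.wavelengths_nm, mean / peak, label)


def _check_references(
    stack: SpectralStack,
    ref_a: EmissionSpectrum,
    ref_b: EmissionSpectrum,
    collinearity_tol: float = 1e-6,
) -> np.ndarray:
    for ref in (ref_a, ref_b):
        if ref.wavelengths_nm.shape != stack.wavelengths_nm.shape or not np.allclose(
            ref.wavelengths_nm, stack.wavelengths_nm
        ):
            raise ValueError("reference spectrum is not on the stack's axis")
    a = ref_a.intensities
    b = ref_b.intensities
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("reference spectrum is identically zero")
    cos = abs(float(a @ b)) / (na * nb)
    if 1.0 - cos < collinearity_tol:
        raise ValueError("reference spectra are collinear; cannot unmix")
    return np.column_stack([a, b])


def _nnls_two_columns(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized exact NNLS for a two-column design.

    The minimizer is either the unconstrained least-squares solution (when it
    is non-negative) or the best of the two single-column non-negative
    projections / the origin.  Y has shape (n_pixels, n_bins); returns
    coefficients of shape (n_pixels, 2).
    """
    a, b = A[:, 0], A[:, 1]
    aa, bb, ab = a @ a, b @ b, a @ b
    ya = Y @ a
    yb = Y @ b
    det = aa * bb - ab * ab
    # interior (unconstrained) solution
    ca = (bb * ya - ab * yb) / det
    cb = (aa * yb - ab * ya) / det
    coeffs = np.stack([ca, cb], axis=1)
    interior_ok = (ca >= 0) & (cb >= 0)
    # boundary candidates: one active coefficient, or none
    ca_only = np.maximum(ya / aa, 0.0)
    cb_only = np.maximum(yb / bb, 0.0)
    # residual^2 = |y|^2 - 2 c.(ya,yb) + c^T G c, compare without |y|^2
    ra = -2 * ca_only * ya + ca_only**2 * aa
    rb = -2 * cb_only * yb + cb_only**2 * bb
    use_a = ra <= rb
    boundary = np.where(
        use_a[:, None],
        np.stack([ca_only, np.zeros_like(ca_only)], axis=1),
        np.stack([np.zeros_like(cb_only), cb_only], axis=1),
    )
    return np.where(interior_ok[:, None], coeffs, boundary)


def unmix(
    stack: SpectralStack,
    ref_retinoid: EmissionSpectrum,
    ref_background: EmissionSpectrum,
    pixel_size_um: float | None = None,
) -> UnmixResult:
    """Separate a stack into retinoid and background component images.

    Per-pixel non-negative least squares against the two reference spectra.
    On a noise-free two-component mixture the recovery is exact (consistent
    system), so residuals vanish to numerical precision.
    """
    A = _check_references(stack, ref_retinoid, ref_background)
    h, w, n = stack.cube.shape
    Y = stack.cube.reshape(-1, n)
    C = _nnls_two_columns(A, Y)
    resid = Y - C @ A.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return UnmixResult(
        coeff_retinoid=C[:, 0].reshape(h, w),
        coeff_background=C[:, 1].reshape(h, w),
        residual_rms=rms.reshape(h, w),
        pixel_size_um=pixel_size_um,
    )


def retinoid_map(
    result: UnmixResult, threshold: float = 0.0, pixel_size_um: float | None = None
) -> ChannelImage:
    """Thresholded retinoid-coefficient image as an RF channel.

    Coefficients below ``threshold`` are zeroed; the rest pass through in
    instrument-intensity units (references are stored at unit maximum).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    px = pixel_size_um or result.pixel_size_um
    if px is None:
        px = 1.0
    c = result.coeff_retinoid
    return ChannelImage(np.where(c >= threshold, c, 0.0), px, channel="RF")


# ---------------------------------------------------------------------------
# I/O: spectra as 2-column CSV, stacks as multi-page TIFF + JSON axis sidecar.


def write_spectrum_csv(path, spectrum: EmissionSpectrum) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths_nm,
            "intensity": spectrum.intensities,
        }
    ).to_csv(path, index=False)


def read_spectrum_csv(path, label: str = "") -> EmissionSpectrum:
    df = pd.read_csv(path)
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), label
    )


def write_spectral_stack(tiff_path, axis_json_path, stack: SpectralStack) -> None:
    """One TIFF page per wavelength bin plus a JSON axis descriptor."""
    pages = np.moveaxis(stack.cube, 2, 0).astype(np.float32)
    tifffile.imwrite(str(tiff_path), pages, photometric="minisblack")
    with open(axis_json_path, "w") as fh:
        json.dump(
            {
                "start_nm": stack.start_nm,
                "stop_nm": stack.stop_nm,
                "step_nm": stack.step_nm,
                "excitation_nm": stack.excitation_nm,
            },
            fh,
            indent=2,
        )


def read_spectral_stack(tiff_path, axis_json_path) -> SpectralStack:
    pages = tifffile.imread(str(tiff_path))
    with open(axis_json_path) as fh:
        axis = json.load(fh)
    cube = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
    return SpectralStack(
        cube,
        start_nm=axis["start_nm"],
        stop_nm=axis["stop_nm"],
        step_nm=axis["step_nm"],
        excitation_nm=axis.get("excitation_nm"),
    )
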