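"""Scatter corrections and gap-segment derivative treatments for NIR spectra.

Implements the pretreatments evaluated when developing faecal calibrations:
standard normal variate (SNV), polynomial detrending (D), their combination
(SNV+D), multiplicative scatter correction (MSC), and derivative codes
``(d, g, s1, s2)`` — derivative order, gap in points, and two moving-average
smoothing widths — applied as smooth(s1) -> d forward gap-differences ->
smooth(s2) with valid-region trimming (no edge padding).

All functions operate on a 2-D matrix (samples x wavelengths) sharing one
uniform grid; 1-D input is treated as a single spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "Spectrum",
    "PretreatmentSpec",
    "SCATTER_OPTIONS",
    "DEFAULT_DERIVATIVES",
    "default_grid",
    "snv",
    "detrend",
    "msc",
    "moving_average",
    "gap_derivative",
    "apply_pretreatment",
]

SCATTER_OPTIONS = ("none", "D", "SNV", "SNV+D", "MSC")

#: Derivative codes evaluated by default: (order, gap, smooth1, smooth2).
DEFAULT_DERIVATIVES = ((0, 0, 1, 1), (1, 4, 4, 1), (1, 8, 8, 1), (2, 5, 5, 1),
                       (2, 10, 10, 1))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a uniform, strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.shape != wl.shape or wl.size < 2:
            raise ValueError("wavelengths/absorbance must be matching 1-D, length >= 2")
        steps = np.diff(wl)
        if steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > 1e-9):
            raise ValueError("wavelength grid must be uniform and increasing")
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"non-finite absorbance in spectrum {self.sample_id!r}")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass(frozen=True)
class PretreatmentSpec:
    """Scatter correction + derivative code applied before calibration."""

    scatter: str = "none"
    derivative: tuple[int, int, int, int] = (0, 0, 1, 1)

    def __post_init__(self):
        if self.scatter not in SCATTER_OPTIONS:
            raise ValueError(
                f"scatter {self.scatter!r} not one of {SCATTER_OPTIONS}"
            )
        d, g, s1, s2 = self.derivative
        if d < 0:
            raise ValueError("derivative order must be >= 0")
        if d >= 1 and g < 1:
            raise ValueError("gap must be >= 1 for derivative order >= 1")
        if s1 < 1 or s2 < 1:
            raise ValueError("smoothing widths must be >= 1")

    @property
    def label(self) -> str:
        d, g, s1, s2 = self.derivative
        return f"{self.scatter},{d},{g},{s1},{s2}"

    @classmethod
    def parse(cls, label: str) -> "PretreatmentSpec":
        scatter, *rest = label.split(",")
        if len(rest) != 4:
            raise ValueError(f"cannot parse pretreatment label {label!r}")
        return cls(scatter=scatter, derivative=tuple(int(x) for x in rest))

    def trimmed_length(self, n: int) -> int:
        """Output length after smoothing/gap trimming of an n-point spectrum."""
        d, g, s1, s2 = self.derivative
        return n - (s1 - 1) - d * g - (s2 - 1)


def default_grid() -> list[PretreatmentSpec]:
    """The full scatter x derivative grid evaluated during model selection."""
    return [
        PretreatmentSpec(scatter=s, derivative=d)
        for s, d in product(SCATTER_OPTIONS, DEFAULT_DERIVATIVES)
    ]


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def snv(x) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to sd 1."""
    mat, squeeze = _as_matrix(x)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)  # population sd
    bad = np.flatnonzero(sd.ravel() == 0.0)
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum at row {bad[0]}")
    out = (mat - mean) / sd
    return out[0] if squeeze else out


def detrend(x, wavelengths, degree: int = 2) -> np.ndarray:
    """Remove the least-squares polynomial of ``degree`` in wavelength."""
    mat, squeeze = _as_matrix(x)
    wl = np.asarray(wavelengths, dtype=float)
    if mat.shape[1] != wl.size:
        raise ValueError("wavelength grid does not match spectra")
    if wl.size <= degree:
        raise ValueError(f"need more than {degree} points to detrend")
    # orthonormal polynomial basis for numerical stability
    basis = np.polynomial.polynomial.polyvander(
        (wl - wl.mean()) / (np.ptp(wl) / 2.0), degree
    )
    q, _ = np.linalg.qr(basis)
    out = mat - (mat @ q) @ q.T
    return out[0] if squeeze else out


def msc(x, reference) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed as ``a + b * reference``; the corrected
    spectrum is ``(x - a) / b``.  The reference is normally the calibration
    set mean and must be reused unchanged on validation spectra.
    """
    mat, squeeze = _as_matrix(x)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (mat.shape[1],):
        raise ValueError("reference length does not match spectra")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise ValueError("MSC reference has zero variance")
    b = (mat - mat.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-12):
        row = int(np.flatnonzero(np.abs(b) < 1e-12)[0])
        raise ValueError(f"MSC slope ~ 0 for spectrum at row {row}")
    a = mat.mean(axis=1) - b * ref.mean()
    out = (mat - a[:, None]) / b[:, None]
    return out[0] if squeeze else out


def moving_average(x, width: int) -> np.ndarray:
    """Centred moving average of exactly ``width`` points, valid region only.

    Even widths use a window carrying one extra point to the right of the
    assigned centre.  ``width == 1`` is the identity.
    """
    mat, squeeze = _as_matrix(x)
    if width < 1:
        raise ValueError("smoothing width must be >= 1")
    if width == 1:
        return x if not squeeze else mat[0]
    if mat.shape[1] < width:
        raise ValueError("spectrum too short for smoothing window")
    kernel = np.full(width, 1.0 / width)
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, mat)
    return out[0] if squeeze else out


def _smooth_grid(wavelengths: np.ndarray, width: int) -> np.ndarray:
    if width == 1:
        return wavelengths
    start = (width - 1) // 2
    return wavelengths[start:start + wavelengths.size - width + 1]


def gap_derivative(x, wavelengths, d: int, g: int, s1: int, s2: int):
    """Gap-segment derivative: smooth(s1) -> d gap-differences -> smooth(s2).

    Returns ``(treated, trimmed_wavelengths)``.  Each forward gap difference
    ``y[i+g] - y[i]`` is assigned the midpoint wavelength, keeping the grid
    uniform.  Code (0,0,1,1) is the identity.
    """
    mat, squeeze = _as_matrix(x)
    wl = np.asarray(wavelengths, dtype=float)
    if mat.shape[1] != wl.size:
        raise ValueError("wavelength grid does not match spectra")
    if d == 0 and s1 == 1 and s2 == 1:
        return (mat[0] if squeeze else mat), wl
    if d >= 1 and g < 1:
        raise ValueError("gap must be >= 1 for derivative order >= 1")
    step = wl[1] - wl[0]
    out = mat
    grid = wl
    n_out = mat.shape[1] - (s1 - 1) - d * g - (s2 - 1)
    if n_out < 2:
        raise ValueError("spectrum too short for treatment")
    out = moving_average(out, s1)
    grid = _smooth_grid(grid, s1)
    for _ in range(d):
        out = out[:, g:] - out[:, :-g]
        grid = grid[:-g] + g * step / 2.0
    out = moving_average(out, s2)
    grid = _smooth_grid(grid, s2)
    return (out[0] if squeeze else out), grid


def apply_pretreatment(
    spectra_matrix,
    wavelengths,
    spec: PretreatmentSpec,
    reference=None,
):
    """Apply scatter correction then derivative to a spectra matrix.

    Returns ``(treated_matrix, treated_wavelengths, msc_reference)`` where
    the reference is the one actually used for MSC (the matrix mean when not
    supplied) and ``None`` for other scatter modes.  Pass the stored
    calibration reference when treating validation spectra.
    """
    mat, squeeze = _as_matrix(spectra_matrix)
    wl = np.asarray(wavelengths, dtype=float)
    used_ref = None
    if spec.scatter == "none":
        out = mat
    elif spec.scatter == "D":
        out = detrend(mat, wl)
    elif spec.scatter == "SNV":
        out = snv(mat)
    elif spec.scatter == "SNV+D":
        out = detrend(snv(mat), wl)
    elif spec.scatter == "MSC":
        used_ref = np.asarray(reference, dtype=float) if reference is not None \
            else mat.mean(axis=0)
        out = msc(mat, used_ref)
    else:  # pragma: no cover - guarded by PretreatmentSpec
        raise ValueError(spec.scatter)
    out, grid = gap_derivative(out, wl, *spec.derivative)
    return (out[0] if squeeze else out), grid, used_ref
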