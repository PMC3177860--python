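"""Cone-space colorimetry: reflectance spectra to cone contrasts and opponent responses.

The chain implemented here is the standard early-vision one: a surface's
spectral reflectance is multiplied by a daylight illuminant to give the
reflected spectral power distribution (SPD); the SPD is projected onto the
L-, M-, and S-cone fundamentals to give cone excitations; excitations are
expressed as Weber contrasts against a reference gray; and the two
retinogeniculate opponent channels are modeled as fixed linear combinations
of the contrasts,

    R_LM = 0.5*C_L - 0.5*C_M
    R_Y  = 0.25*C_L + 0.25*C_M - 0.5*C_S

with the L-cone fundamental scaled by 1.98 so that L+M approximates the
luminous efficiency function.  All computations are in energy units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "ConeFundamentals",
    "ConeExcitations",
    "ConeContrasts",
    "OpponentResponse",
    "Chromaticity",
    "resample_spectrum",
    "reflected_spd",
    "cone_excitations",
    "cone_contrasts",
    "opponent_responses",
    "xy_to_cone_excitations",
    "planckian_spd",
    "synthetic_cone_fundamentals",
    "load_default_illuminant",
    "load_default_fundamentals",
    "spectrum_to_opponent",
]

#: Common wavelength grid (nm): covers the visible band tabulated by both the
#: Munsell reflectance sets and the cone fundamentals, at 5 nm steps.
DEFAULT_GRID = np.arange(390.0, 731.0, 5.0)

#: Scaling of the L-cone fundamental so L+M approximates luminous efficiency.
DEFAULT_L_SCALE = 1.98


class GridMismatchError(ValueError):
    """Two spectra were combined without first being resampled to one grid."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function (reflectance or spectral power).

    Parameters
    ----------
    wavelengths:
        Strictly increasing wavelengths in nm.  Source spectra have at least
        two samples; a resampled probe may have one.
    values:
        Non-negative samples, same length as ``wavelengths``.  Reflectances
        are typically in [0, ~1.2] (glossy chips can exceed 1 at specular
        angles); spectral power is in arbitrary linear energy units.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or va.ndim != 1 or wl.size != va.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 1:
            raise ValueError("a spectrum needs at least one sample")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(va)):
            raise ValueError("spectrum contains non-finite entries")
        if np.any(va < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", va)

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class ConeFundamentals:
    """L/M/S spectral sensitivities on a common wavelength grid.

    ``l_scale`` multiplies the L fundamental when computing excitations
    (default 1.98, so that the sum of the scaled L and the M fundamental
    approximates the luminous efficiency function).
    """

    wavelengths: np.ndarray
    l: np.ndarray
    m: np.ndarray
    s: np.ndarray
    l_scale: float = DEFAULT_L_SCALE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        arrays = {}
        for name in ("l", "m", "s"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != wl.shape:
                raise ValueError("fundamentals must share the wavelength grid")
            if np.any(a < 0):
                raise ValueError(f"{name}-cone fundamental has negative entries")
            arrays[name] = a
        if not self.l_scale > 0:
            raise ValueError("l_scale must be positive")
        object.__setattr__(self, "wavelengths", wl)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)


class ConeExcitations(NamedTuple):
    """L, M, S cone excitations in arbitrary linear energy units."""

    L: float
    M: float
    S: float


class ConeContrasts(NamedTuple):
    """Weber cone contrasts relative to a reference stimulus."""

    C_L: float
    C_M: float
    C_S: float


class OpponentResponse(NamedTuple):
    """Modeled responses of the L-M and S-(L+M) opponent channels."""

    R_LM: float
    R_Y: float


class Chromaticity(NamedTuple):
    """CIE 1931 (x, y) chromaticity plus luminance Y in cd/m^2."""

    x: float
    y: float
    Y: float


def resample_spectrum(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``; zero outside support.

    Wavelengths outside the source range are filled with 0 (no reflectance /
    no power is the conservative extrapolation for band-limited data).
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("target grid is empty")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("target grid must be strictly increasing")
    vals = np.interp(g, s.wavelengths, s.values, left=0.0, right=0.0)
    return Spectrum(g, vals)


def _check_common_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=0.0, atol=1e-9):
        raise GridMismatchError("spectra are not on a common wavelength grid")


def reflected_spd(reflectance: Spectrum, illuminant: Spectrum) -> Spectrum:
    """SPD of light reflected from a surface: element-wise product."""
    _check_common_grid(reflectance.wavelengths, illuminant.wavelengths)
    return Spectrum(reflectance.wavelengths, reflectance.values * illuminant.values)


def cone_excitations(spd: Spectrum, fund: ConeFundamentals) -> ConeExcitations:
    """Dot product of the SPD with each cone fundamental (L scaled by l_scale)."""
    _check_common_grid(spd.wavelengths, fund.wavelengths)
    v = spd.values
    return ConeExcitations(
        L=float(fund.l_scale * np.dot(v, fund.l)),
        M=float(np.dot(v, fund.m)),
        S=float(np.dot(v, fund.s)),
    )


def cone_contrasts(test: ConeExcitations, ref: ConeExcitations) -> ConeContrasts:
    """Weber contrasts (E - E0) / E0 per cone class against a reference gray."""
    if not (ref.L > 0 and ref.M > 0 and ref.S > 0):
        raise ValueError("reference excitations must all be positive")
    return ConeContrasts(
        C_L=(test.L - ref.L) / ref.L,
        C_M=(test.M - ref.M) / ref.M,
        C_S=(test.S - ref.S) / ref.S,
    )


def opponent_responses(c: ConeContrasts) -> OpponentResponse:
    """Fixed-weight opponent channel responses from cone contrasts."""
    if not all(np.isfinite(c)):
        raise ValueError("cone contrasts must be finite")
    return OpponentResponse(
        R_LM=0.5 * c.C_L - 0.5 * c.C_M,
        R_Y=0.25 * c.C_L + 0.25 * c.C_M - 0.5 * c.C_S,
    )


def xy_to_cone_excitations(chrom: Chromaticity, matrix: np.ndarray) -> ConeExcitations:
    """Cone excitations of a display color from CIE xyY via an XYZ->LMS matrix.

    XYZ is reconstructed as (x*Y/y, Y, (1-x-y)*Y/y) and mapped through the
    3x3 ``matrix``.  Used for stimuli specified only by chromaticity and
    luminance (no measured phosphor spectra).
    """
    if chrom.y <= 0:
        raise ValueError("chromaticity y must be positive")
    if chrom.x <= 0 or chrom.x + chrom.y >= 1:
        raise ValueError("chromaticity must satisfy x>0, y>0, x+y<1")
    if chrom.Y < 0:
        raise ValueError("luminance must be non-negative")
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("matrix must be 3x3")
    xyz = np.array(
        [
            chrom.x * chrom.Y / chrom.y,
            chrom.Y,
            (1.0 - chrom.x - chrom.y) * chrom.Y / chrom.y,
        ]
    )
    lms = m @ xyz
    return ConeExcitations(L=float(lms[0]), M=float(lms[1]), S=float(lms[2]))


# ---------------------------------------------------------------------------
# Reference data (synthetic analytic stand-ins)
# ---------------------------------------------------------------------------

def planckian_spd(temperature_k: float = 6504.0, grid: np.ndarray | None = None) -> Spectrum:
    """Blackbody radiator SPD, normalized to 100 at 560 nm.

    A Planckian radiator at 6504 K is a smooth physical approximation to
    average daylight and serves as this package's default illuminant.
    """
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    lam = g * 1e-9
    # Planck's law; constants fold into the normalization.
    c2 = 1.4388e-2  # m K (second radiation constant)
    power = lam ** -5 / np.expm1(c2 / (lam * temperature_k))
    ref = (560e-9) ** -5 / np.expm1(c2 / (560e-9 * temperature_k))
    return Spectrum(g, 100.0 * power / ref)


def synthetic_cone_fundamentals(
    grid: np.ndarray | None = None, l_scale: float = DEFAULT_L_SCALE
) -> ConeFundamentals:
    """Log-Gaussian cone sensitivity templates (synthetic stand-in).

    Analytic approximations to the human 2-degree cone fundamentals: unit-peak
    Gaussians in log10 wavelength with peaks at 570 (L), 543 (M) and 442 (S)
    nm and realistic bandwidths.  They are NOT the tabulated psychophysical
    fundamentals; they reproduce the qualitative structure (ordering, overlap
    of L and M, short-wave isolation of S) that the sign-based analyses in
    this package rely on.  Substitute measured tables via ConeFundamentals
    for quantitative colorimetry.
    """
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    def template(peak_nm: float, sigma_log10: float) -> np.ndarray:
        return np.exp(-0.5 * ((np.log10(g) - np.log10(peak_nm)) / sigma_log10) ** 2)

    return ConeFundamentals(
        wavelengths=g,
        l=template(570.0, 0.0330),
        m=template(543.0, 0.0320),
        s=template(442.0, 0.0280),
        l_scale=l_scale,
    )


def _load_csv_resource(name: str) -> np.ndarray:
    with resources.files("warmcool.data").joinpath(name).open("r") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def load_default_illuminant() -> Spectrum:
    """Packaged daylight-like illuminant (synthetic: Planckian 6504 K)."""
    arr = _load_csv_resource("illuminant_daylight_synthetic.csv")
    return Spectrum(arr[:, 0], arr[:, 1])


def load_default_fundamentals(l_scale: float = DEFAULT_L_SCALE) -> ConeFundamentals:
    """Packaged cone fundamentals (synthetic log-Gaussian templates)."""
    arr = _load_csv_resource("cone_fundamentals_synthetic.csv")
    return ConeFundamentals(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], l_scale=l_scale)


def spectrum_to_opponent(
    reflectance: Spectrum,
    reference_reflectance: Spectrum,
    illuminant: Spectrum | None = None,
    fund: ConeFundamentals | None = None,
    grid: np.ndarray | None = None,
) -> tuple[ConeContrasts, OpponentResponse]:
    """Convenience chain: two reflectances -> contrasts and opponent responses.

    Both reflectances are resampled onto ``grid`` (default DEFAULT_GRID),
    lit by ``illuminant`` (default packaged daylight), and projected onto
    ``fund`` (default packaged fundamentals).
    """
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    ill = load_default_illuminant() if illuminant is None else illuminant
    fd = load_default_fundamentals() if fund is None else fund
    ill_g = resample_spectrum(ill, g)
    if not np.array_equal(fd.wavelengths, g):
        fd = ConeFundamentals(
            g,
            np.interp(g, fd.wavelengths, fd.l, left=0.0, right=0.0),
            np.interp(g, fd.wavelengths, fd.m, left=0.0, right=0.0),
            np.interp(g, fd.wavelengths, fd.s, left=0.0, right=0.0),
            l_scale=fd.l_scale,
        )
    test_exc = cone_excitations(reflected_spd(resample_spectrum(reflectance, g), ill_g), fd)
    ref_exc = cone_excitations(reflected_spd(resample_spectrum(reference_reflectance, g), ill_g), fd)
    c = cone_contrasts(test_exc, ref_exc)
    return c, opponent_responses(c)
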