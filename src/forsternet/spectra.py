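"""Spectra: containers, resampling, overlap densities and dipole strengths.

A :class:`Spectrum` is a strictly monotone 1-D grid (wavelength in nm or
wavenumber in cm^-1) with non-negative values.  The central quantity built
here is the density of interacting states

    rho = Integral  a_bar(nu) * F_bar(nu)  d nu        [cm]

the wavenumber-domain overlap of the *area-normalized* acceptor absorption
line shape a_bar and donor emission line shape F_bar.  rho feeds the
golden-rule transfer rate k = 4 pi^2 c V^2 rho (see :mod:`forsternet.kinetics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

from .units import C_CAL_D2, NM_PER_CM


class AxisKind(str, Enum):
    WAVELENGTH_NM = "wavelength_nm"
    WAVENUMBER_CM1 = "wavenumber_cm-1"


class ValueKind(str, Enum):
    ABSORBANCE = "absorbance"
    EXTINCTION = "extinction_M-1cm-1"
    EMISSION = "emission"
    IRRADIANCE = "irradiance_photon_flux"


class ZeroOverlapWarning(UserWarning):
    """Donor emission and acceptor absorption have disjoint support."""


@dataclass(frozen=True)
class Spectrum:
    """An immutable sampled spectrum on a strictly increasing grid."""

    axis_kind: AxisKind
    grid: np.ndarray
    values: np.ndarray
    value_kind: ValueKind

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if values.shape != grid.shape:
            raise ValueError("grid and values must have identical shape")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("values must be finite and non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    # -- convenience -------------------------------------------------
    @property
    def area(self) -> float:
        """Trapezoidal integral of the values over the grid."""
        return float(np.trapezoid(self.values, self.grid))

    def peak_position(self) -> float:
        """Grid coordinate of the maximum value."""
        return float(self.grid[int(np.argmax(self.values))])

    def to_text(self, path: str | Path, header: str = "") -> None:
        """Write as two-column delimited text (axis, value)."""
        lines = []
        if header:
            lines += [f"# {line}" for line in header.splitlines()]
        lines.append(f"# axis={self.axis_kind.value} value={self.value_kind.value}")
        lines += [f"{x:.8e}\t{y:.8e}" for x, y in zip(self.grid, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(
        cls,
        path: str | Path,
        axis_kind: AxisKind = AxisKind.WAVELENGTH_NM,
        value_kind: ValueKind = ValueKind.ABSORBANCE,
    ) -> "Spectrum":
        """Read a two-column delimited text spectrum; '#' lines are comments."""
        rows = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            rows.append((float(parts[0]), float(parts[1])))
        if len(rows) < 2:
            raise ValueError(f"{path}: fewer than 2 data rows")
        arr = np.array(sorted(rows))
        return cls(axis_kind, arr[:, 0], arr[:, 1], value_kind)


def resample(spectrum: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linearly interpolate onto ``target_grid`` (no extrapolation)."""
    target = np.asarray(target_grid, dtype=float)
    if target.min() < spectrum.grid[0] or target.max() > spectrum.grid[-1]:
        raise ValueError(
            f"target grid [{target.min()}, {target.max()}] exceeds source range "
            f"[{spectrum.grid[0]}, {spectrum.grid[-1]}]"
        )
    vals = np.interp(target, spectrum.grid, spectrum.values)
    return Spectrum(spectrum.axis_kind, target, np.clip(vals, 0.0, None), spectrum.value_kind)


def to_wavenumber(spectrum: Spectrum, jacobian: bool = False) -> Spectrum:
    """Convert a wavelength-axis spectrum to wavenumbers, nu = 1e7/lambda.

    With ``jacobian`` on, values are treated as per-wavelength densities and
    multiplied by lambda^2/1e7 so that integrals are conserved; off, the
    conversion is shape-only (pointwise values untouched).
    """
    if spectrum.axis_kind is not AxisKind.WAVELENGTH_NM:
        raise ValueError("spectrum is not on a wavelength axis")
    if spectrum.grid[0] <= 0:
        raise ValueError("wavelengths must be positive")
    nu = NM_PER_CM / spectrum.grid
    vals = spectrum.values.copy()
    if jacobian:
        vals = vals * spectrum.grid**2 / NM_PER_CM
    order = np.argsort(nu)
    return Spectrum(AxisKind.WAVENUMBER_CM1, nu[order], vals[order], spectrum.value_kind)


def normalize_area(spectrum: Spectrum) -> Spectrum:
    """Rescale so the trapezoidal integral over the grid equals 1."""
    area = spectrum.area
    if area <= 0:
        raise ValueError("cannot area-normalize an all-zero spectrum")
    return replace(spectrum, values=spectrum.values / area)


def _as_wavenumber_lineshape(spectrum: Spectrum) -> Spectrum:
    """Internal: bring any spectrum to a wavenumber axis.

    Values are taken pointwise (shape-only conversion); the subsequent area
    normalization in nu turns them into proper line shapes.  For bands
    narrow relative to their centre (sigma/nu0 ~ 2% here) the difference
    against a per-wavelength-density treatment is O((sigma/nu0)^2) and
    immaterial.
    """
    if spectrum.axis_kind is AxisKind.WAVENUMBER_CM1:
        return spectrum
    return to_wavenumber(spectrum, jacobian=False)


def _common_grid(a: Spectrum, b: Spectrum) -> Optional[np.ndarray]:
    lo = max(a.grid[0], b.grid[0])
    hi = min(a.grid[-1], b.grid[-1])
    if hi <= lo:
        return None
    step = min(np.diff(a.grid).min(), np.diff(b.grid).min())
    n = max(int(np.ceil((hi - lo) / step)) + 1, 8)
    return np.linspace(lo, hi, n)


def density_of_states(acceptor_abs: Spectrum, donor_em: Spectrum) -> float:
    """Overlap density of interacting states rho in cm.

    Both spectra are brought to a common wavenumber grid (intersection of
    supports at the finer spacing), area-normalized *on their own full grid*,
    and their product integrated.  Returns 0 with a warning when the supports
    are disjoint.
    """
    a = _as_wavenumber_lineshape(acceptor_abs)
    f = _as_wavenumber_lineshape(donor_em)
    a = normalize_area(a)
    f = normalize_area(f)
    grid = _common_grid(a, f)
    if grid is None:
        warnings.warn("zero spectral overlap between donor and acceptor", ZeroOverlapWarning)
        return 0.0
    a_vals = np.interp(grid, a.grid, a.values)
    f_vals = np.interp(grid, f.grid, f.values)
    return float(np.trapezoid(a_vals * f_vals, grid))


def lambda4_overlap_ratio(acceptor_abs: Spectrum, donor_em: Spectrum) -> float:
    """Diagnostic: the lambda^4-weighted overlap ratio in the wavelength domain.

    Integral a(l) F(l) l^4 dl / Integral a(l) F(l) dl, in nm^4.  Kept as an
    alternative overlap statistic; it is *not* the rho that enters the rate
    kernel (its units are length^4).
    """
    for s in (acceptor_abs, donor_em):
        if s.axis_kind is not AxisKind.WAVELENGTH_NM:
            raise ValueError("lambda4 ratio requires wavelength-axis spectra")
    grid = _common_grid(acceptor_abs, donor_em)
    if grid is None:
        warnings.warn("zero spectral overlap between donor and acceptor", ZeroOverlapWarning)
        return 0.0
    a = np.interp(grid, acceptor_abs.grid, acceptor_abs.values)
    f = np.interp(grid, donor_em.grid, donor_em.values)
    denom = np.trapezoid(a * f, grid)
    if denom <= 0:
        return 0.0
    return float(np.trapezoid(a * f * grid**4, grid) / denom)


def approximate_emission(
    abs_spectrum: Spectrum, stokes_shift_cm1: float, mirror: bool = False
) -> Spectrum:
    """Build a surrogate emission line shape from an absorption band.

    The absorption line shape (as a wavenumber density) is shifted to lower
    energy by ``stokes_shift_cm1``; with ``mirror`` on it is first reflected
    about its peak (taken as the 0-0 position).  The result is
    area-normalized and returned on a wavenumber axis.  Used where no
    measured emission exists, e.g. Soret-band emission.
    """
    if stokes_shift_cm1 < 0:
        raise ValueError("Stokes shift must be non-negative")
    line = normalize_area(_as_wavenumber_lineshape(abs_spectrum))
    grid, vals = line.grid, line.values
    if mirror:
        pivot = line.peak_position()
        grid = (2.0 * pivot - grid)[::-1]
        vals = vals[::-1]
    grid = grid - stokes_shift_cm1
    out = Spectrum(AxisKind.WAVENUMBER_CM1, grid, vals, ValueKind.EMISSION)
    return normalize_area(out)


def dipole_strength_from_band(
    extinction: Spectrum, band_window_nm: tuple[float, float], n: float = 1.4
) -> float:
    """Transition-dipole magnitude |mu| in Debye from an extinction band.

    |mu|^2 = C_CAL / n * Integral_window eps(nu)/nu d nu  with eps in
    M^-1 cm^-1; C_CAL is the pinned integrated-absorption calibration
    constant (see :mod:`forsternet.units`).
    """
    lo, hi = sorted(band_window_nm)
    if extinction.axis_kind is AxisKind.WAVELENGTH_NM:
        spec = to_wavenumber(extinction, jacobian=False)
        nu_lo, nu_hi = NM_PER_CM / hi, NM_PER_CM / lo
    else:
        spec, nu_lo, nu_hi = extinction, lo, hi
    mask = (spec.grid >= nu_lo) & (spec.grid <= nu_hi)
    if mask.sum() < 2:
        raise ValueError("band window contains fewer than 2 grid points")
    nu = spec.grid[mask]
    eps = spec.values[mask]
    integral = float(np.trapezoid(eps / nu, nu))
    mu_sq = C_CAL_D2 / n * integral
    return float(np.sqrt(max(mu_sq, 0.0)))


# ---------------------------------------------------------------------------
# Spectral library

from .core import Band, PigmentClass, SpectralRole  # noqa: E402


@dataclass
class SpectralLibrary:
    """Lookup of class-level spectra, band peak positions and dipole strengths.

    Keys are (pigment class, band, role).  ``peaks_nm`` holds the band
    maximum per (class, band); ``dipoles_debye`` the effective transition
    dipole magnitude per (class, band).  Carotenoids carry a single bright
    band stored under Band.B.
    """

    spectra: dict
    peaks_nm: dict
    dipoles_debye: dict

    def get(self, pigment_class: PigmentClass, band: Band, role: SpectralRole) -> Spectrum:
        key = (pigment_class, band, role)
        if key not in self.spectra:
            raise KeyError(
                f"spectral library has no {role.value} spectrum for "
                f"{pigment_class.value}/{band.value}"
            )
        return self.spectra[key]

    def has(self, pigment_class: PigmentClass, band: Band, role: SpectralRole) -> bool:
        return (pigment_class, band, role) in self.spectra

    def peak_nm(self, pigment_class: PigmentClass, band: Band) -> float:
        key = (pigment_class, band)
        if key not in self.peaks_nm:
            raise KeyError(f"no band maximum for {pigment_class.value}/{band.value}")
        return self.peaks_nm[key]

    def dipole(self, pigment_class: PigmentClass, band: Band) -> float:
        key = (pigment_class, band)
        if key not in self.dipoles_debye:
            raise KeyError(f"no dipole strength for {pigment_class.value}/{band.value}")
        return self.dipoles_debye[key]
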