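"""Lambert-Beer absorbance of a pigment ensemble under solar irradiance.

The ensemble absorbance is additive in pigment classes,

    A(lambda) = f_cl * sum_g n_g eps_g(lambda),

with n_g the pigment count per complex, eps_g the class extinction spectrum
and f_cl a single dimensionless concentration x path-length knob.  The
absorbed photon score over a window is

    P = Integral_window I(lambda) (1 - 10^(-A(lambda))) d lambda,

which saturates at the available photon flux — so per-class contributions
are *not* additive, and reports expose both the per-class differences and
the full decomposition.  A class's contribution relative to the wild type is

    contribution(g) = [P(WT) - P(variant)] / P(WT)

where the variant removes the class (carotenoids, which are "simply added"
in vivo) or replaces its counts by chlorophyll-a counts (accessory
chlorophylls, which substitute for Chl a).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Band, PigmentClass, SpectralRole
from .spectra import AxisKind, Spectrum, SpectralLibrary, ValueKind, resample

FULL_WINDOW_NM = (350.0, 800.0)
B_BAND_WINDOW_NM = (350.0, 500.0)


@dataclass
class PigmentCensus:
    """Pigment counts per complex plus the concentration-path-length factor."""

    counts: dict = field(default_factory=dict)  # PigmentClass -> int
    cl_factor: float = 1.0

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if int(n) != n or n < 0:
                raise ValueError(f"count for {cls} must be a non-negative integer")
        if self.cl_factor < 0:
            raise ValueError("concentration-path factor must be non-negative")

    def replaced_by_chl_a(self, cls: PigmentClass) -> "PigmentCensus":
        """Variant census with ``cls`` counts folded into chlorophyll a."""
        counts = dict(self.counts)
        moved = counts.pop(cls, 0)
        counts[PigmentClass.CHL_A] = counts.get(PigmentClass.CHL_A, 0) + moved
        return PigmentCensus(counts, self.cl_factor)

    def without(self, cls: PigmentClass) -> "PigmentCensus":
        counts = {c: n for c, n in self.counts.items() if c is not cls}
        return PigmentCensus(counts, self.cl_factor)


@dataclass
class Irradiance:
    """A photon-flux spectrum with a scene label."""

    spectrum: Spectrum
    scene: str = ""

    def __post_init__(self) -> None:
        if self.spectrum.value_kind is not ValueKind.IRRADIANCE:
            raise ValueError("irradiance spectrum must carry photon-flux values")


def _class_extinction(library: SpectralLibrary, cls: PigmentClass) -> Spectrum:
    """Total extinction of a class: sum of its band extinction spectra."""
    bands = [b for b in Band if library.has(cls, b, SpectralRole.EXTINCTION)]
    if not bands:
        raise KeyError(f"no extinction spectrum for class {cls.value}")
    spectra = [library.get(cls, b, SpectralRole.EXTINCTION) for b in bands]
    lo = min(s.grid[0] for s in spectra)
    hi = max(s.grid[-1] for s in spectra)
    step = min(np.diff(s.grid).min() for s in spectra)
    grid = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / step)) + 1, 8))
    total = np.zeros_like(grid)
    for s in spectra:
        mask = (grid >= s.grid[0]) & (grid <= s.grid[-1])
        total[mask] += np.interp(grid[mask], s.grid, s.values)
    return Spectrum(spectra[0].axis_kind, grid, total, ValueKind.EXTINCTION)


def ensemble_absorbance(census: PigmentCensus, library: SpectralLibrary) -> Spectrum:
    """A(lambda) = cl_factor * sum_g n_g eps_g(lambda) on a common nm grid."""
    active = [(c, n) for c, n in census.counts.items() if n > 0]
    if not active:
        # null ensemble: flat zero over the full reporting window
        grid = np.linspace(*FULL_WINDOW_NM, 451)
        return Spectrum(AxisKind.WAVELENGTH_NM, grid, np.zeros_like(grid), ValueKind.ABSORBANCE)
    parts = [(n, _class_extinction(library, c)) for c, n in active]
    lo = min(s.grid[0] for _n, s in parts)
    hi = max(s.grid[-1] for _n, s in parts)
    step = min(np.diff(s.grid).min() for _n, s in parts)
    grid = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / step)) + 1, 8))
    total = np.zeros_like(grid)
    for n, s in parts:
        mask = (grid >= s.grid[0]) & (grid <= s.grid[-1])
        total[mask] += n * np.interp(grid[mask], s.grid, s.values)
    return Spectrum(AxisKind.WAVELENGTH_NM, grid, census.cl_factor * total, ValueKind.ABSORBANCE)


def absorbed_photons(
    absorbance: Spectrum, irradiance: Irradiance, window_nm: tuple[float, float]
) -> float:
    """Photon-absorption score P = Int I(l) (1 - 10^-A(l)) dl over the window.

    Outside the absorbance grid A is taken as zero (nothing absorbs there),
    so the window may extend beyond the pigment bands.
    """
    lo, hi = window_nm
    if hi <= lo:
        raise ValueError(f"empty window ({lo}, {hi})")
    spec_i = irradiance.spectrum
    lo_eff = max(lo, spec_i.grid[0])
    hi_eff = min(hi, spec_i.grid[-1])
    if hi_eff <= lo_eff:
        raise ValueError("window lies outside the irradiance grid")
    step = min(np.diff(spec_i.grid).min(), np.diff(absorbance.grid).min())
    grid = np.linspace(lo_eff, hi_eff, max(int(np.ceil((hi_eff - lo_eff) / step)) + 1, 8))
    flux = np.interp(grid, spec_i.grid, spec_i.values)
    a_vals = np.interp(grid, absorbance.grid, absorbance.values, left=0.0, right=0.0)
    captured = 1.0 - np.power(10.0, -a_vals)
    return float(np.trapezoid(flux * captured, grid))


def class_contribution(
    census: PigmentCensus,
    library: SpectralLibrary,
    irradiance: Irradiance,
    window_nm: tuple[float, float],
    pigment_class: PigmentClass,
    mode: str = "remove",
) -> float:
    """Fractional photon-absorption contribution of one class vs the WT.

    mode="remove": the variant drops the class entirely (carotenoid
    framing).  mode="substitute_chl_a": the variant replaces the class's
    counts by chlorophyll a (accessory-chlorophyll framing).  Returns
    [P(WT) - P(variant)] / P(WT); may be negative in substitute mode when
    the replacement absorbs more.
    """
    if mode == "remove":
        variant = census.without(pigment_class)
    elif mode == "substitute_chl_a":
        variant = census.replaced_by_chl_a(pigment_class)
    else:
        raise ValueError("mode must be 'remove' or 'substitute_chl_a'")
    p_wt = absorbed_photons(ensemble_absorbance(census, library), irradiance, window_nm)
    if p_wt <= 0:
        raise ValueError("wild-type ensemble absorbs no photons; contribution undefined")
    p_var = absorbed_photons(ensemble_absorbance(variant, library), irradiance, window_nm)
    return (p_wt - p_var) / p_wt


def attenuate_irradiance(
    surface: Irradiance, depth_m: float, attenuation: Spectrum
) -> Irradiance:
    """Depth-attenuated irradiance I(l, z) = I0(l) exp(-K(l) z).

    ``attenuation`` holds the diffuse attenuation coefficient K in 1/m on a
    wavelength grid covering the surface spectrum (resampled if needed).
    """
    if depth_m < 0:
        raise ValueError("depth must be non-negative")
    if np.any(attenuation.values < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    k = resample(attenuation, surface.spectrum.grid)
    vals = surface.spectrum.values * np.exp(-k.values * depth_m)
    spec = Spectrum(surface.spectrum.axis_kind, surface.spectrum.grid, vals, ValueKind.IRRADIANCE)
    return Irradiance(spec, scene=f"{surface.scene} @ {depth_m:g} m")


def contribution_report(
    census: PigmentCensus,
    library: SpectralLibrary,
    irradiance: Irradiance,
    windows: Optional[dict] = None,
) -> dict:
    """Per-class contributions for each window plus the full decomposition.

    Carotenoids are scored in remove mode, accessory chlorophylls in
    substitute mode; chlorophyll a itself is scored in remove mode.  The
    absolute WT score is included so the non-additivity of the per-class
    differences stays visible.
    """
    windows = windows or {"full": FULL_WINDOW_NM, "b_band": B_BAND_WINDOW_NM}
    report: dict = {"scene": irradiance.scene, "windows": {}}
    for name, window in windows.items():
        a_wt = ensemble_absorbance(census, library)
        p_wt = absorbed_photons(a_wt, irradiance, window)
        entry = {"window_nm": list(window), "absorbed_wt": p_wt, "classes": {}}
        for cls in census.counts:
            mode = "remove" if cls in (PigmentClass.CRT, PigmentClass.CHL_A) else "substitute_chl_a"
            entry["classes"][cls.value] = {
                "mode": mode,
                "contribution": class_contribution(
                    census, library, irradiance, window, cls, mode
                ),
            }
        report["windows"][name] = entry
    return report
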