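"""Seeded synthetic fixtures: toy geometries, spectra, shifts, irradiance.

These generators stand in for the real inputs of the pipeline — deposited
pigment-protein structures, measured pigment spectra and solar irradiance
curves — so every stage runs and is testable offline.  They emulate the
*shape* of the real data, not its numbers:

* toy complexes place pigments at random, minimum-distance-respecting
  positions in a box, with orthogonal Q/B dipole axes realized as synthetic
  atom pairs (chlorin nitrogen pattern for Chls, a short polyene carbon
  chain for Crts);
* the spectral library builds Gaussian Q and B bands per class, with the
  Soret (B) band stronger than Q, Stokes-shifted emission, accessory-Chl B
  bands red-shifted against chlorophyll a (the B-band energy-sink
  ordering), and a single broad carotenoid band overlapping the Chl B
  window;
* extinction amplitudes are calibrated so the integrated-absorption
  relation recovers each class's assigned dipole strength (6.45 D for the
  chlorophyll-a Q band; B dipoles twice the Q dipoles, putting B couplings
  near 4x Q);
* irradiance is a scaled 5800 K blackbody photon flux, optionally
  attenuated by a toy water column whose K(lambda) grows with wavelength.

Every generator is a pure function of its spec (seed included); child
generators are split off a single SeedSequence, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Band, PigmentClass, SpectralRole
from .spectra import AxisKind, SpectralLibrary, Spectrum, ValueKind
from .structure_io import AxisTable, Pigment
from .units import C_CAL_D2, CM1_PER_EV, NM_PER_CM


@dataclass(frozen=True)
class BandParams:
    """Gaussian band description for one (class, band)."""

    peak_nm: float
    width_cm1: float  # Gaussian sigma in wavenumbers
    stokes_shift_cm1: float
    dipole_debye: float


def default_band_params() -> dict:
    """Shipped per-class band parameters for the study-mimic fixture.

    Chosen once as a realistic chlorophyll/carotenoid caricature: Q bands in
    the 550-700 nm window and Soret bands in 350-500 nm; the chlorophyll-a
    Q dipole at 6.45 D with B dipoles at twice the Q value; accessory-Chl B
    peaks red-shifted relative to chlorophyll a; a single broad carotenoid
    band with a large relaxation shift.  Documented in docs/methods.md.
    """
    return {
        (PigmentClass.CHL_A, Band.Q): BandParams(662.0, 230.0, 140.0, 6.45),
        (PigmentClass.CHL_A, Band.B): BandParams(430.0, 750.0, 900.0, 12.9),
        (PigmentClass.CHL_B, Band.Q): BandParams(645.0, 230.0, 140.0, 4.8),
        (PigmentClass.CHL_B, Band.B): BandParams(455.0, 800.0, 900.0, 9.6),
        (PigmentClass.CHL_C1, Band.Q): BandParams(630.0, 230.0, 140.0, 3.5),
        (PigmentClass.CHL_C1, Band.B): BandParams(460.0, 800.0, 900.0, 11.0),
        (PigmentClass.CRT, Band.B): BandParams(490.0, 1300.0, 2000.0, 13.0),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to generate one reproducible toy study system."""

    seed: int = 2024
    n_chl_a: int = 11
    n_chl_b: int = 0
    n_chl_c1: int = 0
    n_crt: int = 3
    box_angstrom: float = 45.0
    min_distance_angstrom: float = 12.0
    band_params: dict = field(default_factory=default_band_params)

    def __post_init__(self) -> None:
        if min(self.n_chl_a, self.n_chl_b, self.n_chl_c1, self.n_crt) < 0:
            raise ValueError("pigment counts must be non-negative")
        if self.min_distance_angstrom <= 0 or self.box_angstrom <= 0:
            raise ValueError("box size and minimum distance must be positive")

    @property
    def counts(self) -> dict:
        return {
            PigmentClass.CHL_A: self.n_chl_a,
            PigmentClass.CHL_B: self.n_chl_b,
            PigmentClass.CHL_C1: self.n_chl_c1,
            PigmentClass.CRT: self.n_crt,
        }


#: CP24-like default: 11 chlorophylls a plus 3 carotenoids (the worked-example
#: inventory for the rate/efficiency calculations)
CP24_LIKE = FixtureSpec()

#: mixed-inventory study fixture for configuration and absorbance
#: experiments: accessory chlorophylls present so substitution variants and
#: per-class contributions are non-trivial
LHC_MIMIC = FixtureSpec(n_chl_a=8, n_chl_b=3, n_crt=3)


def make_gaussian_band(
    center_nm: float, width_cm1: float, amplitude: float, n_sigma: float = 6.0,
    value_kind: ValueKind = ValueKind.ABSORBANCE,
) -> Spectrum:
    """A Gaussian band in the wavenumber domain rendered on a 0.5 nm grid."""
    if center_nm <= 0 or width_cm1 <= 0:
        raise ValueError("band centre and width must be positive")
    nu0 = NM_PER_CM / center_nm
    lo_nm = NM_PER_CM / (nu0 + n_sigma * width_cm1)
    hi_nm = NM_PER_CM / max(nu0 - n_sigma * width_cm1, width_cm1)
    step = 0.5
    n = int(np.ceil((hi_nm - lo_nm) / step)) + 1
    grid = center_nm + step * (np.arange(n) - int(np.round((center_nm - lo_nm) / step)))
    grid = grid[(grid > 0)]
    nu = NM_PER_CM / grid
    vals = amplitude * np.exp(-0.5 * ((nu - nu0) / width_cm1) ** 2)
    return Spectrum(AxisKind.WAVELENGTH_NM, grid, vals, value_kind)


def _extinction_peak(params: BandParams) -> float:
    """Peak extinction making the integrated-absorption relation exact.

    For a Gaussian band, Int eps/nu d nu ~ eps_peak sigma sqrt(2 pi) / nu0,
    so choosing eps_peak = mu^2 nu0 / (C_CAL sigma sqrt(2 pi)) lets
    dipole_strength_from_band (at n = 1) recover the assigned dipole.
    """
    nu0 = NM_PER_CM / params.peak_nm
    return params.dipole_debye**2 * nu0 / (C_CAL_D2 * params.width_cm1 * np.sqrt(2 * np.pi))


def make_toy_spectral_library(spec: FixtureSpec = CP24_LIKE) -> SpectralLibrary:
    """Gaussian-band spectral library for all classes in the fixture spec."""
    spectra: dict = {}
    peaks: dict = {}
    dipoles: dict = {}
    for (cls, band), p in spec.band_params.items():
        eps_peak = _extinction_peak(p)
        ext = make_gaussian_band(p.peak_nm, p.width_cm1, eps_peak, value_kind=ValueKind.EXTINCTION)
        absn = make_gaussian_band(p.peak_nm, p.width_cm1, eps_peak, value_kind=ValueKind.ABSORBANCE)
        nu_em = NM_PER_CM / p.peak_nm - p.stokes_shift_cm1
        em = make_gaussian_band(
            NM_PER_CM / nu_em, p.width_cm1, 1.0, value_kind=ValueKind.EMISSION
        )
        spectra[(cls, band, SpectralRole.EXTINCTION)] = ext
        spectra[(cls, band, SpectralRole.ABSORPTION)] = absn
        spectra[(cls, band, SpectralRole.EMISSION)] = em
        peaks[(cls, band)] = p.peak_nm
        dipoles[(cls, band)] = p.dipole_debye
    return SpectralLibrary(spectra=spectra, peaks_nm=peaks, dipoles_debye=dipoles)


def _random_orthonormal_pair(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = rng.normal(size=3)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    return u, v


_CHL_RESNAMES = {
    PigmentClass.CHL_A: "CLA",
    PigmentClass.CHL_B: "CHL",
    PigmentClass.CHL_C1: "KC1",
}


def make_toy_complex(spec: FixtureSpec = CP24_LIKE) -> tuple[list[Pigment], AxisTable]:
    """Seeded toy pigment geometry plus the matching axis table.

    Centres are rejection-sampled in a cubic box honouring the minimum
    inter-centre distance.  Chlorophylls get an MG centre atom and two
    orthogonal axis atom pairs (NB-ND for Q, NA-NC for B); carotenoids get
    a 7-carbon polyene chain whose end atoms define the bright-state axis
    and whose centroid is the centre.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_total = sum(spec.counts.values())
    if n_total == 0:
        raise ValueError("fixture needs at least one pigment")

    centers: list[np.ndarray] = []
    max_tries = 20000
    tries = 0
    while len(centers) < n_total:
        cand = rng.uniform(0.0, spec.box_angstrom, size=3)
        if all(np.linalg.norm(cand - c) >= spec.min_distance_angstrom for c in centers):
            centers.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {n_total} pigments at min distance "
                f"{spec.min_distance_angstrom} A in a {spec.box_angstrom} A box"
            )

    pigments: list[Pigment] = []
    idx = 0
    resnum = 601  # cofactor-style numbering
    for cls in (PigmentClass.CHL_A, PigmentClass.CHL_B, PigmentClass.CHL_C1, PigmentClass.CRT):
        for _ in range(spec.counts[cls]):
            center = centers[idx]
            u_q, u_b = _random_orthonormal_pair(rng)
            if cls.is_chlorophyll:
                half = 2.05  # Mg-N distance in a chlorin ring, Angstrom
                atoms = [
                    ("MG", "MG", center.copy()),
                    ("NB", "N", center - half * u_q),
                    ("ND", "N", center + half * u_q),
                    ("NA", "N", center - half * u_b),
                    ("NC", "N", center + half * u_b),
                ]
                subtype = cls.value
            else:
                n_c = 7
                spacing = 1.25
                offsets = (np.arange(n_c) - (n_c - 1) / 2.0) * spacing
                atoms = [
                    (f"CA{k + 1}", "C", center + off * u_q) for k, off in enumerate(offsets)
                ]
                subtype = "toy_carotenoid"
            pigments.append(
                Pigment(
                    site_id=f"X:{resnum}",
                    chain_id="X",
                    pigment_class=cls,
                    subtype=subtype,
                    atoms=atoms,
                    center=center.copy(),
                    monomer_index=0,
                )
            )
            idx += 1
            resnum += 1

    axis_atoms = {}
    for cls_key in ("chl_a", "chl_b", "chl_c1"):
        axis_atoms[(cls_key, Band.Q)] = ("NB", "ND")
        axis_atoms[(cls_key, Band.B)] = ("NA", "NC")
    axis_atoms[("crt", Band.Q)] = ("CA1", "CA7")
    axis_atoms[("crt", Band.B)] = ("CA1", "CA7")
    axis_atoms[("toy_carotenoid", Band.Q)] = ("CA1", "CA7")
    axis_atoms[("toy_carotenoid", Band.B)] = ("CA1", "CA7")
    table = AxisTable(
        axis_atoms=axis_atoms,
        conjugated_atoms={"toy_carotenoid": tuple(f"CA{k + 1}" for k in range(7))},
    )
    return pigments, table


def make_toy_shift_table(
    pigments: list[Pigment], seed: int, scale_ev: float = 0.02
) -> dict:
    """Synthetic site-energy shifts, site_id -> shift in cm^-1.

    Gaussian shifts of the given scale, clipped to +-0.08 eV so they stay
    inside the expected +-0.1 eV envelope; carotenoids are not shifted.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    shifts = {}
    for p in pigments:
        if p.pigment_class is PigmentClass.CRT:
            shifts[p.site_id] = 0.0
        else:
            ev = float(np.clip(rng.normal(0.0, scale_ev), -0.08, 0.08))
            shifts[p.site_id] = ev * CM1_PER_EV
    return shifts


def make_toy_irradiance(kind: str = "surface", depth_m: float = 100.0):
    """Toy solar photon flux: 5800 K blackbody, optionally depth-attenuated.

    kind="surface" gives the sea-level curve; kind="depth" attenuates it by
    a toy water column whose attenuation coefficient rises with wavelength,
    so the transmitted spectrum is blue-dominated.
    """
    from .absorbance import Irradiance, attenuate_irradiance

    grid = np.arange(300.0, 851.0, 1.0)
    lam_m = grid * 1e-9
    hc_over_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * 5800.0)
    flux = lam_m**-4 / np.expm1(hc_over_kT / lam_m)
    flux /= flux.max()
    surface = Irradiance(
        Spectrum(AxisKind.WAVELENGTH_NM, grid, flux, ValueKind.IRRADIANCE),
        scene="toy sea level",
    )
    if kind == "surface":
        return surface
    if kind != "depth":
        raise ValueError("kind must be 'surface' or 'depth'")
    k = make_toy_attenuation()
    return attenuate_irradiance(surface, depth_m, k)


def make_toy_attenuation() -> Spectrum:
    """Toy diffuse attenuation K(lambda) in 1/m, rising towards the red."""
    grid = np.arange(300.0, 851.0, 1.0)
    k = 0.015 + 0.25 * ((grid - 350.0).clip(0.0) / 450.0) ** 3
    return Spectrum(AxisKind.WAVELENGTH_NM, grid, k, ValueKind.ABSORBANCE)


def export_toy_complex_pdb(pigments: list[Pigment], path: str | Path) -> None:
    """Write the toy complex as a minimal PDB file (HETATM records).

    Residue names follow the shipped residue map (CLA/CHL/KC1 and LUT for
    the toy carotenoid), so the written file round-trips through
    :func:`forsternet.structure_io.parse_pigment_sites`.
    """
    lines = []
    serial = 1
    for p in pigments:
        resname = _CHL_RESNAMES.get(p.pigment_class, "LUT")
        resnum = int(p.site_id.split(":")[1])
        for name, element, xyz in p.atoms:
            x, y, z = xyz
            lines.append(
                f"HETATM{serial:5d} {name:<4s}{resname:>4s} {p.chain_id}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_wt_census(spec: FixtureSpec, cl_factor: Optional[float] = None):
    """Pigment census for the fixture; cl factor set so peak WT A ~ 1.

    With the calibrated extinction magnitudes (~1e5 M^-1 cm^-1 peaks) a
    factor of ~1/(n_chl_a * eps_peak) lands the wild-type peak absorbance
    near unity, the regime where per-class contributions are neither
    vanishing nor fully saturated.
    """
    from .absorbance import PigmentCensus

    counts = {c: n for c, n in spec.counts.items() if n > 0}
    if cl_factor is None:
        p = spec.band_params[(PigmentClass.CHL_A, Band.B)]
        cl_factor = 1.0 / (max(spec.n_chl_a, 1) * _extinction_peak(p))
    return PigmentCensus(counts=counts, cl_factor=cl_factor)
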