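"""Excitonic Hamiltonians, delocalization scoring and configuration experiments.

Per band, the site Hamiltonian is the real symmetric matrix with pigment
site energies epsilon_i on the diagonal and Förster couplings V_ij off it.
Diagonalization yields exciton energies (eigenvalues) and per-pigment
weights c_i^2 (squared eigenvector coefficients).  Delocalization is scored
by the inverse participation ratio

    IPR^-1 = 1 / sum_i c_i^4,

ranging from 1 (localized on one pigment) to N (uniform over N pigments).

Site energies are semiempirical: the experimental band maximum of the
pigment class plus a site-specific protein shift.  Carotenoids take the
low-energy peak of their bright band for the B Hamiltonian and, for the Q
Hamiltonian, that value minus 0.8 eV — an estimate of the strongly relaxed
emissive state.

Configuration experiments perturb the pigment inventory (swap every
chlorophyll of one class for another, drop the carotenoids, or both) while
keeping each site's geometry fixed, to probe how accessory pigments break
or build delocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Band, PigmentClass
from .coupling import CouplingMatrix
from .spectra import SpectralLibrary
from .structure_io import Pigment
from .units import CM1_PER_EV, NM_PER_CM

#: energy lowering applied to the carotenoid bright-state energy to place
#: its relaxed emissive state in the Q Hamiltonian
CRT_RELAXATION_EV = 0.8

#: warn when a site shift magnitude exceeds this (expected envelope)
SHIFT_WARN_EV = 0.1

#: minimum squared coefficient for calling an exciton "on" a pigment
DEFAULT_WEIGHT_THRESHOLD = 0.1


class SiteShiftWarning(UserWarning):
    """A site-energy shift exceeds the expected +-0.1 eV envelope."""


@dataclass
class SiteEnergyTable:
    """Per-site excitation energies in cm^-1 with provenance."""

    band: Band
    site_ids: list
    energies_cm1: np.ndarray
    provenance: list = field(default_factory=list)  # str per site

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_cm1, dtype=float)
        if e.shape != (len(self.site_ids),):
            raise ValueError("energies shape does not match site count")
        if np.any(e <= 0):
            raise ValueError("site energies must be positive")
        self.energies_cm1 = e


def site_energy(
    pigment_class: PigmentClass,
    band: Band,
    library: SpectralLibrary,
    shift_cm1: float = 0.0,
    crt_rule: bool = True,
) -> float:
    """Site energy in cm^-1: experimental band maximum plus protein shift.

    Chlorophylls: 1e7/lambda_max(class, band) + shift.  Carotenoids: the
    bright-band 0-0 energy for band B; for band Q (with ``crt_rule`` on)
    that energy minus 0.8 eV, the relaxed-state estimate.
    """
    if abs(shift_cm1) > SHIFT_WARN_EV * CM1_PER_EV:
        warnings.warn(
            f"site shift {shift_cm1 / CM1_PER_EV:+.3f} eV exceeds the expected "
            f"+-{SHIFT_WARN_EV} eV envelope",
            SiteShiftWarning,
        )
    if pigment_class.is_chlorophyll:
        lam = library.peak_nm(pigment_class, band)
        return NM_PER_CM / lam + shift_cm1
    bright = NM_PER_CM / library.peak_nm(PigmentClass.CRT, Band.B)
    if band is Band.B:
        return bright + shift_cm1
    if not crt_rule:
        raise ValueError("carotenoid Q-band energy requires the relaxed-state rule")
    return bright - CRT_RELAXATION_EV * CM1_PER_EV + shift_cm1


def build_site_energy_table(
    pigments: Sequence[Pigment],
    band: Band,
    library: SpectralLibrary,
    shifts_cm1: Optional[dict] = None,
    crt_rule: bool = True,
) -> SiteEnergyTable:
    """Assemble the per-site energy table for one band.

    ``shifts_cm1`` maps site_id -> shift; a missing B-band shift falls back
    to the site's Q-band shift when shifts are keyed as (site_id, band)
    tuples, else missing sites default to zero shift.
    """
    shifts_cm1 = shifts_cm1 or {}
    energies, provenance = [], []
    for p in pigments:
        if (p.site_id, band) in shifts_cm1:
            shift = shifts_cm1[(p.site_id, band)]
        elif (p.site_id, Band.Q) in shifts_cm1:
            shift = shifts_cm1[(p.site_id, Band.Q)]  # B falls back to Q
        else:
            shift = shifts_cm1.get(p.site_id, 0.0)
        e = site_energy(p.pigment_class, band, library, shift, crt_rule)
        energies.append(e)
        provenance.append(f"{p.pigment_class.value} {band.value} max + {shift:.1f} cm-1")
    return SiteEnergyTable(band, [p.site_id for p in pigments], np.array(energies), provenance)


@dataclass
class ExcitonHamiltonian:
    """Real symmetric site Hamiltonian for one band, in cm^-1."""

    band: Band
    site_ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(m)):
            raise ValueError("Hamiltonian entries must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("Hamiltonian must be symmetric")
        self.matrix = m


def build_hamiltonian(
    site_energies: SiteEnergyTable, coupling: CouplingMatrix
) -> ExcitonHamiltonian:
    """Diagonal = site energies, off-diagonal = couplings; exact symmetry."""
    if site_energies.site_ids != coupling.site_ids:
        raise ValueError("site order mismatch between energies and couplings")
    if site_energies.band is not coupling.band:
        raise ValueError("band mismatch between energies and couplings")
    m = coupling.matrix.copy()
    np.fill_diagonal(m, site_energies.energies_cm1)
    return ExcitonHamiltonian(site_energies.band, list(site_energies.site_ids), m)


@dataclass
class ExcitonResult:
    """Eigen-decomposition of a site Hamiltonian with delocalization scores."""

    band: Band
    site_ids: list
    eigenvalues_cm1: np.ndarray  # ascending
    weights: np.ndarray  # (n_excitons, n_sites), rows = c_i^2, each sums to 1
    ipr_inverse: np.ndarray  # per exciton

    def dominant_sites(self, exciton: int, threshold: float = DEFAULT_WEIGHT_THRESHOLD) -> list:
        """Sites carrying at least ``threshold`` of the exciton's weight."""
        return [
            sid
            for sid, w in zip(self.site_ids, self.weights[exciton])
            if w >= threshold
        ]

    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, columns=self.site_ids)


def diagonalize(hamiltonian: ExcitonHamiltonian) -> ExcitonResult:
    """Eigendecompose H with a deterministic sign and ordering convention.

    Eigenvalues ascend; each eigenvector's sign is fixed so its
    largest-magnitude coefficient is positive; within numerically degenerate
    blocks ties are broken by the index of the leading-weight site, giving
    reproducible reports.
    """
    evals, evecs = np.linalg.eigh(hamiltonian.matrix)
    n = evals.size
    # fix sign: largest-|c| coefficient positive
    for k in range(n):
        lead = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[lead, k] < 0:
            evecs[:, k] = -evecs[:, k]
    # stable order: ascending eigenvalue, then leading-weight site index
    lead_idx = np.argmax(evecs**2, axis=0)
    order = np.lexsort((lead_idx, np.round(evals, 6)))
    evals = evals[order]
    evecs = evecs[:, order]
    weights = (evecs**2).T
    ipr_inv = 1.0 / np.sum(weights**2, axis=1)
    return ExcitonResult(
        band=hamiltonian.band,
        site_ids=list(hamiltonian.site_ids),
        eigenvalues_cm1=evals,
        weights=weights,
        ipr_inverse=ipr_inv,
    )


def ipr_inverse(weights: np.ndarray) -> float:
    """Inverse participation ratio 1/sum(c_i^4) of one exciton's weights."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {w.sum():.8f}, expected 1")
    return float(1.0 / np.sum(w**2))


# ---------------------------------------------------------------------------
# Pigment-configuration experiments


@dataclass(frozen=True)
class PigmentConfiguration:
    """A perturbation of the pigment inventory, geometry held fixed."""

    label: str
    substitutions: tuple = ()  # ((source_class, target_class), ...)
    removals: tuple = ()  # (class, ...)

    def __post_init__(self) -> None:
        for src, dst in self.substitutions:
            if src is dst:
                raise ValueError("substituting a class into itself is a no-op")


WT = PigmentConfiguration("WT")
ALL_CHL_A = PigmentConfiguration(
    "ALL_CHL_A",
    substitutions=(
        (PigmentClass.CHL_B, PigmentClass.CHL_A),
        (PigmentClass.CHL_C1, PigmentClass.CHL_A),
    ),
)
NO_CRT = PigmentConfiguration("NO_CRT", removals=(PigmentClass.CRT,))
ALL_CHL_A_NO_CRT = PigmentConfiguration(
    "ALL_CHL_A_NO_CRT",
    substitutions=ALL_CHL_A.substitutions,
    removals=(PigmentClass.CRT,),
)

STANDARD_CONFIGURATIONS = (WT, ALL_CHL_A, NO_CRT, ALL_CHL_A_NO_CRT)


def apply_configuration(
    pigments: Sequence[Pigment], config: PigmentConfiguration
) -> list[Pigment]:
    """Apply substitutions/removals, keeping each site's geometry and atoms.

    A substituted site keeps its coordinates, centre and axis atoms but
    adopts the target class's spectral identity (site-energy source, dipole
    magnitude, overlap class, IC lifetime) downstream.
    """
    out: list[Pigment] = []
    subs = dict(config.substitutions)
    for p in pigments:
        if p.pigment_class in config.removals:
            continue
        if p.pigment_class in subs:
            target = subs[p.pigment_class]
            out.append(
                replace_pigment_class(p, target)
            )
        else:
            out.append(p)
    if not out:
        raise ValueError(f"configuration {config.label} removes every pigment")
    return out


def replace_pigment_class(pigment: Pigment, target: PigmentClass) -> Pigment:
    """Copy of a pigment with a new spectral identity, geometry untouched."""
    return Pigment(
        site_id=pigment.site_id,
        chain_id=pigment.chain_id,
        pigment_class=target,
        subtype=target.value,
        atoms=pigment.atoms,
        center=pigment.center,
        monomer_index=pigment.monomer_index,
    )


def ipr_summary(results: dict) -> pd.DataFrame:
    """Mean IPR^-1 with SEM per (band, configuration label).

    ``results`` maps (label, band) -> ExcitonResult.
    """
    rows = []
    for (label, band), res in results.items():
        ipr = res.ipr_inverse
        rows.append(
            {
                "configuration": label,
                "band": band.value,
                "n_excitons": ipr.size,
                "mean_ipr_inverse": float(ipr.mean()),
                "sem_ipr_inverse": float(ipr.std(ddof=1) / np.sqrt(ipr.size))
                if ipr.size > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)
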