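"""Golden-rule FRET rates and EET-vs-IC branching efficiencies.

The Fermi-golden-rule transfer rate in its wavenumber-domain realization is

    k_FRET = 4 pi^2 c |V|^2 rho          [s^-1]

with V the coupling in cm^-1, rho the density of interacting states in cm
and c the speed of light in cm/s (equivalently 2 pi / hbar |V|^2 rho in SI
units once V and rho are converted through hc).  Rates are reported in
ns^-1.  The branching efficiency of EET against internal conversion is

    E_EET = sum(k_FRET) / (sum(k_FRET) + sum(1/tau_IC)).

Default IC lifetimes: 6.3 ns for the chlorophyll-a Q band, 100 fs for the
Soret (B) band of all chlorophylls — the low end of reported B lifetimes,
deliberately biasing against EET — and a sub-ps relaxed carotenoid S2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import Band, PigmentClass, SpectralRole
from .coupling import CouplingMatrix
from .spectra import SpectralLibrary, density_of_states
from .units import C_CM_PER_S

__all__ = [
    "ICModel",
    "RateTable",
    "fret_rate",
    "ic_rate",
    "eet_efficiency",
    "class_pair_rho",
    "site_eet_summary",
]

_NS_PER_S = 1e9


def fret_rate(v_cm1: float, rho_cm: float) -> float:
    """Golden-rule FRET rate in ns^-1 from V [cm^-1] and rho [cm]."""
    if rho_cm < 0:
        raise ValueError("density of interacting states must be non-negative")
    k_per_s = 4.0 * 3.141592653589793**2 * C_CM_PER_S * v_cm1**2 * rho_cm
    return k_per_s / _NS_PER_S


@dataclass
class ICModel:
    """Internal-conversion lifetimes per (pigment class, band), in ns.

    Q-band entries describe Q -> S0 decay; B-band entries B -> Q internal
    conversion.  The carotenoid B entry stands for relaxation of the bright
    S2 state.
    """

    lifetimes_ns: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ICModel":
        tau = {}
        tau[(PigmentClass.CHL_A, Band.Q)] = 6.3
        for c in (PigmentClass.CHL_B, PigmentClass.CHL_C1):
            tau[(c, Band.Q)] = 6.3  # same order as Chl a; overridable
        for c in (PigmentClass.CHL_A, PigmentClass.CHL_B, PigmentClass.CHL_C1):
            tau[(c, Band.B)] = 100e-6  # 100 fs
        tau[(PigmentClass.CRT, Band.B)] = 150e-6  # sub-ps S2 relaxation
        tau[(PigmentClass.CRT, Band.Q)] = 10e-3  # relaxed Crt state, ~10 ps
        return cls(tau)

    def lifetime_ns(self, pigment_class: PigmentClass, band: Band) -> float:
        key = (pigment_class, band)
        if key not in self.lifetimes_ns:
            raise KeyError(f"no IC lifetime for {pigment_class.value}/{band.value}")
        tau = self.lifetimes_ns[key]
        if tau <= 0:
            raise ValueError("IC lifetime must be positive")
        return tau


def ic_rate(ic_model: ICModel, pigment_class: PigmentClass, band: Band) -> float:
    """Internal-conversion rate 1/tau in ns^-1."""
    return 1.0 / ic_model.lifetime_ns(pigment_class, band)


def eet_efficiency(fret_rates_ns: Sequence[float], ic_rates_ns: Sequence[float]) -> float:
    """Branching ratio sum(k_FRET) / (sum(k_FRET) + sum(k_IC)), in [0, 1)."""
    if len(ic_rates_ns) == 0:
        raise ValueError("at least one IC rate is required")
    if any(k < 0 for k in fret_rates_ns) or any(k < 0 for k in ic_rates_ns):
        raise ValueError("rates must be non-negative")
    k_eet = float(sum(fret_rates_ns))
    k_ic = float(sum(ic_rates_ns))
    total = k_eet + k_ic
    if total == 0:
        raise ValueError("efficiency undefined: all rates are zero")
    return k_eet / total


def class_pair_rho(
    library: SpectralLibrary,
    donor_class: PigmentClass,
    acceptor_class: PigmentClass,
    band: Band,
) -> float:
    """rho for an ordered (donor -> acceptor) class pair in one band, in cm.

    Overlap of the acceptor-class absorption with the donor-class emission.
    Carotenoid spectra live under Band.B regardless of the Hamiltonian band
    in play (the relaxed Crt state inherits the S2 line shape).
    """
    donor_band = band if library.has(donor_class, band, SpectralRole.EMISSION) else Band.B
    acceptor_band = band if library.has(acceptor_class, band, SpectralRole.ABSORPTION) else Band.B
    donor_em = library.get(donor_class, donor_band, SpectralRole.EMISSION)
    acceptor_abs = library.get(acceptor_class, acceptor_band, SpectralRole.ABSORPTION)
    return density_of_states(acceptor_abs, donor_em)


@dataclass
class RateTable:
    """Ordered donor -> acceptor FRET rates for one band."""

    band: Band
    rows: pd.DataFrame  # columns: donor, acceptor, V_cm-1, rho_cm, k_ns-1

    def to_text(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6e")


def site_eet_summary(
    coupling: CouplingMatrix,
    library: SpectralLibrary,
    ic_model: ICModel,
    classes: dict,
) -> tuple[RateTable, pd.DataFrame]:
    """Per-donor-site FRET rates to all other sites and EET efficiencies.

    rho is computed once per ordered (donor class, acceptor class) pair —
    class-level spectral granularity — and shared across site pairs.  Each
    donor's efficiency pits the sum of its outgoing FRET rates against that
    donor's single IC channel for the band.
    """
    band = coupling.band
    ids = coupling.site_ids
    rho_cache: dict = {}

    def rho_for(dc: PigmentClass, ac: PigmentClass) -> float:
        key = (dc, ac)
        if key not in rho_cache:
            rho_cache[key] = class_pair_rho(library, dc, ac, band)
        return rho_cache[key]

    rows = []
    eff_rows = []
    for i, donor in enumerate(ids):
        donor_class = classes[donor]
        k_out = []
        for j, acceptor in enumerate(ids):
            if i == j:
                continue
            v = float(coupling.matrix[i, j])
            rho = rho_for(donor_class, classes[acceptor])
            k = fret_rate(v, rho)
            k_out.append(k)
            rows.append(
                {
                    "donor": donor,
                    "acceptor": acceptor,
                    "band": band.value,
                    "V_cm-1": v,
                    "rho_cm": rho,
                    "k_ns-1": k,
                }
            )
        k_ic = ic_rate(ic_model, donor_class, band)
        eff_rows.append(
            {
                "donor": donor,
                "class": donor_class.value,
                "band": band.value,
                "sum_k_fret_ns-1": float(sum(k_out)),
                "k_ic_ns-1": k_ic,
                "efficiency": eet_efficiency(k_out, [k_ic]) if k_out else 0.0,
            }
        )
    table = RateTable(band=band, rows=pd.DataFrame(rows))
    return table, pd.DataFrame(eff_rows)


def export_efficiencies(efficiencies: pd.DataFrame, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Write the per-donor efficiency report as JSON."""
    payload = {
        "metadata": metadata or {},
        "donors": efficiencies.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
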