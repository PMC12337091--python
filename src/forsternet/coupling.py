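"""Point-dipole Förster couplings and class-pair averaging.

The screened point-dipole coupling between transition dipoles i and j is

    V_ij = C_dip * kappa_ij * |mu_i| |mu_j| / (n^2 R_ij^3)      [cm^-1]

with mu in Debye, R in nm, n the medium refractive index (1.4 by default
for a protein environment) and

    kappa_ij = u_i . u_j - 3 (u_i . r_hat)(u_j . r_hat),   kappa in [-2, 2].

C_dip is derived from first principles in :mod:`forsternet.units`
(~5.034 cm^-1 nm^3 D^-2).  Class-pair averages follow the multimer
convention: average |V| over all cross-pairs of the full assembly, then
multiply by the multimeric order q so trimer/tetramer values are
comparable to monomeric complexes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CLASS_ORDER, Band, PigmentClass
from .units import C_DIP_CM1_NM3_PER_D2

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Medium:
    """Dielectric environment entering the coupling screening as 1/n^2."""

    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass
class TransitionDipole:
    """A band-specific point transition dipole anchored at a pigment centre."""

    site_id: str
    band: Band
    direction: np.ndarray  # unit 3-vector
    magnitude_debye: float
    origin_angstrom: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise ValueError(f"dipole direction for {self.site_id} is not unit length")
        if self.magnitude_debye < 0:
            raise ValueError("dipole magnitude must be non-negative")
        self.direction = d
        self.origin_angstrom = np.asarray(self.origin_angstrom, dtype=float)


@dataclass
class CouplingMatrix:
    """Symmetric matrix of pairwise couplings V_ij in cm^-1, zero diagonal."""

    band: Band
    site_ids: list
    matrix: np.ndarray  # (N, N)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.site_ids), len(self.site_ids)):
            raise ValueError("matrix shape does not match site count")
        if not np.all(np.isfinite(m)):
            raise ValueError("couplings must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("coupling diagonal must be zero")
        self.matrix = m

    def value(self, site_i: str, site_j: str) -> float:
        i = self.site_ids.index(site_i)
        j = self.site_ids.index(site_j)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.site_ids, columns=self.site_ids)


def orientation_factor(u_i: np.ndarray, u_j: np.ndarray, r_ij: np.ndarray) -> float:
    """Dipole-dipole orientation factor kappa, bounded in [-2, 2]."""
    r = np.asarray(r_ij, dtype=float)
    norm = np.linalg.norm(r)
    if norm <= 0:
        raise ValueError("pigment separation vector has zero length")
    r_hat = r / norm
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    return float(u_i @ u_j - 3.0 * (u_i @ r_hat) * (u_j @ r_hat))


def point_dipole_coupling(
    d_i: TransitionDipole, d_j: TransitionDipole, medium: Medium = Medium()
) -> float:
    """Screened point-dipole coupling V_ij in cm^-1; sign follows kappa."""
    if d_i.band is not d_j.band:
        raise ValueError(f"band mismatch: {d_i.band.value} vs {d_j.band.value}")
    r_vec = d_j.origin_angstrom - d_i.origin_angstrom
    r_nm = np.linalg.norm(r_vec) / ANGSTROM_PER_NM
    if r_nm <= 0:
        raise ValueError(f"coincident dipole origins for {d_i.site_id}/{d_j.site_id}")
    kappa = orientation_factor(d_i.direction, d_j.direction, r_vec)
    return (
        C_DIP_CM1_NM3_PER_D2
        * kappa
        * d_i.magnitude_debye
        * d_j.magnitude_debye
        / (medium.refractive_index**2 * r_nm**3)
    )


def coupling_matrix(
    site_ids: Sequence[str],
    dipoles: dict,
    band: Band,
    medium: Medium = Medium(),
) -> CouplingMatrix:
    """Assemble the full symmetric coupling matrix for one band.

    ``dipoles`` maps site_id -> TransitionDipole (for this band).  Each
    unordered pair is computed once and mirrored, so symmetry is exact.
    """
    n = len(site_ids)
    for sid in site_ids:
        if sid not in dipoles:
            raise KeyError(f"no {band.value}-band dipole for site {sid}")
        if dipoles[sid].band is not band:
            raise ValueError(f"dipole for site {sid} is not band {band.value}")
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        v = point_dipole_coupling(dipoles[site_ids[i]], dipoles[site_ids[j]], medium)
        m[i, j] = m[j, i] = v
    return CouplingMatrix(band=band, site_ids=list(site_ids), matrix=m)


def _canonical_pair(a: PigmentClass, b: PigmentClass) -> tuple[PigmentClass, PigmentClass]:
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    return (a, b) if order[a] <= order[b] else (b, a)


def class_pair_averages(
    matrix: CouplingMatrix,
    classes: dict,
    multimer_order: int = 1,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Mean coupling per unordered pigment-class pair, multimer-scaled.

    For each class pair the mean of |V| (mode="absolute", the default used
    for reports) or of signed V (mode="signed") is taken over every
    cross-pair in the full assembly and multiplied by ``multimer_order`` q.
    Averaging over a q-mer and rescaling by q compensates for the many
    near-zero inter-subunit pairs, making q-mer values comparable to
    monomers.  The standard error of the mean uses the number of
    contributing pairs as the sample size.
    """
    if multimer_order < 1:
        raise ValueError("multimer order must be >= 1")
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    values: dict = {}
    ids = matrix.site_ids
    for i, j in combinations(range(len(ids)), 2):
        key = _canonical_pair(classes[ids[i]], classes[ids[j]])
        v = matrix.matrix[i, j]
        values.setdefault(key, []).append(abs(v) if mode == "absolute" else v)
    rows = []
    present = {c for c in classes.values()}
    for a, b in combinations_with_self(sorted(present, key=list(CLASS_ORDER).index)):
        key = _canonical_pair(a, b)
        if key not in values:
            continue  # class pair with zero cross-pairs is omitted
        arr = np.asarray(values[key])
        mean = arr.mean() * multimer_order
        sem = (arr.std(ddof=1) / np.sqrt(arr.size) * multimer_order) if arr.size > 1 else 0.0
        rows.append(
            {
                "class_i": key[0].value,
                "class_j": key[1].value,
                "band": matrix.band.value,
                "mean_V_cm-1": mean,
                "sem_cm-1": sem,
                "n_pairs": int(arr.size),
                "multimer_order": multimer_order,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)


def combinations_with_self(items: Sequence) -> list:
    """Unordered pairs including self-pairs, preserving input order."""
    out = []
    for i, a in enumerate(items):
        for b in items[i:]:
            out.append((a, b))
    return out


def export_coupling(
    matrix: CouplingMatrix,
    path: str | Path,
    metadata: Optional[dict] = None,
) -> None:
    """Write a coupling matrix as delimited text with a metadata header."""
    meta = {"band": matrix.band.value, **(metadata or {})}
    header = "# " + json.dumps(meta, sort_keys=True)
    frame = matrix.to_frame()
    body = frame.to_csv(sep="\t", float_format="%.6e")
    Path(path).write_text(header + "\n" + body)


def dipoles_for_band(pigments, axis_table, library, band: Band) -> dict:
    """site_id -> TransitionDipole for one band, from geometry + library.

    Direction comes from the structure's axis atoms, magnitude from the
    class-level dipole strength of the spectral library (carotenoids fall
    back to their single bright band).
    """
    from .structure_io import dipole_axis

    out = {}
    for p in pigments:
        try:
            mag = library.dipole(p.pigment_class, band)
        except KeyError:
            mag = library.dipole(p.pigment_class, Band.B)
        out[p.site_id] = TransitionDipole(
            site_id=p.site_id,
            band=band,
            direction=dipole_axis(p, band, axis_table),
            magnitude_debye=mag,
            origin_angstrom=p.center,
        )
    return out
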