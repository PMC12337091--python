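"""Pigment extraction from structure files and geometry conventions.

Pigment cofactors (chlorophylls a/b/c1 and carotenoids) are pulled out of
PDB/mmCIF files as hetero-residues.  The geometric conventions are:

* chlorophyll centre = the Mg coordinate;
* carotenoid centre  = unweighted centroid of the conjugated carbon atoms
  (all carbons are mass-equal, so centroid = centre of mass);
* transition-dipole axis = the unit vector between two named atoms,
  standing in for the Q_y or B_x state orientation.

The residue-name -> class mapping and the per-class/band axis-atom pairs
are shipped as documented, overridable conventions (delimited-text
loadable), not as claims about any particular deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import Band, PigmentClass

__all__ = [
    "Pigment",
    "AxisTable",
    "ResidueMap",
    "ParseReport",
    "default_residue_map",
    "default_axis_table",
    "parse_pigment_sites",
    "pigment_center",
    "dipole_axis",
    "export_inventory",
]


@dataclass
class Pigment:
    """One pigment cofactor site extracted from a structure."""

    site_id: str
    chain_id: str
    pigment_class: PigmentClass
    subtype: str  # e.g. "lutein", "chl_a"; mirrors the class for Chls
    atoms: list  # list of (atom_name, element, xyz ndarray (3,)) in Angstrom
    center: np.ndarray  # (3,) Angstrom
    monomer_index: int = 0

    def atom_xyz(self, name: str) -> np.ndarray:
        for atom_name, _el, xyz in self.atoms:
            if atom_name == name:
                return np.asarray(xyz, dtype=float)
        raise KeyError(f"site {self.site_id}: atom {name!r} not present")

    def has_atom(self, name: str) -> bool:
        return any(atom_name == name for atom_name, _el, _xyz in self.atoms)


@dataclass
class ResidueMap:
    """Residue-name -> (pigment class, subtype) mapping.

    A total function on the residue names the caller selects; anything not
    listed is reported by the parser, never silently classified.
    """

    mapping: dict

    def lookup(self, residue_name: str) -> Optional[tuple[PigmentClass, str]]:
        return self.mapping.get(residue_name.upper())

    @classmethod
    def from_text(cls, path: str | Path) -> "ResidueMap":
        """Load from delimited text: residue_name <tab> class <tab> subtype."""
        mapping = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, cls_name, subtype = line.split()[:3]
            mapping[name.upper()] = (PigmentClass(cls_name.lower()), subtype)
        return cls(mapping)


def default_residue_map() -> ResidueMap:
    """Common wwPDB chemical-component codes for LHC pigments.

    A convention, config-overridable; not a claim about any one entry's
    exact cofactor selection.
    """
    m = {
        "CLA": (PigmentClass.CHL_A, "chl_a"),
        "CHL": (PigmentClass.CHL_B, "chl_b"),
        "KC1": (PigmentClass.CHL_C1, "chl_c1"),
        "KC2": (PigmentClass.CHL_C1, "chl_c2"),
        "LUT": (PigmentClass.CRT, "lutein"),
        "XAT": (PigmentClass.CRT, "violaxanthin"),
        "NEX": (PigmentClass.CRT, "neoxanthin"),
        "NEO": (PigmentClass.CRT, "neoxanthin"),
        "BCR": (PigmentClass.CRT, "beta_carotene"),
        "DD6": (PigmentClass.CRT, "diadinoxanthin"),
        "A86": (PigmentClass.CRT, "fucoxanthin"),
        "FXA": (PigmentClass.CRT, "fucoxanthin"),
    }
    return ResidueMap(m)


@dataclass
class AxisTable:
    """Atom-pair table for transition-dipole axes and Crt conjugated atoms.

    ``axis_atoms`` maps (pigment class or subtype key, band) to an ordered
    atom-name pair; ``conjugated_atoms`` maps a Crt subtype (or the class
    key "crt") to the atom names whose centroid defines the carotenoid
    centre.  Entries keyed by subtype take precedence over class keys.
    """

    axis_atoms: dict
    conjugated_atoms: dict = field(default_factory=dict)

    def axis_pair(self, pigment: Pigment, band: Band) -> tuple[str, str]:
        for key in (pigment.subtype, pigment.pigment_class.value):
            if (key, band) in self.axis_atoms:
                a, b = self.axis_atoms[(key, band)]
                if a == b:
                    raise ValueError(f"axis atoms for {key}/{band.value} are not distinct")
                return a, b
        raise KeyError(
            f"no dipole-axis entry for {pigment.subtype}/{pigment.pigment_class.value} "
            f"band {band.value}"
        )

    def conjugated(self, pigment: Pigment) -> Optional[Sequence[str]]:
        for key in (pigment.subtype, pigment.pigment_class.value):
            if key in self.conjugated_atoms:
                return self.conjugated_atoms[key]
        return None

    @classmethod
    def from_text(cls, path: str | Path) -> "AxisTable":
        """Load axis entries from delimited text: key <tab> band <tab> atom1 <tab> atom2.

        Lines of the form ``key  CONJ  name1 name2 ...`` populate the
        conjugated-atom lists instead.
        """
        axis_atoms, conjugated = {}, {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0].lower()
            if parts[1].upper() == "CONJ":
                conjugated[key] = tuple(parts[2:])
            else:
                axis_atoms[(key, Band(parts[1].upper()))] = (parts[2], parts[3])
        return cls(axis_atoms, conjugated)


def default_axis_table() -> AxisTable:
    """Shipped placeholder axes using standard chlorin nitrogen names.

    Q_y is taken along the NB-ND trans-axis and B_x along NA-NC; these are
    documented placeholders following the usual Gouterman orientation and
    should be overridden from a curated table for production use.
    """
    axis_atoms = {}
    for cls_key in ("chl_a", "chl_b", "chl_c1"):
        axis_atoms[(cls_key, Band.Q)] = ("NB", "ND")
        axis_atoms[(cls_key, Band.B)] = ("NA", "NC")
    # carotenoid bright state is polarized along the polyene chain; C6-C31
    # spans the conjugated region in common xanthophyll numbering
    axis_atoms[("crt", Band.B)] = ("C6", "C31")
    axis_atoms[("crt", Band.Q)] = ("C6", "C31")
    return AxisTable(axis_atoms=axis_atoms, conjugated_atoms={})


@dataclass
class ParseReport:
    """What the parser matched and what it skipped."""

    n_pigments: int
    skipped: list  # (chain_id, residue_name, residue_number)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"matched pigments: {self.n_pigments}"]
        if self.skipped:
            lines.append(f"skipped hetero-residues ({len(self.skipped)}):")
            lines += [f"  {c}/{n} {r}" for c, r, n in self.skipped]
        return "\n".join(lines)


class EmptyInventoryError(ValueError):
    """No hetero-residue in the file matched the residue map."""


def _load_structure(structure_source: str | Path):
    import gemmi

    path = Path(structure_source)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ValueError(f"cannot read structure file {path}: {exc}") from exc
    st.setup_entities()
    return st


def parse_pigment_sites(
    structure_source: str | Path,
    residue_map: Optional[ResidueMap] = None,
    chain_filter: Optional[Iterable[str]] = None,
    axis_table: Optional[AxisTable] = None,
) -> tuple[list[Pigment], ParseReport]:
    """Extract pigment sites from a PDB/mmCIF file.

    Returns one :class:`Pigment` per matched hetero-residue plus a report of
    skipped residues.  ``monomer_index`` is assigned from chain grouping
    (chains in file order), standing in for multimer subunits.  Ordering is
    fixed: chain order, then residue number.
    """
    residue_map = residue_map or default_residue_map()
    axis_table = axis_table or default_axis_table()
    st = _load_structure(structure_source)
    model = st[0]
    wanted = set(chain_filter) if chain_filter is not None else None

    pigments: list[Pigment] = []
    skipped: list = []
    for mono_idx, chain in enumerate(model):
        if wanted is not None and chain.name not in wanted:
            continue
        for residue in chain:
            hit = residue_map.lookup(residue.name)
            if hit is None:
                # only report hetero-ish residues, not polymer backbone
                import gemmi

                info = gemmi.find_tabulated_residue(residue.name)
                is_polymer = info is not None and (info.is_amino_acid() or info.is_nucleic_acid())
                if not is_polymer:
                    skipped.append((chain.name, residue.name, residue.seqid.num))
                continue
            cls, subtype = hit
            atoms = [
                (atom.name, atom.element.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                for atom in residue
            ]
            pig = Pigment(
                site_id=f"{chain.name}:{residue.seqid.num}",
                chain_id=chain.name,
                pigment_class=cls,
                subtype=subtype,
                atoms=atoms,
                center=np.zeros(3),
                monomer_index=mono_idx,
            )
            pig.center = pigment_center(pig, axis_table)
            pigments.append(pig)
    pigments.sort(key=lambda p: (p.monomer_index, p.chain_id, p.site_id))
    if not pigments:
        raise EmptyInventoryError(
            f"{structure_source}: no hetero-residue matched the residue map "
            f"({len(skipped)} unmatched)"
        )
    return pigments, ParseReport(len(pigments), skipped)


def pigment_center(pigment: Pigment, axis_table: Optional[AxisTable] = None) -> np.ndarray:
    """Geometric centre used as the point-dipole origin.

    Chlorophylls: the Mg coordinate, exactly.  Carotenoids: unweighted
    centroid of the conjugated carbon atoms — the atoms named in the axis
    table if provided, else every carbon in the residue.
    """
    if pigment.pigment_class.is_chlorophyll:
        mg = [xyz for name, el, xyz in pigment.atoms if el.upper() == "MG" or name == "MG"]
        if len(mg) != 1:
            raise ValueError(
                f"site {pigment.site_id}: chlorophyll requires exactly one Mg atom, "
                f"found {len(mg)}"
            )
        return np.asarray(mg[0], dtype=float)
    names = axis_table.conjugated(pigment) if axis_table is not None else None
    if names:
        coords = [pigment.atom_xyz(n) for n in names if pigment.has_atom(n)]
    else:
        coords = [xyz for _name, el, xyz in pigment.atoms if el.upper() == "C"]
    if not coords:
        raise ValueError(f"site {pigment.site_id}: no conjugated carbon atoms for centre")
    return np.mean(np.asarray(coords, dtype=float), axis=0)


def dipole_axis(pigment: Pigment, band: Band, axis_table: AxisTable) -> np.ndarray:
    """Unit vector from the first to the second axis atom of the band."""
    name_a, name_b = axis_table.axis_pair(pigment, band)
    vec = pigment.atom_xyz(name_b) - pigment.atom_xyz(name_a)
    norm = float(np.linalg.norm(vec))
    if norm < 1e-6:
        raise ValueError(
            f"site {pigment.site_id}: degenerate dipole axis {name_a}-{name_b} "
            f"(separation {norm:.2e} A)"
        )
    return vec / norm


def export_inventory(pigments: Sequence[Pigment], path: str | Path) -> None:
    """Write the pigment inventory as a delimited table."""
    lines = ["site_id\tclass\tsubtype\tcenter_x\tcenter_y\tcenter_z\tmonomer_index"]
    for p in pigments:
        cx, cy, cz = p.center
        lines.append(
            f"{p.site_id}\t{p.pigment_class.value}\t{p.subtype}\t"
            f"{cx:.4f}\t{cy:.4f}\t{cz:.4f}\t{p.monomer_index}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
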