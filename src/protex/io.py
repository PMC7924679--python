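"""PDB-format structure input/output.

Structures are kept as flat, file-ordered lists of atom records: the
downstream feature pipeline depends on file order (the atomic-mass feature
uses the *first* 100 atoms) and never needs the residue/chain hierarchy.
Parsing is backed by Biopython's :class:`Bio.PDB.PDBParser`; only the first
MODEL is kept and disordered atoms resolve to their default (altloc 'A')
conformer, the standard convention for single-conformer analyses.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "PdbParseError",
    "NoAlphaCarbonsError",
    "parse_pdb",
    "alpha_carbon_coordinates",
    "all_atom_coordinates",
    "write_pdb",
]

STRUCTURE_KINDS = ("protein", "ligand")


class PdbParseError(ValueError):
    """Raised when a PDB text contains no usable atom records."""


class NoAlphaCarbonsError(ValueError):
    """Raised when a protein structure has no CA atoms to image."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record: element, name and Cartesian coordinates (Å)."""

    serial: int
    element: str
    name: str
    coords: tuple[float, float, float]
    residue_index: int

    def __post_init__(self) -> None:
        if not self.element or not self.element.isupper():
            raise ValueError(f"element must be a non-empty uppercase symbol, got {self.element!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")


@dataclass
class MolecularStructure:
    """An ordered list of atoms tagged as protein or ligand."""

    id: str
    kind: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"kind must be one of {STRUCTURE_KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.atoms)


def _element_of(atom, name: str) -> str:
    element = (atom.element or "").strip().upper()
    if not element:
        # fall back to the first alphabetic character of the atom name
        for ch in name:
            if ch.isalpha():
                element = ch.upper()
                break
    return element


def parse_pdb(text: str, kind: str, structure_id: str = "structure") -> MolecularStructure:
    """Parse PDB-format text into a :class:`MolecularStructure`.

    Every ATOM/HETATM record of the first model with finite coordinates
    becomes one :class:`AtomRecord`, in file order; all chains are
    concatenated.

    Raises
    ------
    PdbParseError
        If no atom record can be parsed.
    """
    if kind not in STRUCTURE_KINDS:
        raise ValueError(f"kind must be one of {STRUCTURE_KINDS}, got {kind!r}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio_structure = parser.get_structure(structure_id, _io.StringIO(text))
        except Exception as exc:  # malformed beyond recovery
            raise PdbParseError(f"{structure_id}: unparseable PDB text ({exc})") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise PdbParseError(f"{structure_id}: no parseable atom records")

    atoms: list[AtomRecord] = []
    for chain in models[0]:
        for residue in chain:
            for atom in residue:
                # PDB coordinate columns carry exactly 3 decimals; rounding
                # removes the float32 noise of the parser's internal storage
                coords = np.round(np.asarray(atom.get_coord(), dtype=float), 3)
                if not np.all(np.isfinite(coords)):
                    continue
                name = atom.get_name().strip()
                element = _element_of(atom, name)
                if not element:
                    continue
                atoms.append(
                    AtomRecord(
                        serial=int(atom.get_serial_number() or (len(atoms) + 1)),
                        element=element,
                        name=name,
                        coords=(float(coords[0]), float(coords[1]), float(coords[2])),
                        residue_index=int(residue.id[1]),
                    )
                )
    if not atoms:
        raise PdbParseError(f"{structure_id}: no parseable atom records")
    return MolecularStructure(id=structure_id, kind=kind, atoms=atoms)


def alpha_carbon_coordinates(structure: MolecularStructure) -> np.ndarray:
    """Coordinates of all CA atoms in file order, shape (n_residues, 3).

    Only α-carbons represent a protein in the imaging pipeline.
    """
    if structure.kind != "protein":
        raise ValueError(f"{structure.id}: alpha carbons requested from a {structure.kind}")
    coords = [a.coords for a in structure.atoms if a.name == "CA"]
    if not coords:
        raise NoAlphaCarbonsError(f"{structure.id}: no CA atoms; protein unusable for imaging")
    return np.asarray(coords, dtype=float)


def all_atom_coordinates(structure: MolecularStructure) -> np.ndarray:
    """Coordinates of every atom in file order, shape (n_atoms, 3)."""
    if not structure.atoms:
        raise ValueError(f"{structure.id}: structure has no atoms")
    return np.asarray([a.coords for a in structure.atoms], dtype=float)


_PDB_LINE = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2}\n"
)


def write_pdb(structure: MolecularStructure) -> str:
    """Serialize a structure to fixed-column PDB text.

    Proteins get ATOM records (residue ALA), ligands HETATM (residue LIG);
    coordinates land in columns 31-54 and the element symbol in 77-78, the
    dialect :func:`parse_pdb` reads back.
    """
    record = "ATOM" if structure.kind == "protein" else "HETATM"
    resname = "ALA" if structure.kind == "protein" else "LIG"
    lines = []
    for atom in structure.atoms:
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
        lines.append(
            _PDB_LINE.format(
                record=record,
                serial=atom.serial,
                name=name,
                altloc=" ",
                resname=resname,
                chain="A",
                resseq=atom.residue_index,
                icode=" ",
                x=atom.coords[0],
                y=atom.coords[1],
                z=atom.coords[2],
                occ=1.0,
                b=0.0,
                element=atom.element[:2],
            )
        )
    lines.append("END\n")
    return "".join(lines)
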