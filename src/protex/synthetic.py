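"""Synthetic structures and binding datasets with known ground truth.

Real benchmark collections (SCOPe domain files, experimental protein-ligand
complexes) are large external downloads; this module generates small
PDB-format stand-ins with controllable structure so every pipeline stage is
testable end to end:

* proteins — Cα chains at the canonical ~3.8 Å spacing, either ideal
  α-helices (periodic distance-matrix texture) or random walks (irregular
  texture), with N/C/O backbone decoy atoms at covalent offsets so the
  atom-bond features have something to count;
* ligands — compact multi-atom HETATM clusters, including the single-atom
  case that the imaging stage must reject;
* binding datasets — proteins and ligands planted in groups whose geometry
  parameters are offset by a ``separation`` knob; positives are
  within-group pairs only, so a similarity-based predictor should recover
  held-out within-group pairs when separation dominates noise and fall to
  chance at zero separation.

All outputs are bit-reproducible from their recipe and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AtomRecord, MolecularStructure, write_pdb

__all__ = [
    "ChainRecipe",
    "helix_coordinates",
    "random_walk_coordinates",
    "synthetic_protein",
    "synthetic_ligand",
    "BindingDataset",
    "synthetic_binding_dataset",
]

CA_STEP = 3.8  # canonical consecutive-Calpha distance, Å


@dataclass(frozen=True)
class ChainRecipe:
    """Recipe for one synthetic Cα chain."""

    n_residues: int = 48
    geometry: str = "helix"  # "helix" or "random_walk"
    step: float = CA_STEP
    rise: float = 1.5  # helix rise per residue, Å
    turn_deg: float = 100.0  # helix turn per residue, degrees
    noise_sigma: float = 0.05  # isotropic coordinate noise, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.geometry not in ("helix", "random_walk"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def helix_coordinates(recipe: ChainRecipe, rng: np.random.Generator) -> np.ndarray:
    """Ideal helix Cα trace plus noise.

    The radius is derived from (step, rise, turn) so consecutive Cα atoms
    sit exactly ``step`` apart before noise.
    """
    turn = np.deg2rad(recipe.turn_deg)
    chord = np.sqrt(max(recipe.step**2 - recipe.rise**2, 1e-9))
    radius = chord / (2.0 * np.sin(turn / 2.0))
    i = np.arange(recipe.n_residues)
    coords = np.stack(
        [radius * np.cos(i * turn), radius * np.sin(i * turn), recipe.rise * i], axis=1
    )
    return coords + rng.normal(0.0, recipe.noise_sigma, size=coords.shape)


def random_walk_coordinates(recipe: ChainRecipe, rng: np.random.Generator) -> np.ndarray:
    """Fixed-step random walk Cα trace plus noise."""
    directions = rng.normal(size=(recipe.n_residues - 1, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(recipe.step * directions, axis=0)])
    return coords + rng.normal(0.0, recipe.noise_sigma, size=coords.shape)


# covalent offsets of backbone decoy atoms relative to each Cα (Å)
_BACKBONE_OFFSETS = (
    ("N", "N", np.array([-1.46, 0.0, 0.0])),
    ("C", "C", np.array([0.0, 1.52, 0.0])),
    ("O", "O", np.array([0.0, 1.52, 1.23])),  # carbonyl O bonded to that C
)


def synthetic_protein(recipe: ChainRecipe, structure_id: str = "prot"):
    """Generate one protein: (PDB text, Cα coordinate log).

    Each residue carries N, CA, C, O records (in that order) so the file
    exercises both the CA filter and the atom-bond census; the coordinate
    log holds the Cα positions exactly as written (3 decimals).
    """
    rng = np.random.default_rng(recipe.seed)
    if recipe.geometry == "helix":
        ca = helix_coordinates(recipe, rng)
    else:
        ca = random_walk_coordinates(recipe, rng)
    ca = np.round(ca, 3)  # PDB columns carry 3 decimals; log what is written
    atoms = []
    serial = 1
    for res, pos in enumerate(ca, start=1):
        n_pos = np.round(pos + _BACKBONE_OFFSETS[0][2], 3)
        c_pos = np.round(pos + _BACKBONE_OFFSETS[1][2], 3)
        o_pos = np.round(pos + _BACKBONE_OFFSETS[2][2], 3)
        for name, element, xyz in (
            ("N", "N", n_pos),
            ("CA", "C", pos),
            ("C", "C", c_pos),
            ("O", "O", o_pos),
        ):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    element=element,
                    name=name,
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    residue_index=res,
                )
            )
            serial += 1
    structure = MolecularStructure(id=structure_id, kind="protein", atoms=atoms)
    return write_pdb(structure), ca


_LIGAND_ELEMENTS = ("C", "N", "O", "S")


def synthetic_ligand(
    n_atoms: int,
    seed: int = 0,
    structure_id: str = "lig",
    template: np.ndarray | None = None,
    noise_sigma: float = 0.05,
) -> str:
    """Generate one compact multi-atom ligand as PDB text.

    Atom positions come from ``template`` (shape (n_atoms, 3)) when given,
    else from a seeded compact cluster with ~1.5 Å nearest-neighbor
    spacing. ``n_atoms = 1`` is supported deliberately: downstream imaging
    must reject it.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    if template is None:
        template = 1.5 * rng.normal(size=(n_atoms, 3))
    template = np.asarray(template, dtype=float)
    if template.shape != (n_atoms, 3):
        raise ValueError("template must have shape (n_atoms, 3)")
    coords = np.round(template + rng.normal(0.0, noise_sigma, size=template.shape), 3)
    atoms = [
        AtomRecord(
            serial=i + 1,
            element=_LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)],
            name=f"{_LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)]}{i + 1}",
            coords=(float(c[0]), float(c[1]), float(c[2])),
            residue_index=1,
        )
        for i, c in enumerate(coords)
    ]
    return write_pdb(MolecularStructure(id=structure_id, kind="ligand", atoms=atoms))


@dataclass
class BindingDataset:
    """Planted-group binding dataset: structures, pairs and ground truth."""

    proteins: dict[str, str]  # id -> PDB text
    ligands: dict[str, str]
    train_positive: list[tuple[str, str]]
    heldout_positive: list[tuple[str, str]]
    heldout_negative: list[tuple[str, str]]
    protein_group: dict[str, int] = field(default_factory=dict)
    ligand_group: dict[str, int] = field(default_factory=dict)


def synthetic_binding_dataset(
    n_groups: int = 5,
    proteins_per_group: int = 20,
    ligands_per_group: int = 20,
    separation: float = 1.0,
    noise: float = 0.05,
    seed: int = 0,
    train_pairs_per_group: int = 40,
    heldout_pairs_per_group: int = 10,
    n_residues: int = 48,
    ligand_atoms: int = 10,
) -> BindingDataset:
    """Generate a binding dataset whose positives are within-group pairs.

    Group g's proteins are helices whose turn angle is offset from 100° by
    ``8° * separation * (g - (G-1)/2)``; group g's ligands morph between a
    common atom template and a group-specific one with weight
    ``min(separation, 1)``. At ``separation = 0`` every group is generated
    from identical parameters, leaving only noise — no recoverable signal.

    Training positives and held-out positives are disjoint within-group
    pairs (``train_pairs_per_group`` / ``heldout_pairs_per_group`` each per
    group); held-out negatives are cross-group pairs matched in total count
    to the held-out positives.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    rng = np.random.default_rng(seed)
    morph = min(max(separation, 0.0), 1.0)

    proteins: dict[str, str] = {}
    ligands: dict[str, str] = {}
    protein_group: dict[str, int] = {}
    ligand_group: dict[str, int] = {}
    common_template = 1.5 * np.random.default_rng(seed + 10_000).normal(size=(ligand_atoms, 3))
    for g in range(n_groups):
        turn = 100.0 + 8.0 * separation * (g - (n_groups - 1) / 2.0)
        group_template_rng = np.random.default_rng(seed + 20_000 + g)
        group_template = 1.5 * group_template_rng.normal(size=(ligand_atoms, 3))
        ligand_template = (1.0 - morph) * common_template + morph * group_template
        for i in range(proteins_per_group):
            pid = f"P{g}_{i:03d}"
            recipe = ChainRecipe(
                n_residues=n_residues,
                geometry="helix",
                turn_deg=turn,
                noise_sigma=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            proteins[pid], _ = synthetic_protein(recipe, structure_id=pid)
            protein_group[pid] = g
        for i in range(ligands_per_group):
            lid = f"L{g}_{i:03d}"
            ligands[lid] = synthetic_ligand(
                ligand_atoms,
                seed=int(rng.integers(0, 2**31 - 1)),
                structure_id=lid,
                template=ligand_template,
                noise_sigma=noise,
            )
            ligand_group[lid] = g

    train_positive: list[tuple[str, str]] = []
    heldout_positive: list[tuple[str, str]] = []
    heldout_negative: list[tuple[str, str]] = []
    for g in range(n_groups):
        group_pairs = [
            (p, l)
            for p in sorted(pid for pid, gg in protein_group.items() if gg == g)
            for l in sorted(lid for lid, gg in ligand_group.items() if gg == g)
        ]
        wanted = train_pairs_per_group + heldout_pairs_per_group
        if wanted > len(group_pairs):
            raise ValueError("not enough within-group pairs for the requested counts")
        picked = rng.choice(len(group_pairs), size=wanted, replace=False)
        train_positive.extend(group_pairs[i] for i in picked[:train_pairs_per_group])
        heldout_positive.extend(group_pairs[i] for i in picked[train_pairs_per_group:])

    n_negative = len(heldout_positive)
    protein_ids = sorted(proteins)
    ligand_ids = sorted(ligands)
    seen = set(train_positive) | set(heldout_positive)
    while len(heldout_negative) < n_negative:
        p = protein_ids[rng.integers(len(protein_ids))]
        l = ligand_ids[rng.integers(len(ligand_ids))]
        if protein_group[p] == ligand_group[l] or (p, l) in seen:
            continue
        seen.add((p, l))
        heldout_negative.append((p, l))

    return BindingDataset(
        proteins=proteins,
        ligands=ligands,
        train_positive=train_positive,
        heldout_positive=heldout_positive,
        heldout_negative=heldout_negative,
        protein_group=protein_group,
        ligand_group=ligand_group,
    )
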