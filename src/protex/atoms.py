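"""Atom-bond feature group.

Three blocks computed from the atom records alone (no imaging):

1. element composition — the percentage of the structure's atoms that each
   vocabulary element accounts for;
2. mass sequence — standard atomic masses of the first ``mass_prefix_length``
   atoms in file order, zero-padded;
3. bonded-pair percentages — pairs of vocabulary atoms closer than a distance
   threshold count as bonds; each unordered element pair's share of all bonds,
   in percent.

With the default vocabulary [C, N, O, S] and a 100-atom mass prefix the
concatenated vector has 4 + 100 + 10 = 114 entries. The 2.0 Å default
threshold covers covalent bond lengths between heavy atoms (C-C 1.54 Å,
C-N 1.47 Å, C-O 1.43 Å, C-S 1.82 Å) while excluding non-bonded contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial.distance import pdist

from .io import MolecularStructure

__all__ = [
    "ATOMIC_MASSES",
    "UnknownElementError",
    "AtomBondConfig",
    "element_composition",
    "mass_sequence",
    "bond_pair_percentages",
    "atom_bond_features",
    "derive_vocabulary",
    "DEFAULT_VOCABULARY",
]

with resources.files("protex.data").joinpath("atomic_masses.json").open() as _fh:
    ATOMIC_MASSES: dict[str, float] = json.load(_fh)

DEFAULT_VOCABULARY: tuple[str, ...] = ("C", "N", "O", "S")


class UnknownElementError(KeyError):
    """An element symbol missing from the atomic-mass table."""


@dataclass(frozen=True)
class AtomBondConfig:
    """Configuration of the atom-bond feature group."""

    bond_threshold: float = 2.0
    mass_prefix_length: int = 100
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        if self.bond_threshold <= 0:
            raise ValueError("bond_threshold must be positive")
        if self.mass_prefix_length < 1:
            raise ValueError("mass_prefix_length must be >= 1")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary must not contain duplicates")

    @property
    def n_features(self) -> int:
        v = len(self.vocabulary)
        return v + self.mass_prefix_length + v * (v + 1) // 2

    @property
    def pair_order(self) -> list[tuple[str, str]]:
        return list(combinations_with_replacement(self.vocabulary, 2))


def element_composition(
    structure: MolecularStructure, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
) -> np.ndarray:
    """Percentage of all atoms carried by each vocabulary element.

    Atoms outside the vocabulary contribute to the denominator only, so the
    vector sums to at most 100.
    """
    if not structure.atoms:
        raise ValueError(f"{structure.id}: empty structure")
    total = len(structure.atoms)
    counts = {e: 0 for e in vocabulary}
    for atom in structure.atoms:
        if atom.element in counts:
            counts[atom.element] += 1
    return np.array([100.0 * counts[e] / total for e in vocabulary])


def mass_sequence(structure: MolecularStructure, n: int = 100) -> np.ndarray:
    """Standard atomic masses of the first ``n`` atoms in file order, zero-padded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.zeros(n)
    for i, atom in enumerate(structure.atoms[:n]):
        try:
            out[i] = ATOMIC_MASSES[atom.element]
        except KeyError:
            raise UnknownElementError(
                f"{structure.id}: unknown element symbol {atom.element!r}"
            ) from None
    return out


def bond_pair_percentages(structure: MolecularStructure, cfg: AtomBondConfig = AtomBondConfig()) -> np.ndarray:
    """Share of bonds falling on each unordered vocabulary element pair, percent.

    A bond exists between two atoms when both elements are in the vocabulary
    and their distance is at most ``cfg.bond_threshold``. A structure with no
    bonds yields the all-zero vector (small ligands stay usable).
    """
    if not structure.atoms:
        raise ValueError(f"{structure.id}: empty structure")
    vocab = set(cfg.vocabulary)
    members = [a for a in structure.atoms if a.element in vocab]
    pair_index = {p: i for i, p in enumerate(cfg.pair_order)}
    counts = np.zeros(len(pair_index))
    if len(members) >= 2:
        coords = np.asarray([a.coords for a in members])
        vocab_idx = {e: i for i, e in enumerate(cfg.vocabulary)}
        e_idx = np.array([vocab_idx[a.element] for a in members])
        ii, jj = np.triu_indices(len(members), k=1)
        bonded = pdist(coords) <= cfg.bond_threshold
        for a, b in zip(e_idx[ii[bonded]], e_idx[jj[bonded]]):
            lo, hi = (a, b) if a <= b else (b, a)
            counts[pair_index[(cfg.vocabulary[lo], cfg.vocabulary[hi])]] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return 100.0 * counts / total


def atom_bond_features(structure: MolecularStructure, cfg: AtomBondConfig = AtomBondConfig()) -> np.ndarray:
    """Concatenated [composition | masses | pair percentages] vector."""
    return np.concatenate(
        [
            element_composition(structure, cfg.vocabulary),
            mass_sequence(structure, cfg.mass_prefix_length),
            bond_pair_percentages(structure, cfg),
        ]
    )


def derive_vocabulary(structures) -> tuple[str, ...]:
    """Dataset-scan mode: the sorted set of elements seen across structures."""
    seen: set[str] = set()
    for s in structures:
        seen.update(a.element for a in s.atoms)
    return tuple(sorted(seen))
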