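"""Per-structure feature assembly.

Five feature groups are computed from a structure:

========  ============================================  ======
group     descriptor                                    length
========  ============================================  ======
A         LBP histogram of the distance-matrix image       256
B         LBP histogram after Gabor filtering              256
C         atom-bond features (composition/masses/pairs)    114*
D         uniform-LBP histogram after the SRM filter        59
E         uniform-LBP histogram after the NBS filter        59
========  ============================================  ======

(*with the default 4-element vocabulary and 100-atom mass prefix.)

The hybrid vector concatenates A and B on the structure's native-size
image, C, and D and E on the image rescaled to 128x128 — 744 values with
defaults. Proteins are imaged from their α-carbons, ligands from all atoms.

:class:`StructureFeaturizer` wraps the assembly as a scikit-learn
transformer over lists of :class:`~protex.io.MolecularStructure`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import texture
from .atoms import AtomBondConfig, atom_bond_features
from .imaging import (
    DEFAULT_IMAGE_SIDE,
    SingleAtomImageError,
    matrix_to_image,
    pairwise_distance_matrix,
    rescale_image,
)
from .io import MolecularStructure, all_atom_coordinates, alpha_carbon_coordinates
from .texture import GaborParams

__all__ = [
    "GROUPS",
    "FeatureConfig",
    "structure_image",
    "extract_group",
    "hybrid_features",
    "pair_features",
    "feature_names",
    "hybrid_length",
    "StructureFeaturizer",
]

GROUPS = ("A", "B", "C", "D", "E")

# default image-scaling policy for the hybrid vector: A and B are computed on
# the native-size image, D and E on the 128x128 rescaled image.
HYBRID_SCALING = {"A": False, "B": False, "C": False, "D": True, "E": True}


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature pipeline shared by all groups."""

    atom_bond: AtomBondConfig = field(default_factory=AtomBondConfig)
    gabor: GaborParams = field(default_factory=GaborParams)
    image_side: int = DEFAULT_IMAGE_SIDE
    intensity_mode: str = "minmax"
    intensity_cap: float | None = None

    def group_length(self, group: str) -> int:
        if group in ("A", "B"):
            return 256
        if group == "C":
            return self.atom_bond.n_features
        if group in ("D", "E"):
            return 59
        raise ValueError(f"unknown feature group {group!r}")


def structure_image(
    structure: MolecularStructure, scaled: bool, cfg: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Grayscale distance-matrix image of a structure.

    Proteins use α-carbon coordinates, ligands all atoms. Single-coordinate
    structures are excluded (they would give a textureless 1x1 image).
    """
    if structure.kind == "protein":
        coords = alpha_carbon_coordinates(structure)
    else:
        coords = all_atom_coordinates(structure)
    if len(coords) < 2:
        raise SingleAtomImageError(
            f"{structure.id}: single-coordinate structure excluded from imaging"
        )
    image = matrix_to_image(
        pairwise_distance_matrix(coords), mode=cfg.intensity_mode, cap=cfg.intensity_cap
    )
    if scaled:
        image = rescale_image(image, cfg.image_side)
    return image


def extract_group(
    structure: MolecularStructure,
    group: str,
    scaled: bool = False,
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Feature vector of one group for one structure.

    Groups D and E are defined on scaled images only; requesting them
    unscaled is an error. The ``scaled`` flag is ignored for group C, which
    never touches the image.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown feature group {group!r}")
    if group == "C":
        return atom_bond_features(structure, cfg.atom_bond)
    if group in ("D", "E") and not scaled:
        raise ValueError(f"group {group} is defined on scaled images only")
    image = structure_image(structure, scaled=scaled, cfg=cfg)
    if group == "A":
        return texture.histogram_256(texture.lbp_transform(image)).astype(float)
    if group == "B":
        filtered = texture.gabor_filter_image(image, cfg.gabor)
        return texture.histogram_256(texture.lbp_transform(filtered)).astype(float)
    filt = texture.srm_filter if group == "D" else texture.nbs_filter
    return texture.uniform_histogram_59(texture.lbp_transform(filt(image))).astype(float)


def hybrid_features(structure: MolecularStructure, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """The full hybrid vector: A + B (native size) + C + D + E (scaled)."""
    return np.concatenate(
        [extract_group(structure, g, scaled=HYBRID_SCALING[g], cfg=cfg) for g in GROUPS]
    )


def hybrid_length(cfg: FeatureConfig = FeatureConfig(), groups=GROUPS) -> int:
    return sum(cfg.group_length(g) for g in groups)


def pair_features(protein_vector: np.ndarray, ligand_vector: np.ndarray) -> np.ndarray:
    """Protein-ligand pair vector: protein block followed by ligand block."""
    protein_vector = np.asarray(protein_vector, dtype=float)
    ligand_vector = np.asarray(ligand_vector, dtype=float)
    if protein_vector.size == 0 or ligand_vector.size == 0:
        raise ValueError("pair_features requires two non-empty vectors")
    return np.concatenate([protein_vector, ligand_vector])


def feature_names(groups=GROUPS, cfg: FeatureConfig = FeatureConfig()) -> list[str]:
    """Group-prefixed column names, e.g. A_000..A_255, D_00..D_58."""
    names: list[str] = []
    for g in groups:
        n = cfg.group_length(g)
        width = len(str(n - 1))
        names.extend(f"{g}_{i:0{width}d}" for i in range(n))
    return names


class StructureFeaturizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer turning structures into feature matrices.

    Parameters
    ----------
    groups : str, default "ABCDE"
        Which feature groups to concatenate, in order.
    scaling : {"hybrid", "scaled", "unscaled"}, default "hybrid"
        Image policy: ``hybrid`` uses native-size images for A/B and 128x128
        for D/E; ``scaled`` rescales for every image group; ``unscaled`` uses
        native-size images everywhere (invalid for D/E).
    config : FeatureConfig, optional
        Shared pipeline configuration.
    """

    def __init__(self, groups: str = "ABCDE", scaling: str = "hybrid", config: FeatureConfig | None = None):
        self.groups = groups
        self.scaling = scaling
        self.config = config

    def _cfg(self) -> FeatureConfig:
        return self.config if self.config is not None else FeatureConfig()

    def _scaled(self, group: str) -> bool:
        if self.scaling == "hybrid":
            return HYBRID_SCALING[group]
        if self.scaling == "scaled":
            return True
        if self.scaling == "unscaled":
            return False
        raise ValueError(f"unknown scaling policy {self.scaling!r}")

    def fit(self, X, y=None):
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown feature group {g!r}")
        self.n_features_out_ = sum(self._cfg().group_length(g) for g in self.groups)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._cfg()
        rows = [
            np.concatenate(
                [extract_group(s, g, scaled=self._scaled(g), cfg=cfg) for g in self.groups]
            )
            for s in X
        ]
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(tuple(self.groups), self._cfg()), dtype=object)
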