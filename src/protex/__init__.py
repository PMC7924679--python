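"""protex: image-based texture features from protein tertiary structures.

A protein's α-carbon pairwise distance matrix, viewed as a grayscale
image, carries texture that tracks the protein's fold. This package turns
that observation into fixed-length feature vectors (LBP histograms, Gabor-
filtered LBP, uniform-LBP after two block filters, and atom-bond
statistics), and builds two predictors on top: SMOTE-balanced structural
class classification and a similarity-based protein-ligand binding
predictor.
"""

from .atoms import AtomBondConfig, atom_bond_features
from .binding import ALL_CATEGORIES, DistanceCategory, SimilarityBindingClassifier
from .features import (
    FeatureConfig,
    StructureFeaturizer,
    extract_group,
    hybrid_features,
    pair_features,
)
from .imaging import matrix_to_image, pairwise_distance_matrix, rescale_image
from .io import MolecularStructure, parse_pdb, write_pdb
from .resampling import (
    SmoteOversampler,
    balance_training_set,
    cluster_negative_pairs,
    random_negative_pairs,
    smote_percentage,
)
from .evaluation import compute_metrics, run_class_experiment, stratified_folds
from .synthetic import (
    ChainRecipe,
    synthetic_binding_dataset,
    synthetic_ligand,
    synthetic_protein,
)
from .texture import GaborParams

__version__ = "0.1.0"

__all__ = [
    "AtomBondConfig",
    "atom_bond_features",
    "ALL_CATEGORIES",
    "DistanceCategory",
    "SimilarityBindingClassifier",
    "FeatureConfig",
    "StructureFeaturizer",
    "extract_group",
    "hybrid_features",
    "pair_features",
    "matrix_to_image",
    "pairwise_distance_matrix",
    "rescale_image",
    "MolecularStructure",
    "parse_pdb",
    "write_pdb",
    "SmoteOversampler",
    "balance_training_set",
    "cluster_negative_pairs",
    "random_negative_pairs",
    "smote_percentage",
    "compute_metrics",
    "run_class_experiment",
    "stratified_folds",
    "ChainRecipe",
    "synthetic_binding_dataset",
    "synthetic_ligand",
    "synthetic_protein",
    "GaborParams",
]
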