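"""High-level pipelines tying digestion, features, training and evaluation together."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .features import (
    FeatureRegistry,
    Standardizer,
    default_registry,
    estimate_cleavage_propensities,
)
from .network import ModelConfig, TrainedModel, build_network, train
from .proteins import ProteinRecord, parse_fasta
from .queries import (
    QueryGroup,
    load_intensity_table,
    training_targets,
)


def fit_model(
    train_groups: Sequence[QueryGroup],
    database: Sequence[ProteinRecord],
    config: Optional[ModelConfig] = None,
    registry: Optional[FeatureRegistry] = None,
    fit_propensities: bool = True,
) -> TrainedModel:
    """Train the rank regressor on ingested query groups.

    The cleavage-propensity table for the terminal digestion-probability
    features is estimated from the training table itself (unless a registry
    with fitted propensities is supplied or ``fit_propensities`` is False);
    features are standardized on the training matrix and the parameters are
    stored with the model.
    """
    if not train_groups:
        raise ValueError("no training groups")
    config = config or ModelConfig()
    registry = registry or default_registry()
    if fit_propensities:
        registry = registry.with_propensities(
            estimate_cleavage_propensities(train_groups, database))
    by_id = {p.id: p for p in database}

    peptides, targets, _ = training_targets(train_groups)
    X = registry.featurize_many(peptides, by_id)
    standardizer = Standardizer.fit(X)
    Xz = standardizer.apply(X)

    model = build_network(config, n_features=X.shape[1], registry=registry)
    model.standardizer = standardizer
    return train(model, Xz, targets, config)


def training_matrix(model: TrainedModel,
                    groups: Sequence[QueryGroup],
                    database: Sequence[ProteinRecord]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(standardized features, relevance targets) in the model's feature space."""
    by_id = {p.id: p for p in database}
    peptides, targets, _ = training_targets(groups)
    X = model.registry.featurize_many(peptides, by_id)
    if model.standardizer is not None:
        X = model.standardizer.apply(X)
    return X, targets


def train_from_files(
    fasta: Union[str, Path],
    intensities: Union[str, Path],
    config: Optional[ModelConfig] = None,
    min_length: int = 6,
    max_length: int = 30,
    pep_threshold: float = 0.01,
) -> tuple[TrainedModel, list[QueryGroup]]:
    """FASTA + intensity TSV in, trained model and its training groups out."""
    database = parse_fasta(fasta)
    groups, _ = load_intensity_table(
        intensities, database, min_length=min_length,
        max_length=max_length, pep_threshold=pep_threshold)
    model = fit_model(groups, database, config=config)
    return model, groups
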