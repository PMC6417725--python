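"""Shared fixtures: synthetic chemistry sets reused across the suite."""

import numpy as np
import pytest

from rationalqsar.curation import curate
from rationalqsar.features import Featurizer, build_vocabulary
from rationalqsar.qsar import CocktailQSAR
from rationalqsar.synth import FixtureConfig, make_dataset


SEPARABLE_CONFIG = FixtureConfig(
    n_active=200,
    n_inactive=800,
    alert_penetrance=1.0,
    label_noise=0.0,
    decoy_fraction=0.0,
    interferer_fraction=0.0,
    contaminant_rates={},
    seed=11,
)


@pytest.fixture(scope="session")
def separable_dataset():
    """Curated, cleanly separable 200/800 set (planted alerts, no noise)."""
    dataset = curate(make_dataset(SEPARABLE_CONFIG))
    kept = dataset.kept_frame()
    labels = (kept["label"] == "ACTIVE").astype(int).to_numpy()
    return kept, labels


@pytest.fixture(scope="session")
def separable_features(separable_dataset):
    kept, labels = separable_dataset
    smiles = kept["canonical_smiles"].tolist()
    vocabulary = build_vocabulary(smiles)
    features = Featurizer(vocabulary).transform(smiles, kept["id"].tolist())
    return features, labels


@pytest.fixture(scope="session")
def fitted_cocktail(separable_features):
    features, labels = separable_features
    return CocktailQSAR(features, labels).fit(seed=3)


@pytest.fixture(scope="session")
def contaminated_table():
    """Small noisy universe laced with every contaminant type."""
    config = FixtureConfig(
        n_active=40,
        n_inactive=360,
        alert_penetrance=0.9,
        label_noise=0.05,
        decoy_fraction=0.05,
        interferer_fraction=0.10,
        contaminant_rates={
            "salt": 0.03,
            "mixture": 0.02,
            "low_carbon": 0.01,
            "bad_element": 0.01,
            "duplicate_concordant": 0.02,
            "duplicate_conflict": 0.01,
        },
        seed=7,
    )
    return make_dataset(config), config
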