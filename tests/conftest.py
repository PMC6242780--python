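"""Shared fixtures: toy databases and a small trained model.

Everything is generated programmatically; the expensive standard-fixture
trainings used by the acceptance tests are cached per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import pepobs as pb

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_database() -> list[pb.ProteinRecord]:
    """Three tiny proteins with one shared tryptic peptide (AVTGR)."""
    return [
        pb.ProteinRecord("p1", "MAVLKAVTGRSSDEK"),
        pb.ProteinRecord("p2", "GGKAVTGRWLLMNK"),
        pb.ProteinRecord("p3", "TTTKWCYDEFGHIK"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A 60-protein simulated dataset: (proteome, groups, config)."""
    config = pb.SimulationConfig(n_proteins=60, protein_length=(80, 200),
                                 seed=7)
    proteome = pb.generate_proteome(config)
    table, _ = pb.simulate_intensities(proteome, config)
    groups = pb.groups_from_table(table, proteome, config)
    return proteome, groups, config


@pytest.fixture(scope="session")
def small_model(small_sim):
    """A quickly trained model on the small simulated dataset."""
    proteome, groups, _ = small_sim
    config = pb.ModelConfig(hidden_layers=2, nodes_per_layer=16, epochs=3,
                            dropout_p=0.0, seed=3)
    model = pb.fit_model(groups, proteome, config=config)
    return model


@pytest.fixture(scope="session")
def standard_fixture_bundle():
    return pb.standard_fixture()


@pytest.fixture(scope="session")
def fixture_trained_models(standard_fixture_bundle):
    """Default-configuration models trained on the standard fixture, seeds 1-3."""
    fx = standard_fixture_bundle
    return {
        seed: pb.fit_model(fx.train, fx.proteome,
                           config=pb.ModelConfig(seed=seed))
        for seed in (1, 2, 3)
    }


def random_protein(rng: np.random.Generator, length: int) -> str:
    from pepobs.proteins import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
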