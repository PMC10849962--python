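import numpy as np
import pytest

from lsfgdl import ModelConfig, ReactionRecord
from lsfgdl.synthetic import SyntheticSpec, make_dataset

#: small network dimensions used throughout the tests (architecture is the
#: same as at production scale; only the widths shrink)
SMALL_DIMS = dict(hidden_dim=16, embed_dim=8, post_pool_dim=16, mlp_hidden=16,
                  n_frequencies=8)


def small_config(**kwargs) -> ModelConfig:
    merged = {**SMALL_DIMS, **kwargs}
    return ModelConfig(**merged)


def make_record(rxn_id="r1", substrate="Cc1ccccc1", yield_percent=50.0, **kwargs) -> ReactionRecord:
    defaults = dict(
        source="experimental",
        products=[],
        catalyst="[Ir(COD)OMe]2",
        ligand="dtbbpy",
        solvent="cyclohexane",
        reagent="B2Pin2",
        temperature=80.0,
        time=16.0,
        concentration=0.2,
        scale=0.1,
        citation="unit test",
    )
    defaults.update(kwargs)
    return ReactionRecord(rxn_id=rxn_id, substrate=substrate,
                          yield_percent=yield_percent, **defaults)


@pytest.fixture(scope="session")
def synth_experimental():
    """Small experimental-regime dataset shared across tests (12 substrates)."""
    spec = SyntheticSpec(n_substrates=12, seed=3)
    records, manifest = make_dataset(spec)
    return spec, records, manifest


@pytest.fixture(scope="session")
def synth_literature():
    """Literature-regime dataset covering all 12/9/2/4 condition categories."""
    spec = SyntheticSpec(n_substrates=60, regime="literature", seed=5)
    records, manifest = make_dataset(spec)
    return spec, records, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
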