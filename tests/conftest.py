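import numpy as np
import pytest

from mmpaq.fixtures import FixtureSpec, extended_spec, generate_library
from mmpaq.mmp import mine_pairs
from mmpaq.molprep import MoleculeRecord
from mmpaq.rules import compile_rules


@pytest.fixture(scope="session")
def noisy_library():
    """Default planted library: 2 scaffolds x 8 substituents x 2 sites, sigma=0.1."""
    return generate_library(FixtureSpec(noise_sd=0.1, seed=20240901))


@pytest.fixture(scope="session")
def clean_library():
    """Same library without noise: every pair delta is an exact contribution difference."""
    return generate_library(FixtureSpec(noise_sd=0.0, seed=20240901))


@pytest.fixture(scope="session")
def noisy_pairs(noisy_library):
    records, _ = noisy_library
    return mine_pairs(records)


@pytest.fixture(scope="session")
def clean_pairs(clean_library):
    records, _ = clean_library
    return mine_pairs(records)


@pytest.fixture(scope="session")
def noisy_rules(noisy_pairs):
    return compile_rules(noisy_pairs, task="regression")


@pytest.fixture(scope="session")
def qsar_run():
    """One shared MMPA-by-QSAR run on the six-scaffold library (expensive)."""
    from mmpaq.pipeline import RunConfig, run_mmpa_by_qsar

    records, truth = generate_library(extended_spec(noise_sd=0.1, seed=11))
    rng = np.random.default_rng(11)
    idx = rng.permutation(len(records))
    labeled = [records[i] for i in sorted(idx[: len(records) // 2])]
    unlabeled = [
        MoleculeRecord(id=records[i].id, smiles_canonical=records[i].smiles_canonical)
        for i in sorted(idx[len(records) // 2 :])
    ]
    config = RunConfig(task="regression", seed=11)
    result = run_mmpa_by_qsar(labeled, unlabeled, config)
    return result, labeled, unlabeled, truth
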