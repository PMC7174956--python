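import numpy as np
import pytest

import hmmstack as hs


def random_profile(rng: np.random.Generator, length: int = 8,
                   star_rate: float = 0.0, pid: str = "rand") -> hs.HMMProfile:
    """A random raw profile with scores in [0, 3000] and optional STARs."""
    scores = rng.integers(0, 3000, size=(length, 20))
    if star_rate > 0:
        scores[rng.random(scores.shape) < star_rate] = hs.STAR
    residues = "".join(rng.choice(list(hs.STANDARD_AA), size=length))
    return hs.HMMProfile(
        protein_id=pid, length=length, residues=residues,
        raw_scores=scores, alphabet=hs.STANDARD_AA,
    )


def random_normalized(rng: np.random.Generator, length: int = 8,
                      pid: str = "rand") -> hs.NormalizedProfile:
    """A random normalized profile with strictly positive entries."""
    mat = rng.uniform(0.01, 1.0, size=(length, 20))
    return hs.NormalizedProfile(
        protein_id=pid, length=length, matrix=mat, alphabet=hs.STANDARD_AA
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def moderate_features(tmp_path_factory):
    """Features of a moderately separable dataset (20/20, separation 1)."""
    cfg = hs.SimulationConfig(n_pos=20, n_neg=20, separation=1.0, seed=11,
                              length_range=(30, 80))
    ds = hs.generate_dataset(cfg, tmp_path_factory.mktemp("sim_moderate"))
    return hs.batch_encode(ds)


@pytest.fixture(scope="session")
def separable_features(tmp_path_factory):
    """Features of a strongly separated dataset (15/15, separation 3)."""
    cfg = hs.SimulationConfig(n_pos=15, n_neg=15, separation=3.0, seed=7,
                              length_range=(30, 80))
    ds = hs.generate_dataset(cfg, tmp_path_factory.mktemp("sim_separable"))
    return hs.batch_encode(ds)
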