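import numpy as np
import pandas as pd
import pytest

from straincgh.io import PresenceMatrix
from straincgh.simulate import GeneratorConfig, IslandPlan, NoiseModel


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Small two-replicon genome: fast enough for end-to-end pipeline tests."""
    return GeneratorConfig(
        replicons=(("C1", 120_000), ("P1", 24_000)),
        loci_per_replicon=(("C1", 100), ("P1", 20)),
        island_plans=(IslandPlan("C1", 2, (6, 10)),),
        plasmid_replicons=("P1",),
        min_island_separation=4,
        n_group_i=3,
        n_group_ii=3,
        grid=(2, 2),
    )


@pytest.fixture(scope="session")
def default_noise() -> NoiseModel:
    return NoiseModel()


def random_presence_matrix(
    rng: np.random.Generator,
    n_genes: int,
    n_strains: int,
    p_present: float = 0.5,
    p_na: float = 0.0,
    gene_prefix: str = "g",
) -> PresenceMatrix:
    """Random nullable-boolean presence matrix for brute-force comparisons."""
    calls = pd.DataFrame(
        rng.random((n_genes, n_strains)) < p_present,
        index=[f"{gene_prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_strains)],
    ).astype("boolean")
    if p_na > 0:
        mask = rng.random((n_genes, n_strains)) < p_na
        calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns))
    return PresenceMatrix(calls=calls)
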