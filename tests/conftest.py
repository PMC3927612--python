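import numpy as np
import pandas as pd
import pytest

from paranet import simulate as sim


def make_random_hit_table(
    rng: np.random.Generator, n_proteins: int = 30, density: float = 0.2
) -> pd.DataFrame:
    """Random asymmetric hit table with a mix of strong and weak e-values."""
    ids = [f"P{i:03d}" for i in range(n_proteins)]
    rows = []
    for qi in range(n_proteins):
        for si in range(n_proteins):
            if qi == si or rng.random() > density:
                continue
            bitscore = float(rng.uniform(40, 500))
            evalue = 10.0 ** (-bitscore / 12.0)
            if rng.random() < 0.15:
                evalue = float(rng.uniform(1e-5, 1e-2))  # fails the cutoff
            rows.append((ids[qi], ids[si], round(evalue, 12), round(bitscore, 1)))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


def rich_config(seed: int = 7, n_species: int = 2) -> sim.EvolutionConfig:
    """Two-species simulation with all six event kinds active."""
    return sim.EvolutionConfig(
        n_ancestral_families=14,
        n_mobile_families=3,
        n_ancestral_genes=6,
        domains_per_ancestor=(1, 2),
        n_species=n_species,
        species_divergence_times_my=(800.0,)[: n_species - 1],
        gene_duplication=8e-4,
        domain_gain_terminal=3e-4,
        domain_gain_internal=3e-4,
        domain_loss=2e-4,
        tandem_duplication=3e-4,
        shuffling_insertion=4e-4,
        seed=seed,
    )


@pytest.fixture(scope="session")
def confusion_result():
    return sim.generate_proteome(sim.shuffle_internal_config(1))


@pytest.fixture(scope="session")
def confusion_hits(confusion_result):
    return sim.score_all_pairs(confusion_result.proteins)


@pytest.fixture(scope="session")
def rich_result():
    return sim.generate_proteome(rich_config())


@pytest.fixture(scope="session")
def rich_hits(rich_result):
    return sim.score_all_pairs(rich_result.proteins)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
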