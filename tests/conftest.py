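"""Shared fixtures: synthetic cohorts are generated once per session."""

import pytest

from lncrecur import de as de_mod
from lncrecur.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-scale cohort (19 pairs, 300 lncRNAs, 10% planted DE)."""
    config = SimulationConfig(seed=1)
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def default_expr(default_cohort):
    _, cohort, _ = default_cohort
    return de_mod.normalize(cohort)


@pytest.fixture(scope="session")
def null_pair_cohort():
    """A single matched pair with 2,000 transcripts and no planted signal."""
    config = SimulationConfig(
        seed=1,
        n_pairs=2,
        n_coding_genes=1700,
        n_lncRNA=300,
        frac_de=0.0,
        n_short_decoys=0,
    )
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth
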