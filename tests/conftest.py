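import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridgs import genio, mm, simcross as sc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    return sc.GenomeSpec.uniform(5, 1.0, 40)


@pytest.fixture(scope="session")
def panels(genome):
    ff, fd = sc.simulate_founders(genome, 4, 0.3, seed=101)
    flint = sc.derive_dh_lines(
        ff, [("F0", "F1"), ("F2", "F3")], 20, genome, seed=102, prefix="LF"
    )
    dent = sc.derive_dh_lines(
        fd, [("D0", "D1"), ("D2", "D3")], 20, genome, seed=103, prefix="LD"
    )
    return flint, dent


@pytest.fixture(scope="session")
def genos(genome, panels):
    flint, dent = panels
    return (
        flint.to_genotype_matrix(genome.marker_ids),
        dent.to_genotype_matrix(genome.marker_ids),
    )


@pytest.fixture(scope="session")
def factorial(panels):
    flint, dent = panels
    return sc.make_factorial(flint.ids, dent.ids, 2.0, seed=104)


@pytest.fixture(scope="session")
def trait(genome, panels):
    flint, dent = panels
    t = sc.TraitModel.sample(genome.n_markers, 25, np.random.default_rng(105))
    return t.calibrate(flint, dent, 0.44, 0.25, 0.19)


@pytest.fixture(scope="session")
def plots(factorial, trait, panels):
    flint, dent = panels
    return sc.simulate_phenotypes(
        factorial, trait, flint, dent, n_trials=3, seed=106
    )


@pytest.fixture(scope="session")
def lsm(plots):
    return mm.ls_means(plots)["ls_mean"]


@pytest.fixture(scope="session")
def small_scheme():
    return sc.simulate_two_cycle_scheme(
        genome=sc.GenomeSpec.uniform(5, 1.0, 40),
        lines_per_group_g0=60,
        hybrids_per_line_g0=1.5,
        n_trials_g0=4,
        n_trials_g1=4,
        n_qtl=40,
        n_selected=12,
        n_intragroup_crosses=10,
        lines_per_group_g1=40,
        hybrids_per_line_g1=1.5,
        n_g0s_hybrids=12,
        select_on="predicted_gca",
        seed=107,
    )
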