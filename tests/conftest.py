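import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stemloop as sl

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20140103)


@pytest.fixture
def four_taxon_tree():
    return sl.PhyloTree.from_newick("((t1:0.1,t2:0.2):0.15,t3:0.3,t4:0.05);")


@pytest.fixture
def loop_hky_g():
    return sl.build_model(
        "HKY",
        {"pi": np.array([0.3, 0.2, 0.25, 0.25]), "kappa": 3.0, "gamma_shape": 0.7},
    )


@pytest.fixture
def small_alignment(four_taxon_tree, loop_hky_g):
    stem = sl.build_model(
        "16D",
        {
            "nuc_pi": np.array([0.3, 0.2, 0.25, 0.25]),
            "alpha": 5.0,
            "beta": 2.0,
            "rates": {"ts": 3.0, "double": 0.4},
        },
    )
    mix = sl.MixtureModel(loop_hky_g, stem, rho=1.3)
    aln, _ = sl.simulate_alignment(
        sl.SimulationSpec(mix, 20, 15, seed=42, tree=four_taxon_tree)
    )
    return aln
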