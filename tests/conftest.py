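import numpy as np
import pytest

import grnscape as g


@pytest.fixture(scope="session")
def at_network():
    return g.at_flower_network()


@pytest.fixture(scope="session")
def at_model(at_network):
    return g.build_continuous_model(at_network)


@pytest.fixture(scope="session")
def single_gene_fpe():
    """Unregulated gene dp/dt = 1 - p at system size 50."""
    net = g.make_toy_network("single_gene")
    return g.FPEModel(g.build_continuous_model(net), omega=50.0)


@pytest.fixture(scope="session")
def single_gene_grid(single_gene_fpe):
    ax = np.linspace(0.0025, 3.0, 600)
    return g.grid_fpe_stationary(single_gene_fpe, [ax])


@pytest.fixture(scope="session")
def known_mixture_2d():
    """A well-separated 2-gene, 2-component gamma mixture with known modes."""

    def moment_params(mode, var):
        m, v = np.asarray(mode, float), np.asarray(var, float)
        beta = (m + np.sqrt(m**2 + 4 * v)) / (2 * v)
        return 1 + m * beta, beta

    a1, b1 = moment_params([1.4, 0.6], [0.02, 0.015])
    a2, b2 = moment_params([0.5, 2.0], [0.015, 0.03])
    return g.GammaMixture(np.array([0.4, 0.6]), np.array([a1, a2]), np.array([b1, b2]))
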