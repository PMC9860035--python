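import numpy as np
import pytest

from coopnet import GameParams, InstitutionalNetwork


@pytest.fixture
def fig3_params() -> GameParams:
    """Parameters used throughout the 3-person monitoring-motif examples."""
    return GameParams(N=3, b=2, m=4, p=3, c_t=1, c_p=0.25)


@pytest.fixture
def fig3_network() -> InstitutionalNetwork:
    """Node 0 monitors nodes 1 and 2; nobody monitors node 0."""
    return InstitutionalNetwork(3, [(0, 1), (0, 2)])


def random_digraph(rng: np.random.Generator, n: int, q: float) -> InstitutionalNetwork:
    """Erdos-Renyi style random simple digraph with link probability q."""
    edges = [
        (i, j) for i in range(n) for j in range(n) if i != j and rng.random() < q
    ]
    return InstitutionalNetwork(n, edges)


def random_params(rng: np.random.Generator, n: int) -> GameParams:
    """Random but valid parameter draw used by the oracle batteries."""
    c_t = 1.0
    c_p = float(rng.uniform(0.05, 1.0)) * c_t
    return GameParams(
        N=n,
        b=float(rng.uniform(1.0, 4.0)),
        m=float(rng.uniform(0.5, 10.0)),
        p=float(rng.uniform(0.1, 5.0)),
        c_t=c_t,
        c_p=c_p,
    )
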