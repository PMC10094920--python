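import numpy as np
import pytest

import meanet as m


@pytest.fixture(scope="session")
def layout10():
    return m.make_chip_layout(10, 10, 0.042)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def build_raster(layout, trains: dict[int, list[float]], duration: float) -> m.SpikeRaster:
    """Raster from an {electrode_id: times} dict; silent elsewhere."""
    spikes = [np.sort(np.asarray(trains.get(i, []), dtype=float))
              for i in range(layout.n_electrodes)]
    return m.SpikeRaster(layout=layout, duration_s=duration, spikes=spikes)


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """The packaged desk-scale demo, run once and shared across tests."""
    out = tmp_path_factory.mktemp("demo")
    config = m.demo_config(seed=0, out_dir=str(out))
    return m.run_experiment(config)


@pytest.fixture(scope="session")
def random_graphs():
    """50 random undirected graphs up to 40 nodes for oracle comparisons."""
    import networkx as nx
    rng = np.random.default_rng(777)
    graphs = []
    for _ in range(50):
        n = int(rng.integers(4, 41))
        p = float(rng.uniform(0.05, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        graphs.append(g)
    return graphs
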