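import warnings

import networkx as nx
import numpy as np
import pytest

from drugnetstrat import CohortConfig, PipelineConfig, generate_cohort, run_pipeline

warnings.filterwarnings("ignore", category=UserWarning)


def make_graph(edges, default_weight=0.5):
    """Tiny weighted interactome from (u, v[, weight]) tuples."""
    g = nx.Graph()
    for e in edges:
        u, v, *rest = e
        w = rest[0] if rest else default_weight
        g.add_edge(u, v, weight=w, origin="reference")
    return g


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config, tmp_path_factory):
    """One end-to-end run on the default synthetic cohort, shared by tests."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(cohort=default_config, out_dir=str(out))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
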