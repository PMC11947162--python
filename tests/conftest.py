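import numpy as np
import pytest
from hypothesis import settings

import ferroprop as fp

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_run():
    """One default-condition monolayer experiment: cells, graph, events."""
    cfg = fp.SimulationConfig(seed=7)
    cells = fp.generate_monolayer(cfg)
    graph = fp.build_contact_graph(cells)
    events = fp.simulate_propagation(cells, graph, cfg)
    return cfg, cells, graph, events


@pytest.fixture(scope="session")
def rendered_run():
    """A small rendered time-lapse with ground truth, shared across
    quantification tests (rendering is the slow step)."""
    cfg = fp.SimulationConfig(
        field_size=210.0, n_illuminated=3, t_end=240.0, seed=1
    )
    cells = fp.generate_monolayer(cfg)
    graph = fp.build_contact_graph(cells)
    events = fp.simulate_propagation(cells, graph, cfg)
    imaging = fp.ImagingConfig(seed=1)
    stack, label_map = fp.render_frames(
        cells, events, imaging, field_size=cfg.field_size, t_end=cfg.t_end
    )
    return cfg, cells, graph, events, imaging, stack, label_map


def match_centroids(cells, centroids, tol_um):
    """Greedy one-to-one nearest matching of segmented centroids to true
    cell centres; returns (n_matched, true_index_per_centroid)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(cells[["x", "y"]].to_numpy())
    d, j = tree.query(centroids, k=1)
    used = set()
    n_ok = 0
    for di, ji in zip(d, j):
        if di <= tol_um and ji not in used:
            used.add(ji)
            n_ok += 1
    return n_ok, j


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
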