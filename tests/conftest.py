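import numpy as np
import pytest

import scgale as sg


@pytest.fixture(scope="session")
def cluster_fixture():
    """Small planted-marker fixture shared by unit tests."""
    spec = sg.SyntheticSpec(n_cells=300, n_features=120, seed=3)
    m, truth = sg.generate_counts(spec)
    return spec, m, truth


@pytest.fixture(scope="session")
def processed(cluster_fixture):
    _, m, _ = cluster_fixture
    return sg.log_transform(sg.normalize_library_size(m))


@pytest.fixture(scope="session")
def trained_setup(processed):
    """Geometry + GRAE + graph + trained GAT on the small fixture."""
    xi = sg.phate_embed(processed, params=sg.GeometryParams(seed=1))
    grae = sg.train_grae(processed, xi, sg.TrainConfig(seed=1))
    graph = sg.knn_graph(grae.latent, k=15, source="GRAE")
    clf, report = sg.train_classifier(
        graph, processed, sg.GATConfig(seed=1, max_epochs=150), arch="GAT"
    )
    return {"xi": xi, "grae": grae, "graph": graph, "clf": clf,
            "report": report}
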