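import numpy as np
import pytest

from crossomics.model import CrossOmicsNet, ModelConfig, PatientBatch
from crossomics.simulate import SimConfig, build_fixture_graph, make_cohort
from crossomics.training import (TrainRun, apply_standardizer, fit_standardizer,
                                 substream, train_model)

#: compact model settings used throughout the suite (hidden width and epochs
#: sized for a desk-scale synthetic cohort)
TEST_CONFIG = dict(hidden_dim=16, num_layers=2)
TEST_RUN = dict(max_epochs=150, patience=30)


@pytest.fixture(scope="session")
def sim_default():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def fixture_graph(sim_default):
    graph, clusters, genes, probes, targets = build_fixture_graph(sim_default)
    return {"graph": graph, "clusters": clusters, "genes": genes,
            "probes": probes, "targets": targets}


@pytest.fixture(scope="session")
def cohort(sim_default, fixture_graph):
    return make_cohort(fixture_graph["graph"], fixture_graph["clusters"],
                       sim_default)


@pytest.fixture(scope="session")
def std_batch(fixture_graph, cohort):
    """Whole cohort, standardized on itself (fine for forward-pass tests)."""
    raw = cohort.raw_matrices()
    x = apply_standardizer(fit_standardizer(raw), raw)
    n = cohort.config.n_patients
    return PatientBatch(x=x, modality_mask=np.ones((n, 3), dtype=bool),
                        labels=cohort.labels,
                        sample_ids=cohort.sample_ids)


@pytest.fixture(scope="session")
def untrained_model(fixture_graph):
    return CrossOmicsNet(fixture_graph["graph"],
                         ModelConfig(**TEST_CONFIG, seed=3))


@pytest.fixture(scope="session")
def trained_model(fixture_graph, std_batch):
    """One model trained on a fixed 90/10 split of the synthetic cohort.

    Shared session-wide by the interpretability / robustness / calibration
    tests so the suite trains only once.
    """
    graph = fixture_graph["graph"]
    n = std_batch.n_patients
    perm = substream(11, "split").permutation(n)
    fit_b = std_batch.subset(perm[: int(0.9 * n)])
    val_b = std_batch.subset(perm[int(0.9 * n):])
    model = CrossOmicsNet(graph, ModelConfig(**TEST_CONFIG, seed=5),
                          rng=substream(5, "init"))
    run = TrainRun(**TEST_RUN, monitor="accuracy", seed=5)
    result = train_model(model, fit_b, val_b, run)
    return {"model": model, "fit": fit_b, "val": val_b, "result": result}
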