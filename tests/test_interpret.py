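"""Attribution methods: saliency, integrated gradients, edge gates,
subnetwork extraction and fold overlap."""

import hashlib
import math

import numpy as np
import pandas as pd
import pytest

from crossomics.graphs import MODALITIES, RELATION_GC, RELATION_MG
from crossomics.interpret import (aggregate_edge_attributions,
                                  aggregate_node_attributions,
                                  edge_gate_attribution, extract_subnetwork,
                                  fold_overlap, integrated_gradients_nodes,
                                  saliency_nodes)
from crossomics.model import PatientBatch

from test_model_core import toy_batch, toy_graph
from crossomics.model import CrossOmicsNet, ModelConfig


def param_hash(model):
    h = hashlib.sha256()
    for k in sorted(model.params):
        h.update(model.params[k].data.tobytes())
    return h.hexdigest()


class TestSaliency:
    def test_masked_modality_scores_are_zero(self):
        graph = toy_graph()
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=0))
        batch = toy_batch(graph)
        mask = np.ones((3, 3), bool)
        mask[:, 2] = False
        batch = PatientBatch(x=batch.x, modality_mask=mask)
        scores = saliency_nodes(model, batch, subtype=1)
        assert np.all(scores["m"] == 0.0)
        assert np.any(scores["g"] > 0.0)

    def test_matches_finite_differences(self):
        graph = toy_graph(seed=2)
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=3))
        batch = toy_batch(graph, n_patients=1, seed=4)
        scores = saliency_nodes(model, batch, subtype=0)
        rng = np.random.default_rng(5)
        eps = 1e-5
        for _ in range(10):
            t = MODALITIES[rng.integers(3)]
            v = int(rng.integers(batch.x[t].shape[1]))
            for sign, store in ((1, "hi"), (-1, "lo")):
                pert = {m: batch.x[m].copy() for m in MODALITIES}
                pert[t][0, v] += sign * eps
                b = PatientBatch(x=pert, modality_mask=batch.modality_mask)
                if sign == 1:
                    hi = model.forward(b).logits.data[0, 0]
                else:
                    lo = model.forward(b).logits.data[0, 0]
            fd = abs((hi - lo) / (2 * eps))
            assert scores[t][0, v] == pytest.approx(fd, abs=1e-4)

    def test_pipeline_does_not_mutate_parameters(self):
        graph = toy_graph()
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=0))
        batch = toy_batch(graph)
        before = param_hash(model)
        saliency_nodes(model, batch, 0)
        integrated_gradients_nodes(model, batch, 0, steps=8)
        edge_gate_attribution(model, batch, 0)
        assert param_hash(model) == before


class TestIntegratedGradients:
    def test_zero_input_gives_zero_scores(self):
        graph = toy_graph()
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=0))
        batch = toy_batch(graph)
        for t in MODALITIES:
            batch.x[t][:] = 0.0
        ig, residual = integrated_gradients_nodes(model, batch, 0, steps=8)
        for t in MODALITIES:
            assert np.allclose(ig[t], 0.0)
        assert np.allclose(residual, 0.0, atol=1e-10)

    def test_completeness_on_trained_model(self, trained_model):
        model = trained_model["model"]
        batch = trained_model["val"].subset(np.arange(8))
        ig, residual = integrated_gradients_nodes(model, batch, 2, steps=128)
        span = model.forward(batch).logits.data[:, 2] - model.forward(
            PatientBatch(x={t: np.zeros_like(batch.x[t]) for t in MODALITIES},
                         modality_mask=batch.modality_mask)).logits.data[:, 2]
        assert np.all(np.abs(residual) <= 0.01 * np.maximum(np.abs(span), 1e-6))


class TestEdgeGates:
    def test_matches_finite_differences(self):
        graph = toy_graph(seed=6)
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=7))
        batch = toy_batch(graph, n_patients=1, seed=8)
        scores = edge_gate_attribution(model, batch, 1)
        eps = 1e-5
        for base in (RELATION_GC, RELATION_MG):
            for e in range(min(3, len(graph.edges[base]))):
                vals = []
                for sign in (1, -1):
                    gates = model.unit_gates()
                    gates[base].data[e] += sign * eps
                    logit = model.forward(batch, gates=gates).logits.data[0, 1]
                    vals.append(logit)
                fd = abs((vals[0] - vals[1]) / (2 * eps))
                assert scores[base][0, e] == pytest.approx(fd, abs=1e-4)


class TestAggregation:
    def test_tables_are_complete_and_nonnegative(self, trained_model):
        model = trained_model["model"]
        batch = trained_model["val"]
        nodes = aggregate_node_attributions(model, batch)
        edges = aggregate_edge_attributions(model, batch)
        assert (nodes["score"] >= 0).all() and (edges["score"] >= 0).all()
        n_nodes_per_subtype = nodes.groupby("subtype").size().unique()
        assert set(n_nodes_per_subtype) == {model.graph.n_nodes}


class TestSubnetworks:
    def edge_frame(self, scores, subtype=0):
        rows = []
        for (rel, u, v), s in scores.items():
            rows.append({"subtype": subtype, "relation": rel, "src": u,
                         "dst": v, "score": s})
        return pd.DataFrame(rows)

    def test_retention_count_is_ceil_of_budget(self):
        scores = {(RELATION_GC, i, i): 1.0 for i in range(100)}
        frame = self.edge_frame(scores)
        sub = extract_subnetwork(frame, 0, budget=0.01, min_component_size=0)
        assert sub.n_retained_before_pruning == 1

    def test_star_concentration_recovers_star(self):
        scores = {(RELATION_GC, i, 0): 10.0 for i in range(5)}
        scores.update({(RELATION_GC, 10 + i, i + 1): 0.1 for i in range(45)})
        frame = self.edge_frame(scores)
        sub = extract_subnetwork(frame, 0, budget=0.1, min_component_size=3)
        assert sub.edge_keys() == {(RELATION_GC, i, 0) for i in range(5)}
        assert sub.hub_counts["g"] == 1  # the star center

    def test_matches_sort_oracle_on_random_scores(self):
        rng = np.random.default_rng(9)
        scores = {(RELATION_MG, int(u), int(v)): float(s)
                  for (u, v), s in zip(rng.integers(0, 200, (1000, 2)),
                                       rng.random(1000))}
        frame = self.edge_frame(scores)
        budget = 0.05
        sub = extract_subnetwork(frame, 0, budget=budget, min_component_size=0)
        n_keep = math.ceil(budget * len(frame))
        oracle = set(sorted(scores, key=lambda k: (-scores[k],) + k)[:n_keep])
        assert sub.edge_keys() == oracle

    def test_edge_count_monotone_in_budget(self):
        rng = np.random.default_rng(10)
        scores = {(RELATION_GC, int(u), int(v)): float(s)
                  for (u, v), s in zip(rng.integers(0, 50, (300, 2)),
                                       rng.random(300))}
        frame = self.edge_frame(scores)
        counts = [extract_subnetwork(frame, 0, budget=b,
                                     min_component_size=0).n_retained_before_pruning
                  for b in (0.01, 0.05, 0.2, 0.5)]
        assert counts == sorted(counts)


class TestFoldOverlap:
    @pytest.mark.parametrize("sets,expected", [
        ([{1, 2, 3}, {1, 2, 3}], 1.0),
        ([{1, 2}, {3, 4}], 0.0),
        ([{"a", "b", "c"}, {"b", "c", "d"}], 0.5),
    ])
    def test_pairwise_jaccard(self, sets, expected):
        assert fold_overlap(sets) == pytest.approx(expected)

    def test_three_sets_average(self):
        sets = [{1, 2}, {1, 2}, {1, 3}]
        expected = (1.0 + 1 / 3 + 1 / 3) / 3
        assert fold_overlap(sets) == pytest.approx(expected)
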