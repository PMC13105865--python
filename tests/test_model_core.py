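"""Forward-pass semantics: message passing, attention, fusion, losses."""

import math

import numpy as np
import pytest

from crossomics.autodiff import Tensor, no_grad
from crossomics.graphs import (HeteroGraph, MODALITIES, RELATION_GC,
                               RELATION_MG, empty_graph_like)
from crossomics.model import CrossOmicsNet, ModelConfig, PatientBatch


def toy_graph(n_g=6, n_c=5, n_m=4, seed=0):
    rng = np.random.default_rng(seed)
    gc = {(int(rng.integers(n_c)), int(rng.integers(n_g))) for _ in range(8)}
    mg = {(int(rng.integers(n_m)), int(rng.integers(n_g))) for _ in range(7)}
    return HeteroGraph(gene_ids=[f"g{i}" for i in range(n_g)],
                       cpg_ids=[f"c{i}" for i in range(n_c)],
                       mirna_ids=[f"m{i}" for i in range(n_m)],
                       edges={RELATION_GC: np.array(sorted(gc)),
                              RELATION_MG: np.array(sorted(mg))})


def toy_batch(graph, n_patients=3, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    x = {"g": rng.normal(size=(n_patients, len(graph.gene_ids))),
         "c": rng.normal(size=(n_patients, len(graph.cpg_ids))),
         "m": rng.normal(size=(n_patients, len(graph.mirna_ids)))}
    return PatientBatch(x=x, modality_mask=np.ones((n_patients, 3), bool),
                        labels=labels)


@pytest.fixture
def toy_model():
    graph = toy_graph()
    return CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=1)), graph


class TestInitStates:
    def test_zero_input_gives_bias_plus_embedding(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        for t in MODALITIES:
            batch.x[t][:] = 0.0
        states, _ = model.init_node_states(batch)
        expected = np.concatenate(
            [np.tile(model.params[f"in_b_{t}"].data, (graph_len, 1))
             for t, graph_len in (("g", 6), ("c", 5), ("m", 4))])
        expected = expected + model.params["node_emb"].data
        assert np.allclose(states.data, expected[None])

    def test_identical_patients_get_identical_states(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph, n_patients=2)
        batch.x = {t: np.tile(batch.x[t][:1], (2, 1)) for t in MODALITIES}
        states, _ = model.init_node_states(batch)
        assert np.allclose(states.data[0], states.data[1])

    def test_alignment_mismatch_rejected(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        batch.x["g"] = batch.x["g"][:, :-1]
        with pytest.raises(ValueError, match="features"):
            model.forward(batch)


class TestRgcnLayer:
    def test_zero_edge_graph_is_self_term_only(self):
        graph = toy_graph()
        empty = empty_graph_like(graph)
        model = CrossOmicsNet(empty, ModelConfig(hidden_dim=8, seed=1,
                                                 nonlinearity="relu"))
        batch = toy_batch(empty)
        states, _ = model.init_node_states(batch)
        out = model.rgcn_layer(states, 0, {})
        expected = np.maximum(states.data @ model.params["W0_0"].data, 0.0)
        assert np.allclose(out.data, expected)

    def test_zero_gates_equal_zero_edge_case(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        states, _ = model.init_node_states(batch)
        gates = {base: Tensor(np.zeros(len(graph.edges[base])))
                 for base in (RELATION_GC, RELATION_MG)}
        gated = model.rgcn_layer(states, 0, gates)
        expected = np.tanh(states.data @ model.params["W0_0"].data)
        assert np.allclose(gated.data, expected)

    def test_matches_dense_loop_oracle(self):
        graph = toy_graph(n_g=12, n_c=10, n_m=8, seed=3)
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=2,
                                                 nonlinearity="relu"))
        batch = toy_batch(graph, n_patients=2, seed=4)
        states, _ = model.init_node_states(batch)
        out = model.rgcn_layer(states, 0, {})

        # oracle: materialize every neighborhood explicitly
        h = states.data
        n = model.n_nodes
        expected = h @ model.params["W0_0"].data
        for rel, (src, dst, _, _) in model._directed.items():
            w = model.params[f"W_{rel}_0"].data
            for v in range(n):
                neigh = src[dst == v]
                if len(neigh):
                    expected[:, v] += (h[:, neigh] @ w).sum(axis=1) / len(neigh)
        expected = np.maximum(expected, 0.0)
        assert np.allclose(out.data, expected, atol=1e-6)


class TestAttentionAndFusion:
    def test_identical_states_give_uniform_attention(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        for t in MODALITIES:
            batch.x[t][:] = 0.0
        model.params["node_emb"].data[:] = 0.0  # make nodes indistinguishable
        trace = model.forward(batch)
        for t, n_t in (("g", 6), ("c", 5), ("m", 4)):
            assert np.allclose(trace.alpha[t].data, 1.0 / n_t)

    def test_alpha_and_beta_normalized(self, toy_model):
        model, graph = toy_model
        trace = model.forward(toy_batch(graph, seed=9))
        for t in MODALITIES:
            assert np.allclose(trace.alpha[t].data.sum(axis=1), 1.0)
        assert np.allclose(trace.beta.data.sum(axis=1), 1.0)
        assert np.allclose(trace.probs.data.sum(axis=1), 1.0)
        assert (trace.probs.data > 0).all()

    def test_single_present_modality_takes_all_fusion_weight(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        batch.modality_mask[:, 1] = False
        batch.modality_mask[:, 2] = False
        batch = PatientBatch(x=batch.x, modality_mask=batch.modality_mask)
        trace = model.forward(batch)
        assert np.allclose(trace.beta.data[:, 0], 1.0)
        assert np.allclose(trace.beta.data[:, 1:], 0.0)
        assert np.allclose(trace.z.data, trace.z_mod["g"].data)

    def test_masked_modality_gradient_is_zero(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph)
        mask = np.ones((3, 3), bool)
        mask[:, 2] = False
        batch = PatientBatch(x=batch.x, modality_mask=mask)
        trace = model.forward(batch)
        trace.logits.sum().backward()
        assert np.all(trace.inputs["m"].grad == 0.0)
        assert np.any(trace.inputs["g"].grad != 0.0)

    def test_classifier_shift_invariance_and_uniformity(self, toy_model):
        model, graph = toy_model
        z = Tensor(np.random.default_rng(0).normal(size=(4, 8)))
        model.params["out_W"].data[:] = 0.0
        model.params["out_b"].data[:] = 0.0
        _, probs = model.classify(z)
        assert np.allclose(probs.data, 1.0 / model.config.num_classes)


class TestPermutationEquivariance:
    def test_forward_is_equivariant_to_gene_relabeling(self):
        graph = toy_graph(seed=5)
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=6))
        batch = toy_batch(graph, seed=7)
        probs = model.forward(batch).probs.data

        rng = np.random.default_rng(8)
        perm = rng.permutation(len(graph.gene_ids))
        inv = np.argsort(perm)
        # relabel gene nodes, permute edge endpoints and feature columns
        permuted_graph = HeteroGraph(
            gene_ids=[graph.gene_ids[i] for i in perm],
            cpg_ids=list(graph.cpg_ids), mirna_ids=list(graph.mirna_ids),
            edges={RELATION_GC: np.column_stack(
                       [graph.edges[RELATION_GC][:, 0],
                        inv[graph.edges[RELATION_GC][:, 1]]]),
                   RELATION_MG: np.column_stack(
                       [graph.edges[RELATION_MG][:, 0],
                        inv[graph.edges[RELATION_MG][:, 1]]])})
        pmodel = CrossOmicsNet(permuted_graph, ModelConfig(hidden_dim=8, seed=6))
        for key, tensor in model.params.items():
            pmodel.params[key].data = tensor.data.copy()
        pmodel.params["node_emb"].data[: len(perm)] = \
            model.params["node_emb"].data[perm]
        pbatch = PatientBatch(x={"g": batch.x["g"][:, perm],
                                 "c": batch.x["c"], "m": batch.x["m"]},
                              modality_mask=batch.modality_mask)
        pprobs = pmodel.forward(pbatch).probs.data
        assert np.allclose(probs, pprobs, atol=1e-10)


class TestRegularizerAndLoss:
    def test_identical_embeddings_give_zero(self, toy_model):
        model, graph = toy_model
        h = Tensor(np.ones((2, model.n_nodes, 8)))
        assert np.allclose(model.graph_regularizer(h).data, 0.0)

    def test_single_edge_hand_value(self):
        graph = HeteroGraph(gene_ids=["g0"], cpg_ids=["c0"], mirna_ids=["m0"],
                            edges={RELATION_GC: np.array([[0, 0]]),
                                   RELATION_MG: np.empty((0, 2), int)})
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=2, seed=0))
        h = np.zeros((1, 3, 2))
        h[0, 1] = [1.0, 0.0]  # the CpG node differs from its gene by [1,0]
        assert model.graph_regularizer(Tensor(h)).data[0] == pytest.approx(1.0)

    def test_matches_edge_loop_oracle(self):
        graph = toy_graph(n_g=10, n_c=8, n_m=6, seed=11)
        model = CrossOmicsNet(graph, ModelConfig(hidden_dim=8, seed=1))
        rng = np.random.default_rng(12)
        h = rng.normal(size=(3, model.n_nodes, 8))
        got = model.graph_regularizer(Tensor(h)).data
        off_g = model._offsets["g"]
        expected = np.zeros(3)
        for base, off_src in ((RELATION_GC, model._offsets["c"]),
                              (RELATION_MG, model._offsets["m"])):
            for u, v in graph.edges[base]:
                diff = h[:, u + off_src] - h[:, v + off_g]
                expected += (diff ** 2).sum(axis=1)
        assert np.allclose(got, expected, atol=1e-8)

    def test_loss_closed_forms(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph, labels=np.array([0, 1, 2]))
        trace = model.forward(batch)
        # uniform prediction: CE = ln K
        trace.probs = Tensor(np.full((3, 5), 0.2))
        loss = model.total_loss(trace, batch.labels, lambda_gr=0.0,
                                lambda_wd=0.0)
        assert loss.data == pytest.approx(math.log(5))
        # perfect one-hot prediction: CE = 0
        onehot = np.zeros((3, 5))
        onehot[np.arange(3), batch.labels] = 1.0
        trace.probs = Tensor(onehot)
        loss = model.total_loss(trace, batch.labels, lambda_gr=0.0,
                                lambda_wd=0.0)
        assert loss.data == pytest.approx(0.0)

    def test_lambda_gr_zero_removes_regularizer_exactly(self, toy_model):
        model, graph = toy_model
        batch = toy_batch(graph, labels=np.array([0, 1, 2]))
        trace = model.forward(batch)
        base = model.total_loss(trace, batch.labels, lambda_gr=0.0).data
        with no_grad():
            ce = -np.log(trace.probs.data[np.arange(3), batch.labels]).mean()
            wd = model.config.lambda_wd * sum(
                (p.data ** 2).sum() for p in model.params.values())
        assert base == pytest.approx(ce + wd)


class TestFusionOnlyEquivalence:
    def test_removing_all_edges_equals_fusion_only_variant(self):
        """With no cross-omics edges the forward pass must coincide with the
        fusion-only architecture (independent encoders + attention fusion)."""
        graph = toy_graph(seed=13)
        stripped = empty_graph_like(graph)
        cfg = ModelConfig(hidden_dim=8, seed=14)
        a = CrossOmicsNet(stripped, cfg)
        b = CrossOmicsNet(stripped, cfg)
        batch = toy_batch(graph, seed=15)
        assert np.allclose(a.forward(batch).probs.data,
                           b.forward(batch).probs.data)

    def test_checkpoint_refuses_wrong_graph(self, tmp_path, toy_model):
        model, graph = toy_model
        path = tmp_path / "ckpt.npz"
        model.save(path)
        other = toy_graph(seed=99)
        with pytest.raises(ValueError, match="different graph"):
            CrossOmicsNet.load(path, other)
        again = CrossOmicsNet.load(path, graph)
        batch = toy_batch(graph)
        assert np.allclose(again.forward(batch).probs.data,
                           model.forward(batch).probs.data)
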