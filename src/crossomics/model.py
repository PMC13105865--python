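"""Relational cross-omics attention network.

Forward computation over a fixed heterogeneous graph with per-patient scalar
node signals:

1. each node's standardized measurement is lifted to ``hidden_dim`` through a
   per-type affine projection;
2. ``num_layers`` relation-aware graph-convolution layers mix information
   across typed edges: ``h_v <- σ(W0 h_v + Σ_r Σ_{u∈N_r(v)} g_e/|N_r(v)| W_r h_u)``,
   where ``g_e`` is a per-edge gate fixed at 1 except during edge attribution;
3. an attention-weighted readout pools each node type into a modality vector;
4. a second-stage masked attention fuses the (present) modality vectors;
5. a softmax classifier maps the fused vector to subtype probabilities.

Training minimizes cross-entropy plus a Laplacian-style smoothness penalty on
final-layer embeddings across cross-omics edges and an L2 weight penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, stack
from .graphs import (HeteroGraph, MODALITIES, MODALITY_CPG, MODALITY_GENE,
                     MODALITY_MIRNA, RELATION_GC, RELATION_MG)

#: directed message-passing relations derived from the two stored edge types:
#: base direction first, then the learnable inverse direction.
_BASE_DIRECTED = {RELATION_GC: "c>g", RELATION_MG: "m>g"}
_INVERSE_DIRECTED = {RELATION_GC: "g>c", RELATION_MG: "g>m"}


@dataclass
class ModelConfig:
    hidden_dim: int = 64
    num_layers: int = 2
    lambda_gr: float = 3e-2
    lambda_wd: float = 1e-4
    nonlinearity: str = "tanh"
    dropout: float = 0.0
    num_classes: int = 5
    inverse_relations: bool = True
    #: learnable per-node embedding added to the lifted scalar signal; gives
    #: identity-less nodes an addressable representation so attention can
    #: target specific molecular entities rather than only value patterns
    node_embeddings: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientBatch:
    """Standardized modality matrices aligned to the graph's node ordering."""

    x: dict[str, np.ndarray]           # modality -> (patients, |V_t|)
    modality_mask: np.ndarray          # (patients, 3) bool, column order g, c, m
    labels: np.ndarray | None = None   # subtype index 0..K-1
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.modality_mask = np.asarray(self.modality_mask, dtype=bool)
        n = None
        for t in MODALITIES:
            self.x[t] = np.asarray(self.x[t], dtype=float)
            if n is None:
                n = self.x[t].shape[0]
            elif self.x[t].shape[0] != n:
                raise ValueError("modalities disagree on patient count")
        if self.modality_mask.shape != (n, len(MODALITIES)):
            raise ValueError("modality_mask shape mismatch")
        # a masked modality carries all-zero features by construction
        for ti, t in enumerate(MODALITIES):
            self.x[t] = self.x[t] * self.modality_mask[:, ti:ti + 1]

    @property
    def n_patients(self) -> int:
        return self.x[MODALITY_GENE].shape[0]

    def validate_against(self, graph: HeteroGraph):
        want = {MODALITY_GENE: len(graph.gene_ids), MODALITY_CPG: len(graph.cpg_ids),
                MODALITY_MIRNA: len(graph.mirna_ids)}
        for t in MODALITIES:
            if self.x[t].shape[1] != want[t]:
                raise ValueError(
                    f"modality {t!r}: {self.x[t].shape[1]} features, graph has {want[t]} nodes")

    def subset(self, rows) -> "PatientBatch":
        rows = np.asarray(rows)
        return PatientBatch(
            x={t: self.x[t][rows] for t in MODALITIES},
            modality_mask=self.modality_mask[rows],
            labels=None if self.labels is None else np.asarray(self.labels)[rows],
            sample_ids=None if self.sample_ids is None
            else [self.sample_ids[i] for i in rows.tolist()],
        )


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass (autodiff tensors)."""

    inputs: dict[str, Tensor]
    h_final: Tensor                    # (B, N, hidden) final node states
    alpha: dict[str, Tensor]           # per-type node attention (B, |V_t|)
    z_mod: dict[str, Tensor]           # per-type readout (B, hidden)
    beta: Tensor                       # (B, 3) modality attention
    z: Tensor                          # fused representation (B, hidden)
    logits: Tensor                     # (B, K)
    probs: Tensor                      # (B, K)
    gates: dict[str, Tensor]           # per base relation (E,) edge gates


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan = sum(shape) if len(shape) > 1 else shape[0] + 1
    return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)


class CrossOmicsNet:
    """The model: parameters + forward pass bound to one HeteroGraph."""

    def __init__(self, graph: HeteroGraph, config: ModelConfig,
                 rng: np.random.Generator | None = None):
        self.graph = graph
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        h = config.hidden_dim
        self._offsets = {MODALITY_GENE: 0,
                         MODALITY_CPG: len(graph.gene_ids),
                         MODALITY_MIRNA: len(graph.gene_ids) + len(graph.cpg_ids)}
        self.n_nodes = graph.n_nodes
        self._build_relations()

        p: dict[str, Tensor] = {}
        for t in MODALITIES:
            p[f"in_w_{t}"] = Tensor(_glorot(rng, (h,)), requires_grad=True, name=f"in_w_{t}")
            p[f"in_b_{t}"] = Tensor(np.zeros(h), requires_grad=True, name=f"in_b_{t}")
        if config.node_embeddings:
            p["node_emb"] = Tensor(rng.normal(0.0, 0.1, size=(self.n_nodes, h)),
                                   requires_grad=True, name="node_emb")
        for layer in range(config.num_layers):
            p[f"W0_{layer}"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
            for rel in self._directed:
                p[f"W_{rel}_{layer}"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
        for t in MODALITIES:
            p[f"read_W_{t}"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
            p[f"read_a_{t}"] = Tensor(_glorot(rng, (h, 1)), requires_grad=True)
        p["fuse_U"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
        p["fuse_q"] = Tensor(_glorot(rng, (h, 1)), requires_grad=True)
        p["out_W"] = Tensor(_glorot(rng, (h, config.num_classes)), requires_grad=True)
        p["out_b"] = Tensor(np.zeros(config.num_classes), requires_grad=True)
        self.params = p

    # ----------------------------------------------------------- graph wiring
    def _build_relations(self):
        """Per directed relation: global (src, dst) indices, the contiguous
        node-type block the sources live in, and per-edge 1/|N_r(v)| factors."""
        g = self.graph
        off_g = self._offsets[MODALITY_GENE]
        off_c = self._offsets[MODALITY_CPG]
        off_m = self._offsets[MODALITY_MIRNA]
        n_g, n_c, n_m = len(g.gene_ids), len(g.cpg_ids), len(g.mirna_ids)
        block = {MODALITY_GENE: (off_g, off_g + n_g),
                 MODALITY_CPG: (off_c, off_c + n_c),
                 MODALITY_MIRNA: (off_m, off_m + n_m)}
        src_off = {RELATION_GC: off_c, RELATION_MG: off_m}
        src_type = {RELATION_GC: MODALITY_CPG, RELATION_MG: MODALITY_MIRNA}
        self._directed: dict[str, tuple[np.ndarray, np.ndarray, str, tuple]] = {}
        for base in (RELATION_GC, RELATION_MG):
            e = g.edges[base]
            src = e[:, 0] + src_off[base]
            dst = e[:, 1] + off_g
            self._directed[_BASE_DIRECTED[base]] = (src, dst, base,
                                                    block[src_type[base]])
            if self.config.inverse_relations:
                self._directed[_INVERSE_DIRECTED[base]] = (dst, src, base,
                                                           block[MODALITY_GENE])
        self._inv_degree = {}
        self._local_src = {}
        for rel, (src, dst, _, (lo, _hi)) in self._directed.items():
            deg = np.bincount(dst, minlength=self.n_nodes).astype(float)
            deg[deg == 0] = 1.0  # zero-neighbor nodes: relation term omitted
            self._inv_degree[rel] = 1.0 / deg[dst]  # per-edge normalization
            self._local_src[rel] = src - lo
        # reusable concatenated destination vector for the shared scatter
        active = tuple(rel for rel, (src, _, _, _) in self._directed.items()
                       if len(src))
        self._concat_dst = {active: np.concatenate(
            [self._directed[rel][1] for rel in active]) if active
            else np.empty(0, dtype=np.int64)}

    def unit_gates(self, requires_grad: bool = False,
                   batch_size: int | None = None) -> dict[str, Tensor]:
        """Per-base-edge gates, all exactly 1 (shared by both directions).

        With ``batch_size`` the gates are (B, E)-shaped so gradients resolve
        per patient; otherwise a single gate vector is shared by the batch.
        """
        out = {}
        for base in (RELATION_GC, RELATION_MG):
            n_e = len(self.graph.edges[base])
            shape = (n_e,) if batch_size is None else (batch_size, n_e)
            out[base] = Tensor(np.ones(shape), requires_grad=requires_grad)
        return out

    # --------------------------------------------------------------- forward
    def init_node_states(self, batch: PatientBatch,
                         inputs: dict[str, Tensor] | None = None
                         ) -> tuple[Tensor, dict[str, Tensor]]:
        """Layer-0 states: per-type affine lift of the scalar node signals.

        Masked modalities are multiplied by their 0/1 mask inside the graph so
        that gradients with respect to masked features are identically zero.
        """
        batch.validate_against(self.graph)
        B = batch.n_patients
        if inputs is None:
            inputs = {t: Tensor(batch.x[t], requires_grad=True) for t in MODALITIES}
        blocks = []
        for ti, t in enumerate(MODALITIES):
            mask = batch.modality_mask[:, ti:ti + 1]
            x = inputs[t] * mask  # (B, n_t); constant mask zeroes masked grads
            n_t = x.shape[1]
            h = x.reshape(B, n_t, 1) * self.params[f"in_w_{t}"] + self.params[f"in_b_{t}"]
            blocks.append(h)
        states = concat(blocks, axis=1)
        if self.config.node_embeddings:
            states = states + self.params["node_emb"]
        return states, inputs

    def _sigma(self, x: Tensor) -> Tensor:
        if self.config.nonlinearity == "relu":
            return x.relu()
        if self.config.nonlinearity == "tanh":
            return x.tanh()
        raise ValueError(f"unknown nonlinearity {self.config.nonlinearity!r}")

    def rgcn_layer(self, states: Tensor, layer: int,
                   gates: dict[str, Tensor]) -> Tensor:
        """One relation-aware convolution: self term + normalized, gated
        neighbor means per directed relation, then the nonlinearity.

        Sources of each relation live in one contiguous node-type block, so
        the relation transform is applied to the block once and the per-edge
        messages are gathered from the transformed block; all relations then
        share a single scatter into the node axis.
        """
        out = states @ self.params[f"W0_{layer}"]
        msgs_parts, dst_parts = [], []
        for rel, (src, dst, base, (lo, hi)) in self._directed.items():
            if len(src) == 0:
                continue
            transformed = states.take_block(lo, hi) @ self.params[f"W_{rel}_{layer}"]
            msgs = transformed.take_nodes(self._local_src[rel])
            msgs = msgs * self._inv_degree[rel][None, :, None]
            gate = gates.get(base)
            if gate is None:            # implicit unit gates (training fast path)
                pass
            elif gate.ndim == 1:        # one gate per edge, shared across batch
                msgs = msgs * gate.reshape(1, -1, 1)
            else:                       # per-sample gates (edge attribution)
                msgs = msgs * gate.reshape(gate.shape[0], gate.shape[1], 1)
            msgs_parts.append(msgs)
            dst_parts.append(rel)
        if msgs_parts:
            all_msgs = concat(msgs_parts, axis=1)
            out = out + all_msgs.scatter_add_nodes(
                self._concat_dst[tuple(dst_parts)], self.n_nodes)
        return self._sigma(out)

    def _softmax_nodes(self, scores: Tensor) -> Tensor:
        shifted = scores + Tensor(-scores.max_detached(axis=1, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=1, keepdims=True)

    def attentive_readout(self, states: Tensor, t: str) -> tuple[Tensor, Tensor]:
        """Softmax attention over the nodes of type ``t``; weighted sum."""
        lo = self._offsets[t]
        n_t = {MODALITY_GENE: len(self.graph.gene_ids),
               MODALITY_CPG: len(self.graph.cpg_ids),
               MODALITY_MIRNA: len(self.graph.mirna_ids)}[t]
        h_t = states.take_block(lo, lo + n_t)
        scores = (h_t @ self.params[f"read_W_{t}"]).tanh() @ self.params[f"read_a_{t}"]
        alpha = self._softmax_nodes(scores.reshape(-1, n_t))
        B = alpha.shape[0]
        z = (alpha.reshape(B, n_t, 1) * h_t).sum(axis=1)
        return z, alpha

    def fuse_modalities(self, z_mod: dict[str, Tensor],
                        modality_mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Second-stage attention over the *present* modalities only.

        Absent modalities receive β = 0 and contribute nothing to the fused
        vector; β over present modalities sums to 1.
        """
        scores = []
        for t in MODALITIES:
            s = (z_mod[t] @ self.params["fuse_U"]).tanh() @ self.params["fuse_q"]
            scores.append(s.reshape(-1))
        S = stack(scores, axis=1)                       # (B, 3)
        mask = modality_mask.astype(float)
        shifted = S + Tensor(-S.max_detached(axis=1, keepdims=True))
        e = shifted.exp() * mask
        beta = e / e.sum(axis=1, keepdims=True)
        B = beta.shape[0]
        z = None
        for ti, t in enumerate(MODALITIES):
            term = beta[:, ti].reshape(B, 1) * z_mod[t]
            z = term if z is None else z + term
        return z, beta

    def classify(self, z: Tensor) -> tuple[Tensor, Tensor]:
        logits = z @ self.params["out_W"] + self.params["out_b"]
        shifted = logits + Tensor(-logits.max_detached(axis=1, keepdims=True))
        e = shifted.exp()
        probs = e / e.sum(axis=1, keepdims=True)
        return logits, probs

    def forward(self, batch: PatientBatch, gates: dict[str, Tensor] | None = None,
                inputs: dict[str, Tensor] | None = None) -> ForwardTrace:
        # gates=None means implicit unit gates without the multiply; explicit
        # gate tensors are only materialized for edge attribution
        gates = gates if gates is not None else {}
        states, inputs = self.init_node_states(batch, inputs)
        for layer in range(self.config.num_layers):
            states = self.rgcn_layer(states, layer, gates)
        z_mod, alpha = {}, {}
        for t in MODALITIES:
            z_mod[t], alpha[t] = self.attentive_readout(states, t)
        z, beta = self.fuse_modalities(z_mod, batch.modality_mask)
        logits, probs = self.classify(z)
        return ForwardTrace(inputs=inputs, h_final=states, alpha=alpha,
                            z_mod=z_mod, beta=beta, z=z, logits=logits,
                            probs=probs, gates=gates)

    # ----------------------------------------------------------------- losses
    def graph_regularizer(self, h_final: Tensor) -> Tensor:
        """Per-patient Laplacian smoothness: Σ_edges w_uv ||h_u - h_v||²; (B,)."""
        B = h_final.shape[0]
        total = Tensor(np.zeros(B))
        if not hasattr(self, "_reg_endpoints"):
            off_g = self._offsets[MODALITY_GENE]
            src_off = {RELATION_GC: self._offsets[MODALITY_CPG],
                       RELATION_MG: self._offsets[MODALITY_MIRNA]}
            self._reg_endpoints = {
                base: (self.graph.edges[base][:, 0] + src_off[base],
                       self.graph.edges[base][:, 1] + off_g)
                for base in (RELATION_GC, RELATION_MG)
                if len(self.graph.edges[base])}
        for base, (u, v) in self._reg_endpoints.items():
            diff = h_final.take_nodes(u) - h_final.take_nodes(v)
            w = self.graph.edge_weights[base]
            per_edge = diff.square().sum(axis=2) * w          # (B, E)
            total = total + per_edge.sum(axis=1)
        return total

    def weight_norm(self) -> Tensor:
        acc = None
        for tensor in self.params.values():
            s = tensor.square().sum()
            acc = s if acc is None else acc + s
        return acc

    def total_loss(self, trace: ForwardTrace, labels: np.ndarray,
                   lambda_gr: float | None = None,
                   lambda_wd: float | None = None,
                   sample_weights: np.ndarray | None = None) -> Tensor:
        """Mean cross-entropy + λ_gr · mean graph penalty + λ_wd · ||Θ||².

        ``sample_weights`` (normalized to mean 1) reweight the per-sample
        cross-entropy, e.g. inverse class frequencies on imbalanced cohorts.
        """
        lam_gr = self.config.lambda_gr if lambda_gr is None else lambda_gr
        lam_wd = self.config.lambda_wd if lambda_wd is None else lambda_wd
        B = trace.probs.shape[0]
        picked = trace.probs[np.arange(B), np.asarray(labels)]
        if sample_weights is not None:
            w = np.asarray(sample_weights, dtype=float)
            loss = -((picked.log() * (w / w.mean())).mean())
        else:
            loss = -(picked.log().mean())
        if lam_gr and self.graph.n_edges:
            # normalized per edge so lambda_gr is invariant to graph size,
            # mirroring the batch-mean reduction of the cross-entropy term
            penalty = self.graph_regularizer(trace.h_final).mean() \
                * (1.0 / self.graph.n_edges)
            loss = loss + lam_gr * penalty
        if lam_wd:
            loss = loss + lam_wd * self.weight_norm()
        return loss

    def reinitialize(self, rng: np.random.Generator):
        """Redraw all parameters in place (used for training restarts)."""
        self.__init__(self.graph, self.config, rng=rng)

    # ------------------------------------------------------------ persistence
    def parameter_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def save(self, path):
        payload = {k: v.data for k, v in self.params.items()}
        meta = json.dumps({"config": self.config.to_dict(),
                           "graph_fingerprint": self.graph.fingerprint()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **payload)

    @classmethod
    def load(cls, path, graph: HeteroGraph) -> "CrossOmicsNet":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            if meta["graph_fingerprint"] != graph.fingerprint():
                raise ValueError("checkpoint was trained against a different graph")
            model = cls(graph, ModelConfig(**meta["config"]))
            model.load_state_dict({k: archive[k] for k in archive.files
                                   if k != "__meta__"})
        return model
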