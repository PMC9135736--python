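"""Two-stream attention network for peptide-binding residue prediction.

The network keeps a protein stream (n residues) and a peptide stream
(m residues). Each block applies, in order: contextual attention on the
protein stream (graph attention over the k-NN residue graph in struct mode,
ordinary self-attention in seq mode), self-attention on the peptide stream,
a reciprocal cross-attention module that updates both streams from a single
shared query/key product, and position-wise feed-forward layers. Every
sub-layer is wrapped post-norm style: x = LayerNorm(x + Dropout(Sublayer(x))).

Reciprocal attention is the distinguishing piece: protein embeddings supply
the queries Q and one value set V_prot, peptide embeddings supply the keys K
and the other value set V_pep, and

    update_prot = softmax(Q K^T / sqrt(d_k)) V_pep
    update_pep  = softmax(K Q^T / sqrt(d_k)) V_prot

so the unnormalized attention logits of the two directions are exact
transposes of one another — information about who attends to whom is shared
symmetrically between the binding partners.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .embeddings import one_hot_sequence
from .features import EDGE_DIM, NODE_DIM, ResidueGraph


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are the published operating point (embedding width 64,
    feed-forward width 64, key width 64, value width 128, dropout 0.2,
    six reciprocal blocks of six heads each). ``d_node``/``d_edge`` describe
    the structural feature tensors; ``lm_dim`` is the width of an optional
    frozen language-model embedding concatenated to the node features.
    """

    d_model: int = 64
    d_i: int = 64
    d_k: int = 64
    d_v: int = 128
    heads: int = 6
    n_blocks: int = 6
    dropout: float = 0.2
    mode: str = "struct"
    d_node: int = NODE_DIM
    d_edge: int = EDGE_DIM
    lm_dim: int = 0
    graph_k: int = 30  # neighbor count the struct-mode featurization uses
    peptide_positions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_model", "d_i", "d_k", "d_v", "heads", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.mode not in ("struct", "seq"):
            raise ValueError("mode must be 'struct' or 'seq'")


@dataclass
class PredictionResult:
    """Per-protein-residue binding probabilities and raw class scores."""

    probs: np.ndarray  # (n,) probability of the binding class
    scores: np.ndarray  # (n, 2) pre-softmax class scores
    attention: list | None = None


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with the softmax taken along rows."""
    d_k = Q.shape[-1]
    logits = (Q @ K.T) * (1.0 / np.sqrt(d_k))
    return logits.softmax(axis=-1) @ V


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class ReciprocalAttentionNetwork:
    """The full stacked model. Parameters live in a flat name->Tensor dict.

    Construction is deterministic given ``config.seed`` (Xavier-uniform
    initialization). Use :meth:`forward` for predictions and
    ``save``/``load`` for checkpointing.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()
        self.training = False

    # -- parameter helpers -------------------------------------------------

    def _xavier(self, name: str, din: int, dout: int) -> None:
        bound = np.sqrt(6.0 / (din + dout))
        self.params[name] = Tensor(
            self._rng.uniform(-bound, bound, size=(din, dout)), requires_grad=True
        )
        self.params[name + ".b"] = Tensor(np.zeros(dout), requires_grad=True)

    def _ln(self, name: str, dim: int) -> None:
        self.params[name + ".g"] = Tensor(np.ones(dim), requires_grad=True)
        self.params[name + ".beta"] = Tensor(np.zeros(dim), requires_grad=True)

    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[name] + self.params[name + ".b"]

    def _build(self) -> None:
        c = self.config
        d_in = (c.d_node + c.lm_dim) if c.mode == "struct" else (21 + c.lm_dim)
        self._xavier("prot_in", d_in, c.d_model)
        self._xavier("pep_in", 21, c.d_model)
        for b in range(c.n_blocks):
            p = f"block{b}."
            for h in range(c.heads):
                hp = f"{p}protattn.h{h}."
                if c.mode == "struct":
                    self._xavier(hp + "Wq", c.d_model, c.d_k)
                    self._xavier(hp + "Wk", c.d_model + c.d_edge, c.d_k)
                    self._xavier(hp + "Wv", c.d_model + c.d_edge, c.d_v)
                else:
                    self._xavier(hp + "Wq", c.d_model, c.d_k)
                    self._xavier(hp + "Wk", c.d_model, c.d_k)
                    self._xavier(hp + "Wv", c.d_model, c.d_v)
                hp = f"{p}pepattn.h{h}."
                for w, dout in (("Wq", c.d_k), ("Wk", c.d_k), ("Wv", c.d_v)):
                    self._xavier(hp + w, c.d_model, dout)
                hp = f"{p}recip.h{h}."
                self._xavier(hp + "Wq", c.d_model, c.d_k)
                self._xavier(hp + "Wk", c.d_model, c.d_k)
                self._xavier(hp + "Wvprot", c.d_model, c.d_v)
                self._xavier(hp + "Wvpep", c.d_model, c.d_v)
            self._xavier(p + "protattn.Wout", c.heads * c.d_v, c.d_model)
            self._xavier(p + "pepattn.Wout", c.heads * c.d_v, c.d_model)
            self._xavier(p + "recip.Wout_prot", c.heads * c.d_v, c.d_model)
            self._xavier(p + "recip.Wout_pep", c.heads * c.d_v, c.d_model)
            self._xavier(p + "prot_ff.W1", c.d_model, c.d_i)
            self._xavier(p + "prot_ff.W2", c.d_i, c.d_model)
            self._xavier(p + "pep_ff.W1", c.d_model, c.d_i)
            self._xavier(p + "pep_ff.W2", c.d_i, c.d_model)
            for ln in ("ln_protattn", "ln_pepattn", "ln_recip_prot", "ln_recip_pep",
                       "ln_prot_ff", "ln_pep_ff"):
                self._ln(p + ln, c.d_model)
        self._xavier("out", c.d_model, 2)

    # -- sub-layers --------------------------------------------------------

    def _sublayer(self, x: Tensor, y: Tensor, ln: str, rng) -> Tensor:
        y = y.dropout(self.config.dropout, rng, self.training)
        return (x + y).layer_norm(self.params[ln + ".g"], self.params[ln + ".beta"])

    def _self_attention(self, x: Tensor, prefix: str) -> Tensor:
        heads = []
        for h in range(self.config.heads):
            hp = f"{prefix}.h{h}."
            Q = self._linear(hp + "Wq", x)
            K = self._linear(hp + "Wk", x)
            V = self._linear(hp + "Wv", x)
            heads.append(scaled_dot_attention(Q, K, V))
        return self._linear(prefix + ".Wout", concat(heads, axis=-1))

    def _graph_attention(self, x: Tensor, graph: ResidueGraph, prefix: str) -> Tensor:
        """Attention restricted to graph neighbors; keys and values are built
        from the concatenation of the neighbor embedding and edge features."""
        c = self.config
        edge = Tensor(graph.edge_features)  # (L, K, d_edge)
        nbr = x.gather_rows(graph.neighbor_idx)  # (L, K, d_model)
        ctx = concat([nbr, edge], axis=-1)  # (L, K, d_model + d_edge)
        heads = []
        for h in range(c.heads):
            hp = f"{prefix}.h{h}."
            Q = self._linear(hp + "Wq", x)  # (L, d_k)
            K = self._linear(hp + "Wk", ctx)  # (L, K, d_k)
            V = self._linear(hp + "Wv", ctx)  # (L, K, d_v)
            logits = (K @ Q.reshape(len(graph), c.d_k, 1)).reshape(
                len(graph), graph.neighbor_idx.shape[1]
            ) * (1.0 / np.sqrt(c.d_k))
            w = logits.softmax(axis=-1)  # (L, K)
            out = (w.reshape(len(graph), 1, -1) @ V).reshape(len(graph), c.d_v)
            heads.append(out)
        return self._linear(prefix + ".Wout", concat(heads, axis=-1))

    def _reciprocal(self, prot: Tensor, pep: Tensor, prefix: str, collect=None):
        c = self.config
        prot_heads, pep_heads = [], []
        for h in range(c.heads):
            hp = f"{prefix}.h{h}."
            Q = self._linear(hp + "Wq", prot)
            K = self._linear(hp + "Wk", pep)
            Vprot = self._linear(hp + "Wvprot", prot)
            Vpep = self._linear(hp + "Wvpep", pep)
            logits = (Q @ K.T) * (1.0 / np.sqrt(c.d_k))  # (n, m); shared product
            logits_t = logits.T  # (m, n): exact transpose by construction
            prot_heads.append(logits.softmax(axis=-1) @ Vpep)
            pep_heads.append(logits_t.softmax(axis=-1) @ Vprot)
            if collect is not None:
                collect.append((logits.data, logits_t.data))
        return (
            self._linear(prefix + ".Wout_prot", concat(prot_heads, axis=-1)),
            self._linear(prefix + ".Wout_pep", concat(pep_heads, axis=-1)),
        )

    def _ffn(self, x: Tensor, prefix: str) -> Tensor:
        h = self._linear(prefix + ".W1", x).relu()
        return self._linear(prefix + ".W2", h)

    # -- forward -----------------------------------------------------------

    def _protein_input(self, protein_repr) -> tuple[Tensor, ResidueGraph | None]:
        c = self.config
        if c.mode == "struct":
            if not isinstance(protein_repr, ResidueGraph):
                raise TypeError("struct mode requires a ResidueGraph input")
            feats = protein_repr.node_features
            if c.lm_dim:
                if protein_repr.lm_embedding is None:
                    raise ValueError("model expects a language-model embedding on the graph")
                feats = np.concatenate([feats, protein_repr.lm_embedding], axis=-1)
            return self._linear("prot_in", Tensor(feats)), protein_repr
        feats = np.asarray(protein_repr, dtype=float)
        x = self._linear("prot_in", Tensor(feats))
        x = x + sinusoidal_positions(feats.shape[0], c.d_model)
        return x, None

    def forward(
        self,
        protein_repr,
        peptide_seq: str,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> PredictionResult:
        """Run the network.

        ``protein_repr`` is a :class:`ResidueGraph` in struct mode or an
        (L, 21 + lm_dim) embedded sequence in seq mode; ``peptide_seq`` is a
        plain amino-acid string (never empty — peptide-agnostic scanning
        supplies a poly-glycine probe instead).
        """
        if not peptide_seq:
            raise ValueError(
                "empty peptide: for peptide-agnostic prediction pass a poly-glycine probe"
            )
        c = self.config
        rng = rng or np.random.default_rng(0)
        prot, graph = self._protein_input(protein_repr)
        pep = self._linear("pep_in", Tensor(one_hot_sequence(peptide_seq)))
        if c.peptide_positions:
            pep = pep + sinusoidal_positions(len(peptide_seq), c.d_model)

        collected: list | None = [] if collect_attention else None
        for b in range(c.n_blocks):
            p = f"block{b}."
            if c.mode == "struct":
                upd = self._graph_attention(prot, graph, p + "protattn")
            else:
                upd = self._self_attention(prot, p + "protattn")
            prot = self._sublayer(prot, upd, p + "ln_protattn", rng)
            pep = self._sublayer(pep, self._self_attention(pep, p + "pepattn"), p + "ln_pepattn", rng)
            block_logits: list | None = [] if collect_attention else None
            prot_upd, pep_upd = self._reciprocal(prot, pep, p + "recip", block_logits)
            prot = self._sublayer(prot, prot_upd, p + "ln_recip_prot", rng)
            pep = self._sublayer(pep, pep_upd, p + "ln_recip_pep", rng)
            prot = self._sublayer(prot, self._ffn(prot, p + "prot_ff"), p + "ln_prot_ff", rng)
            pep = self._sublayer(pep, self._ffn(pep, p + "pep_ff"), p + "ln_pep_ff", rng)
            if collect_attention:
                collected.append(block_logits)

        scores = self._linear("out", prot)
        probs = scores.softmax(axis=-1)
        self._last_probs = probs  # kept for the training loss
        self._last_scores = scores
        return PredictionResult(
            probs=probs.data[:, 1].copy(), scores=scores.data.copy(), attention=collected
        )

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise ValueError(f"checkpoint/model parameter mismatch: {sorted(missing)[:5]}")
        bad = [k for k in state if state[k].shape != self.params[k].data.shape]
        if bad:
            raise ValueError(f"checkpoint shape mismatch for tensors: {bad[:5]}")
        for k in state:
            self.params[k].data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"config": asdict(self.config)}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReciprocalAttentionNetwork":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]))
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
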