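"""Sequence encodings: one-hot and pluggable frozen language-model embeddings.

The language-model slot is an input featurizer, never trained. Three
embedders are exposed: ``onehot`` (21-dim indicators), ``mock`` (a
deterministic 32-dim stand-in keyed on residue identity and position, so the
full pipeline is testable without downloads), and ``protbert`` (a real
transformer adapter that requires the optional ``transformers`` dependency
and downloaded weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AMINO_ACIDS, UNK

MOCK_DIM = 32
PROTBERT_DIM = 1024


@dataclass(frozen=True)
class EmbedderSpec:
    name: str = "onehot"
    dim: int = 21
    frozen: bool = True

    @classmethod
    def make(cls, name: str) -> "EmbedderSpec":
        dims = {"onehot": 21, "mock": MOCK_DIM, "protbert": PROTBERT_DIM}
        if name not in dims:
            raise ValueError(f"unknown embedder {name!r}; choose from {sorted(dims)}")
        return cls(name=name, dim=dims[name])


def one_hot_sequence(seq: str) -> np.ndarray:
    """(L, 21) indicator matrix; 'X' maps to the UNK column (index 20)."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    out = np.zeros((len(seq), 21))
    for i, aa in enumerate(seq):
        if aa in AMINO_ACIDS:
            out[i, AMINO_ACIDS.index(aa)] = 1.0
        elif aa == UNK:
            out[i, 20] = 1.0
        else:
            raise ValueError(f"illegal amino acid {aa!r} at position {i + 1}")
    return out


def mock_embedding(seq: str, dim: int = MOCK_DIM) -> np.ndarray:
    """Deterministic per-residue vectors keyed on (identity, position).

    Each row is drawn from a generator seeded with the residue letter and
    its position, so the matrix is bit-identical across processes and runs
    while still being position-dependent like a real contextual embedding.
    """
    out = np.empty((len(seq), dim))
    for i, aa in enumerate(seq):
        rng = np.random.default_rng([ord(aa), i, 77003])
        out[i] = rng.standard_normal(dim)
    return out


def protbert_embedding(seq: str) -> np.ndarray:  # pragma: no cover - needs downloads
    try:
        import torch  # noqa: F401
        from transformers import BertModel, BertTokenizer
    except ImportError as exc:
        raise RuntimeError(
            "the protbert embedder needs the optional 'transformers' and 'torch' "
            "dependencies plus downloaded weights; use --embedder mock for an "
            "offline deterministic stand-in"
        ) from exc
    tokenizer = BertTokenizer.from_pretrained("Rostlab/prot_bert", do_lower_case=False)
    model = BertModel.from_pretrained("Rostlab/prot_bert")
    model.eval()
    tokens = tokenizer(" ".join(seq), return_tensors="pt")
    with torch.no_grad():
        hidden = model(**tokens).last_hidden_state[0, 1:-1]
    return hidden.numpy().astype(float)


def embed_protein(seq: str, spec: EmbedderSpec) -> np.ndarray:
    """(L, spec.dim) embedding matrix, deterministic per (seq, spec)."""
    if spec.name == "onehot":
        return one_hot_sequence(seq)
    if spec.name == "mock":
        return mock_embedding(seq, spec.dim)
    if spec.name == "protbert":
        return protbert_embedding(seq)
    raise ValueError(f"unknown embedder {spec.name!r}")
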