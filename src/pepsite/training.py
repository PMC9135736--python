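"""Training protocol: weighted cross-entropy, Adam, early stopping, transfer.

The published recipe is transfer learning: pre-train on fragment complexes
(at most 150,000 iterations, learning rate 1e-4), then fine-tune on real
peptide complexes (at most 35,000 iterations; 1e-4 in struct mode, 1e-5 in
seq mode). The loss is a class-weighted cross-entropy — binding residues are
rare, so classes are weighted by inverse frequency — and during fine-tuning
each example is additionally weighted by the inverse of its sequence-cluster
size so large redundant families do not dominate. Early stopping tracks the
validation loss and keeps the best-validation checkpoint. One complex is
processed per iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .model import ModelConfig, ReciprocalAttentionNetwork

PRETRAIN_MAX_ITERS = 150_000
FINETUNE_MAX_ITERS = 35_000
STRUCT_LR = 1e-4
SEQ_FINETUNE_LR = 1e-5


@dataclass
class TrainConfig:
    lr: float = STRUCT_LR
    max_iters: int = FINETUNE_MAX_ITERS
    patience: int = 10  # evaluations without improvement before stopping
    eval_every: int = 50
    batch_size: int = 1
    seed: int = 0
    phase: str = "finetune"

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError("phase must be 'pretrain' or 'finetune'")


@dataclass
class TrainingExample:
    """One complex ready for the model: featurized protein input, peptide
    sequence, per-residue labels and the record's cluster-based weight."""

    protein_repr: object
    peptide_seq: str
    labels: np.ndarray
    example_weight: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def class_weights(label_arrays: list[np.ndarray]) -> np.ndarray:
    """Inverse-frequency class weights (non-binding, binding), mean 1."""
    flat = np.concatenate([np.asarray(a, dtype=int).ravel() for a in label_arrays])
    counts = np.bincount(flat, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present to compute class weights")
    freqs = counts / counts.sum()
    w = 1.0 / freqs
    return w / w.mean()


def example_weights(cluster_ids: list[int]) -> np.ndarray:
    """Per-record weight 1 / (size of the record's sequence cluster)."""
    ids, counts = np.unique(np.asarray(cluster_ids), return_counts=True)
    size = dict(zip(ids.tolist(), counts.tolist()))
    return np.array([1.0 / size[c] for c in cluster_ids])


def weighted_ce_loss(
    probs: Tensor,
    labels: np.ndarray,
    class_w: np.ndarray = (1.0, 1.0),
    example_w: float = 1.0,
) -> Tensor:
    """Mean over residues of example_w * class_w[label] * (-log p_label)."""
    labels = np.asarray(labels, dtype=int)
    cw = np.asarray(class_w, dtype=float)[labels]
    logp = probs.take_column(labels).log()
    return (logp * (-example_w * cw)).mean()


@dataclass
class TrainHistory:
    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    eval_iterations: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_val: float = float("inf")
    best_iteration: int = -1
    stopped_early: bool = False

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, tl in zip(self.iterations, self.train_loss):
                fh.write(json.dumps({"iteration": i, "train_loss": tl}) + "\n")
            for i, vl in zip(self.eval_iterations, self.val_loss):
                fh.write(json.dumps({"iteration": i, "val_loss": vl}) + "\n")


def _forward_loss(
    model: ReciprocalAttentionNetwork,
    ex: TrainingExample,
    class_w: np.ndarray,
    use_example_w: bool,
    rng: np.random.Generator,
) -> Tensor:
    model.forward(ex.protein_repr, ex.peptide_seq, rng=rng)
    probs = model._last_probs
    ew = ex.example_weight if use_example_w else 1.0
    return weighted_ce_loss(probs, ex.labels, class_w, ew)


def evaluate_loss(
    model: ReciprocalAttentionNetwork,
    examples: list[TrainingExample],
    class_w: np.ndarray,
    use_example_w: bool,
) -> float:
    model.training = False
    rng = np.random.default_rng(0)
    losses = [float(_forward_loss(model, ex, class_w, use_example_w, rng).data)
              for ex in examples]
    return float(np.mean(losses))


def train(
    model: ReciprocalAttentionNetwork,
    train_set: list[TrainingExample],
    val_set: list[TrainingExample],
    config: TrainConfig,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Run the optimization loop; returns (best-validation state, history).

    Fully seeded: example order and dropout masks derive from
    ``config.seed``. The model is left holding the best-validation weights.
    Raises on a non-finite loss with the offending iteration in the message.
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    cw = class_weights([ex.labels for ex in train_set])
    use_ew = config.phase == "finetune"
    opt = Adam(model.params, lr=config.lr)
    history = TrainHistory()
    best_state = model.state_dict()
    bad_evals = 0
    order: list[int] = []

    for it in range(1, config.max_iters + 1):
        if not order:
            order = rng.permutation(len(train_set)).tolist()
        ex = train_set[order.pop()]
        model.training = True
        loss = _forward_loss(model, ex, cw, use_ew, rng)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.iterations.append(it)
        history.train_loss.append(float(loss.data))

        if val_set and it % config.eval_every == 0:
            vl = evaluate_loss(model, val_set, cw, use_ew)
            history.eval_iterations.append(it)
            history.val_loss.append(vl)
            if vl < history.best_val:
                history.best_val = vl
                history.best_iteration = it
                best_state = model.state_dict()
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= config.patience:
                    history.stopped_early = True
                    break

    if not val_set:
        best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.training = False
    return best_state, history


def transfer(checkpoint_path: str | Path, model: ReciprocalAttentionNetwork) -> ReciprocalAttentionNetwork:
    """Load pre-trained weights into an architecture-compatible model.

    Refuses checkpoints from the other input mode and reports any tensors
    whose shapes disagree.
    """
    path = Path(checkpoint_path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    ckpt_mode = meta["config"]["mode"]
    if ckpt_mode != model.config.mode:
        raise ValueError(
            f"checkpoint was trained in {ckpt_mode!r} mode; model is {model.config.mode!r}"
        )
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
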