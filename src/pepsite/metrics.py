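"""Per-residue evaluation metrics and structural comparison utilities."""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class MetricReport:
    roc_auc: float
    mcc: float
    top_k_hit: bool
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


def roc_auc(probs, labels) -> float:
    """Probability that a random binding residue outranks a random
    non-binding one, ties counted one half (standard ROC AUC)."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("ROC AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


def mcc(pred_flags, labels) -> float:
    """Matthews correlation coefficient; 0 by convention on zero marginals."""
    p = np.asarray(pred_flags, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    tp = int(np.sum(p & y))
    fp = int(np.sum(p & ~y))
    tn = int(np.sum(~p & ~y))
    fn = int(np.sum(~p & y))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def top_k_hit(probs, labels, k: int = 10) -> bool:
    """True iff at least one true binding residue appears among the k
    highest-probability residues (probability ties broken by lower index)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(probs) < k:
        raise ValueError(f"need at least k={k} residues, got {len(probs)}")
    order = np.lexsort((np.arange(len(probs)), -probs))
    return bool(labels[order[:k]].any())


def evaluate(probs, labels, threshold: float = 0.5, k: int = 10) -> MetricReport:
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = probs >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return MetricReport(
        roc_auc=roc_auc(probs, y),
        mcc=mcc(pred, y),
        top_k_hit=top_k_hit(probs, y, k=min(k, len(probs))),
        threshold=threshold,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def kabsch_rmsd(coords_a, coords_b) -> float:
    """RMSD after optimal reflection-free least-squares superposition.

    Centroids are removed, the optimal rotation is taken from the SVD of the
    covariance matrix with the determinant sign corrected so no reflection
    sneaks in, and the RMSD of the superposed clouds is returned.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    U, _, Vt = np.linalg.svd(a0.T @ b0)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = a0 - b0 @ R.T
    return float(np.sqrt((diff**2).sum() / len(a)))


def conformational_change(peptide_ca, reference_ca_sets, cutoff: float = 2.5) -> bool:
    """Flag a peptide as undergoing a conformational change when its Cα-RMSD
    to any reference conformation reaches the cutoff (2.5 Å, inclusive)."""
    pep = np.asarray(peptide_ca, dtype=float)
    if not len(reference_ca_sets):
        raise ValueError("need at least one reference conformation")
    for ref in reference_ca_sets:
        ref = np.asarray(ref, dtype=float)
        if ref.shape != pep.shape:
            warnings.warn(
                f"reference with {len(ref)} points skipped (peptide has {len(pep)})",
                stacklevel=2,
            )
            continue
        if kabsch_rmsd(pep, ref) >= cutoff:
            return True
    return False
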