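"""Peptide-agnostic binding-site scoring.

A trained model queried with a poly-glycine probe peptide (length 10 by
default) yields per-residue binding probabilities for any protein, without
committing to a binding partner. A single scalar score then summarizes how
confidently the protein presents a peptide-binding site:

    score = max over n of  alpha * mean(top-n probabilities)
                           + (1 - alpha) * pdf(n / N)

where the pdf is a Gaussian fitted to the per-protein fraction of binding
residues in the training data and N is the protein length. The first term
rewards a cluster of high-probability residues; the second rewards a site
whose size looks like a real binding site. The published weighting is
alpha = 0.955 for structure input and 0.965 for sequence input; alpha can
also be re-calibrated on a validation set by maximizing the correlation
between scores and per-protein prediction quality (MCC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, spearmanr

from .model import PredictionResult, ReciprocalAttentionNetwork

#: Published score weightings for the two input modes.
STRUCT_ALPHA = 0.955
SEQ_ALPHA = 0.965
DEFAULT_PROBE_LEN = 10


@dataclass
class GaussianPrior:
    """Gaussian over the fraction of a protein's residues that bind."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValueError("mu must lie strictly between 0 and 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def pdf(self, x) -> np.ndarray:
        return norm.pdf(x, loc=self.mu, scale=self.sigma)


@dataclass
class BindingSiteScore:
    score: float
    n_star: int
    alpha: float
    N: int


def fit_prior(training_label_masks: list[np.ndarray]) -> GaussianPrior:
    """Sample mean and SD of the per-protein binding-residue fraction."""
    if len(training_label_masks) < 2:
        raise ValueError("need at least 2 proteins to fit the prior")
    fractions = np.array([np.asarray(m, dtype=float).mean() for m in training_label_masks])
    sigma = float(fractions.std(ddof=1))
    if sigma == 0:
        raise ValueError("zero variance in binding fractions; prior undefined")
    return GaussianPrior(mu=float(fractions.mean()), sigma=sigma)


def _score_components(probs: np.ndarray, prior: GaussianPrior) -> tuple[np.ndarray, np.ndarray]:
    """Per-n arrays: mean of the top-n probabilities, and pdf(n/N)."""
    p = np.sort(np.asarray(probs, dtype=float))[::-1]
    N = len(p)
    n = np.arange(1, N + 1)
    top_mean = np.cumsum(p) / n
    return top_mean, prior.pdf(n / N)


def site_score(probs, prior: GaussianPrior, alpha: float) -> BindingSiteScore:
    """Maximize the alpha-weighted score over the site size n = 1..N.

    Ties go to the smaller n. The pdf is evaluated at n/N with the fitted
    Gaussian as-is (no renormalization to the unit interval).
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    if probs.size < 1:
        raise ValueError("need at least one residue probability")
    top_mean, pdf = _score_components(probs, prior)
    s = alpha * top_mean + (1 - alpha) * pdf
    n_star = int(np.argmax(s)) + 1
    return BindingSiteScore(score=float(s[n_star - 1]), n_star=n_star, alpha=alpha,
                            N=len(probs))


def peptide_agnostic_predict(
    model: ReciprocalAttentionNetwork,
    protein_repr,
    probe_len: int = DEFAULT_PROBE_LEN,
) -> PredictionResult:
    """Forward pass with a poly-glycine probe as the peptide."""
    model.training = False
    return model.forward(protein_repr, "G" * probe_len)


def calibrate_alpha(
    per_protein_probs: list[np.ndarray],
    per_protein_mcc: list[float],
    prior: GaussianPrior,
    grid_step: float = 0.005,
    method: str = "pearson",
) -> float:
    """Grid-search alpha to maximize the correlation between each protein's
    site score and its prediction MCC on a validation set.

    Ties resolve to the smaller alpha. Raises when the scores carry no
    signal (constant at every alpha).
    """
    if len(per_protein_probs) < 3:
        raise ValueError("need at least 3 proteins to calibrate alpha")
    mccs = np.asarray(per_protein_mcc, dtype=float)
    if not np.isfinite(mccs).all():
        raise ValueError("all MCC values must be finite")
    components = [_score_components(p, prior) for p in per_protein_probs]
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    best_alpha, best_corr = None, -np.inf
    for alpha in grid:
        scores = np.array(
            [float(np.max(alpha * tm + (1 - alpha) * pdf)) for tm, pdf in components]
        )
        if np.ptp(scores) == 0 or np.ptp(mccs) == 0:
            continue
        if method == "pearson":
            corr = float(np.corrcoef(scores, mccs)[0, 1])
        elif method == "spearman":
            corr = float(spearmanr(scores, mccs).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        if np.isnan(corr):
            continue
        if corr > best_corr + 1e-12:
            best_corr = corr
            best_alpha = float(alpha)
    if best_alpha is None:
        raise ValueError("scores are constant at every alpha; cannot calibrate")
    return best_alpha


def rank_candidates(
    scored_proteins: list[tuple[str, float]],
    reference_scores,
) -> list[dict]:
    """Sort candidates by descending score (stable under ties) and flag the
    ones scoring above the mean of a reference set of known binders."""
    ref_mean = float(np.mean(reference_scores)) if len(reference_scores) else float("inf")
    order = sorted(range(len(scored_proteins)), key=lambda i: -scored_proteins[i][1])
    return [
        {
            "id": scored_proteins[i][0],
            "score": scored_proteins[i][1],
            "rank": rank + 1,
            "above_reference": scored_proteins[i][1] > ref_mean,
        }
        for rank, i in enumerate(order)
    ]
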