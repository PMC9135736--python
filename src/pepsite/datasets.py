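"""Dataset construction: binding labels, filters, clustering and splits.

The rules are the ones used to curate peptide-protein complexes for
training: a crystal structure at 2.5 Å resolution or better, a receptor
chain of more than 30 residues bound to a partner of at most 25, a buried
surface area of at least 400 Å², binding residues defined by a 6 Å
heavy-atom distance, redundancy handled by 30%-identity clustering with a
cluster-level 90/10 train/validation split. Fragment ("hot segment")
complexes for pre-training are contiguous 5-25-residue windows of a partner
chain scored by a simplified contact count — a documented stand-in for the
interface energies used at scale, NOT equivalent to them; the filter logic
around the score (mean + 1 SD of the peptide-complex distribution, 400 Å²
BSA) is faithful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sasa import buried_surface_area
from .structure import ProteinStructure

logger = logging.getLogger(__name__)

BINDING_CUTOFF = 6.0
RESOLUTION_CUTOFF = 2.5
MIN_RECEPTOR_LEN = 30  # receptor must be strictly longer
MAX_PARTNER_LEN = 25
MIN_BSA = 400.0
FRAGMENT_CONTACT_CUTOFF = 5.0


@dataclass
class ComplexRecord:
    """One receptor-partner pair with per-receptor-residue binding labels."""

    receptor: ProteinStructure
    partner: ProteinStructure
    labels: np.ndarray
    resolution: float | None = None
    bsa: float = float("nan")
    cluster_id: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.labels) != len(self.receptor):
            raise ValueError("labels must align with receptor residues")


@dataclass
class FragmentRecord:
    """A contiguous partner-chain window paired with its receptor."""

    receptor: ProteinStructure
    fragment: ProteinStructure
    start: int
    length: int
    interface_score: float
    bsa: float | None = None

    def __post_init__(self) -> None:
        if not 5 <= self.length <= 25:
            raise ValueError("fragment length must be within 5..25")


@dataclass
class DatasetSplit:
    train: list[int]
    val: list[int]
    cluster_to_split: dict[int, str]
    seed: int


def annotate_binding_residues(
    receptor: ProteinStructure,
    partner: ProteinStructure | None,
    cutoff: float = BINDING_CUTOFF,
) -> np.ndarray:
    """Flag receptor residues with any heavy atom within ``cutoff`` Å of any
    partner heavy atom (strict inequality; neighbor-tree accelerated)."""
    labels = np.zeros(len(receptor), dtype=bool)
    if partner is None or len(partner) == 0:
        return labels
    pcoords, _, _ = partner.heavy_atoms()
    tree = cKDTree(pcoords)
    rcoords, _, owner = receptor.heavy_atoms()
    dists, _ = tree.query(rcoords, k=1)
    hit = dists < cutoff
    labels[np.unique(owner[hit])] = True
    return labels


def filter_peptide_complexes(
    records: list[ComplexRecord],
) -> tuple[list[ComplexRecord], list[tuple[str, str]]]:
    """Apply the four curation rules; returns (kept, [(source_id, reason)]).

    Keep iff resolution ≤ 2.5 Å ("2.5 Å or better"), receptor > 30 aa,
    partner ≤ 25 aa, and BSA ≥ 400 Å². A record without a reported
    resolution is excluded with a logged reason. Rules are evaluated
    independently so the surviving set never depends on their order.
    """
    kept, excluded = [], []
    for rec in records:
        reasons = []
        if rec.resolution is None:
            reasons.append("missing resolution")
        elif rec.resolution > RESOLUTION_CUTOFF:
            reasons.append(f"resolution {rec.resolution:.2f} Å worse than 2.5 Å")
        if len(rec.receptor) <= MIN_RECEPTOR_LEN:
            reasons.append(f"receptor length {len(rec.receptor)} not > {MIN_RECEPTOR_LEN}")
        if len(rec.partner) > MAX_PARTNER_LEN:
            reasons.append(f"partner length {len(rec.partner)} > {MAX_PARTNER_LEN}")
        if not rec.bsa >= MIN_BSA:  # also catches NaN
            reasons.append(f"buried surface area {rec.bsa:.0f} Å² < {MIN_BSA:.0f} Å²")
        if reasons:
            for r in reasons:
                logger.info("excluding %s: %s", rec.source_id, r)
                excluded.append((rec.source_id, r))
        else:
            kept.append(rec)
    return kept, excluded


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -1.0
        # stiff gap opening keeps alignments of unrelated sequences from
        # fragmenting into match-enriched islands, which would inflate the
        # matches-per-aligned-column identity
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment sequence identity and coverage, both in percent.

    Identity = matches / aligned columns (columns where both sequences have
    a residue); coverage = aligned columns / length of the shorter sequence.
    These conventions differ slightly from MMseqs2's defaults; they are the
    package's documented choice.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    matches = 0
    cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        cols += a1 - a0
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * cols / min(len(a), len(b))
    return identity, coverage


def greedy_cluster(seqs: list[str], threshold: float = 30.0) -> list[list[int]]:
    """Longest-first greedy centroid clustering at an identity threshold.

    Sequences are visited longest first (ties by input order); each joins
    the first existing cluster whose centroid it matches at ≥ threshold %
    identity, else founds a new cluster. The first index of each cluster is
    its centroid. A built-in stand-in for an external clustering tool.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    clusters: list[list[int]] = []
    for i in order:
        for cl in clusters:
            ident, _ = pairwise_identity(seqs[i], seqs[cl[0]])
            if ident >= threshold:
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def assign_cluster_ids(records: list[ComplexRecord], threshold: float = 30.0) -> list[list[int]]:
    clusters = greedy_cluster([r.receptor.sequence for r in records], threshold)
    for cid, members in enumerate(clusters):
        for i in members:
            records[i].cluster_id = cid
    return clusters


def split_clusters(
    clusters: list[list[int]], train_frac: float = 0.9, seed: int = 0
) -> DatasetSplit:
    """Cluster-level shuffle and split: ~90% of clusters to train, the rest
    to validation. No cluster ever spans both splits."""
    n = len(clusters)
    if n < 2:
        raise ValueError("need at least 2 clusters to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    train_clusters = set(order[:n_train].tolist())
    train, val = [], []
    cluster_to_split = {}
    for cid, members in enumerate(clusters):
        if cid in train_clusters:
            train.extend(members)
            cluster_to_split[cid] = "train"
        else:
            val.extend(members)
            cluster_to_split[cid] = "val"
    return DatasetSplit(sorted(train), sorted(val), cluster_to_split, seed)


def deduplicate_test(
    test_seqs: list[str],
    reference_seqs: list[str],
    identity_cutoff: float = 30.0,
    coverage_cutoff: float = 70.0,
    centroid_identity: float = 90.0,
) -> list[int]:
    """Independent-test-set hygiene; returns surviving indices.

    First drop any test sequence with more than ``identity_cutoff`` %
    identity at ≥ ``coverage_cutoff`` % coverage to a training/validation
    sequence, then cluster the survivors at ``centroid_identity`` % and keep
    one centroid per cluster.
    """
    survivors = []
    for i, seq in enumerate(test_seqs):
        leaky = False
        for ref in reference_seqs:
            ident, cov = pairwise_identity(seq, ref)
            if ident > identity_cutoff and cov >= coverage_cutoff:
                leaky = True
                break
        if not leaky:
            survivors.append(i)
    if not survivors:
        return []
    clusters = greedy_cluster([test_seqs[i] for i in survivors], centroid_identity)
    return sorted(survivors[cl[0]] for cl in clusters)


def _window_structure(partner: ProteinStructure, start: int, length: int) -> ProteinStructure:
    return ProteinStructure(
        partner.chain_id, partner.residues[start : start + length], partner.resolution
    )


def scan_fragments(
    receptor: ProteinStructure,
    partner: ProteinStructure,
    min_len: int = 5,
    max_len: int = 25,
) -> list[FragmentRecord]:
    """Score every contiguous partner window of length 5..25 against the
    receptor.

    interface_score = -(number of heavy-atom pairs under 5 Å between window
    and receptor): more negative means a stronger interface, mimicking the
    sign of an interface energy. Use :func:`best_fragments_per_length` for
    the per-length winners.
    """
    if len(receptor) < 50:
        raise ValueError("fragment receptors must have at least 50 residues")
    if len(partner) < min_len:
        raise ValueError("partner shorter than the minimum fragment length")
    rcoords, _, _ = receptor.heavy_atoms()
    tree = cKDTree(rcoords)
    per_res_contacts = np.array(
        [
            sum(len(tree.query_ball_point(atom, FRAGMENT_CONTACT_CUTOFF)) for atom in res.heavy_atoms()[0])
            for res in partner.residues
        ]
    )
    csum = np.concatenate([[0], np.cumsum(per_res_contacts)])
    out = []
    for length in range(min_len, min(max_len, len(partner)) + 1):
        for start in range(len(partner) - length + 1):
            contacts = int(csum[start + length] - csum[start])
            out.append(
                FragmentRecord(
                    receptor=receptor,
                    fragment=_window_structure(partner, start, length),
                    start=start,
                    length=length,
                    interface_score=-float(contacts),
                )
            )
    return out


def best_fragments_per_length(fragments: list[FragmentRecord]) -> dict[int, FragmentRecord]:
    """Lowest (strongest) interface score per window length, ties to the
    earliest window."""
    best: dict[int, FragmentRecord] = {}
    for frag in fragments:
        cur = best.get(frag.length)
        if cur is None or frag.interface_score < cur.interface_score:
            best[frag.length] = frag
    return best


def filter_fragments(
    fragments: list[FragmentRecord],
    peptide_score_mean: float,
    peptide_score_sd: float,
    min_bsa: float = MIN_BSA,
    compute_bsa: bool = False,
) -> list[FragmentRecord]:
    """Keep fragments whose interface score is at most one standard
    deviation above the mean of the real peptide-complex score distribution
    and whose BSA is at least 400 Å²."""
    cutoff = peptide_score_mean + peptide_score_sd
    kept = []
    for frag in fragments:
        if frag.interface_score > cutoff:
            continue
        if frag.bsa is None:
            if not compute_bsa:
                raise ValueError(
                    "fragment has no BSA; pass compute_bsa=True or fill bsa first"
                )
            frag.bsa = buried_surface_area(frag.receptor, frag.fragment)
        if frag.bsa < min_bsa:
            continue
        kept.append(frag)
    return kept
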