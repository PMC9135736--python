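"""Rotation- and translation-invariant residue graph featurization.

Each residue gets a local orthonormal frame built from its backbone, and all
geometric quantities (neighbor directions, inter-frame rotations, side-chain
centroid directions) are expressed in those frames, which makes every feature
exactly invariant under global rigid motions of the structure.

Feature layout (kept stable; serialized sidecars record it):

* node (46-dim): amino-acid one-hot (21) | sin/cos of phi, psi, omega (6) |
  side-chain centroid direction in the local frame (3) | RBF of the
  CA-centroid distance (16)
* edge (88-dim): RBF of the CA-CA distance (16) | unit direction to the
  neighbor CA in the source frame (3) | unit quaternion of the inter-frame
  rotation (4) | one-hot of the sequence offset clipped to [-32, 32] (65)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import AMINO_ACIDS, ProteinStructure, Residue

#: Default RBF grid for CA-CA distances: 16 centers uniform on [0, 20] Å,
#: width equal to the center spacing.
RBF_CENTERS = np.linspace(0.0, 20.0, 16)
RBF_WIDTH = 20.0 / 16.0
#: Side-chain centroids sit within a few Å of the CA, so a tighter grid.
SC_RBF_CENTERS = np.linspace(0.0, 8.0, 16)
SC_RBF_WIDTH = 8.0 / 16.0

RELPOS_CLIP = 32
CHAIN_BREAK_CA_DIST = 4.5

NODE_DIM = 21 + 6 + 3 + 16
EDGE_DIM = 16 + 3 + 4 + 2 * RELPOS_CLIP + 1


@dataclass
class LocalFrame:
    """Per-residue orthonormal right-handed coordinate system at the CA."""

    origin: np.ndarray
    basis: np.ndarray  # rows are the three axis vectors

    def to_local(self, v: np.ndarray) -> np.ndarray:
        """Express a world-space displacement in this frame."""
        return self.basis @ np.asarray(v, dtype=float)


@dataclass
class ResidueGraph:
    """k-nearest-neighbor residue graph with invariant feature tensors.

    ``neighbor_idx[i]`` lists the ``min(k, L-1)`` nearest residues of i by
    CA-CA distance, ascending, ties broken by lower residue position. The
    sequence is kept alongside so models can attach language-model
    embeddings without re-reading the structure.
    """

    node_features: np.ndarray  # (L, NODE_DIM)
    neighbor_idx: np.ndarray  # (L, K) int
    edge_features: np.ndarray  # (L, K, EDGE_DIM)
    k: int
    sequence: str = ""
    lm_embedding: np.ndarray | None = None

    def __len__(self) -> int:
        return self.node_features.shape[0]


def aa_one_hot(aa: str) -> np.ndarray:
    v = np.zeros(21)
    v[AMINO_ACIDS.index(aa) if aa in AMINO_ACIDS else 20] = 1.0
    return v


def local_frame(residue: Residue) -> LocalFrame:
    """Gram-Schmidt frame from the backbone: e1 along C-CA, e2 from N-CA
    orthogonalized against e1, e3 their cross product (right-handed)."""
    try:
        n, ca, c = (residue.backbone[a] for a in ("N", "CA", "C"))
    except KeyError as exc:
        raise ValueError(f"residue {residue.index} missing backbone atom {exc}") from exc
    e1 = c - ca
    e1 = e1 / np.linalg.norm(e1)
    u = n - ca
    e2 = u - np.dot(u, e1) * e1
    nrm = np.linalg.norm(e2)
    if nrm < 1e-8:
        raise ValueError(f"degenerate backbone geometry at residue {residue.index}")
    e2 = e2 / nrm
    e3 = np.cross(e1, e2)
    return LocalFrame(origin=ca.copy(), basis=np.stack([e1, e2, e3]))


def rbf_encode(d: float, centers: np.ndarray = RBF_CENTERS, width: float = RBF_WIDTH) -> np.ndarray:
    """Gaussian radial basis encoding exp(-(d - c)^2 / (2 w^2)) per center."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if width <= 0:
        raise ValueError("width must be positive")
    c = np.asarray(centers, dtype=float)
    return np.exp(-((d - c) ** 2) / (2.0 * width**2))


def rotation_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation matrix, w >= 0.

    Shepperd's method: branch on the largest of trace-based candidates for
    numerical stability near 180-degree rotations.
    """
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def frame_quaternion(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Quaternion of the relative rotation between the two local frames.

    With basis rows holding the axis vectors, R = B_i B_j^T is the rotation
    expressed in local coordinates, so it is unchanged by any global rigid
    motion of the structure. (With axes stored as columns this is the
    familiar B_i^T B_j.)
    """
    return rotation_to_quaternion(frame_i.basis @ frame_j.basis.T)


def _dihedral(p0, p1, p2, p3) -> float | None:
    """Signed dihedral in radians; None when geometry is degenerate."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    if np.linalg.norm(np.cross(b0, b1)) < 1e-8 or np.linalg.norm(np.cross(b1, b2)) < 1e-8:
        return None
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def backbone_dihedrals(structure: ProteinStructure) -> np.ndarray:
    """(L, 6) array of sin/cos pairs for (phi, psi, omega) per residue.

    Undefined angles — chain termini, residues flanking a chain break
    (consecutive CA-CA > 4.5 Å), or degenerate collinear geometry — are
    encoded as (0, 0), keeping the features bounded without a sentinel.
    """
    L = len(structure)
    out = np.zeros((L, 6))
    res = structure.residues
    ca = structure.ca_coords()
    connected = [
        float(np.linalg.norm(ca[i + 1] - ca[i])) <= CHAIN_BREAK_CA_DIST for i in range(L - 1)
    ]

    def enc(col: int, i: int, angle: float | None) -> None:
        if angle is not None:
            out[i, 2 * col] = np.sin(angle)
            out[i, 2 * col + 1] = np.cos(angle)

    for i in range(L):
        bb = res[i].backbone
        if i > 0 and connected[i - 1] and "C" in res[i - 1].backbone and res[i].has_full_backbone:
            enc(0, i, _dihedral(res[i - 1].backbone["C"], bb["N"], bb["CA"], bb["C"]))
        if i < L - 1 and connected[i] and res[i].has_full_backbone and "N" in res[i + 1].backbone:
            enc(1, i, _dihedral(bb["N"], bb["CA"], bb["C"], res[i + 1].backbone["N"]))
        if (
            i < L - 1
            and connected[i]
            and "CA" in bb
            and "C" in bb
            and all(a in res[i + 1].backbone for a in ("N", "CA"))
        ):
            enc(
                2,
                i,
                _dihedral(bb["CA"], bb["C"], res[i + 1].backbone["N"], res[i + 1].backbone["CA"]),
            )
    return out


def sidechain_centroid_features(
    residue: Residue,
    frame: LocalFrame,
    centers: np.ndarray = SC_RBF_CENTERS,
    width: float = SC_RBF_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Direction (in the local frame) and RBF-encoded distance of the
    side-chain heavy-atom centroid from the CA.

    Glycine (no side-chain heavy atoms) gets a zero direction and the
    distance encoded at d = 0.
    """
    if len(residue.sidechain_coords) == 0:
        return np.zeros(3), rbf_encode(0.0, centers, width)
    centroid = residue.sidechain_coords.mean(axis=0)
    v = frame.to_local(centroid - frame.origin)
    d = float(np.linalg.norm(v))
    direction = v / d if d > 1e-8 else np.zeros(3)
    return direction, rbf_encode(d, centers, width)


def _knn(ca: np.ndarray, k: int) -> np.ndarray:
    """Nearest neighbors by CA distance; ties broken by lower index."""
    L = len(ca)
    kk = min(k, L - 1)
    tree = cKDTree(ca)
    dist, idx = tree.query(ca, k=L)
    out = np.empty((L, kk), dtype=int)
    for i in range(L):
        mask = idx[i] != i
        d, j = dist[i][mask], idx[i][mask]
        order = np.lexsort((j, np.round(d, 9)))
        out[i] = j[order][:kk]
    return out


def build_residue_graph(
    structure: ProteinStructure,
    k: int = 30,
    rbf_centers: np.ndarray = RBF_CENTERS,
    rbf_width: float = RBF_WIDTH,
) -> ResidueGraph:
    """Assemble the full invariant graph representation of one chain.

    Residues lacking a complete (N, CA, C) backbone cannot carry a local
    frame and are excluded before the graph is built.
    """
    kept = [r for r in structure.residues if r.has_full_backbone]
    if len(kept) < len(structure.residues):
        structure = ProteinStructure(structure.chain_id, kept, structure.resolution)
    L = len(structure)
    if L < 2:
        raise ValueError("structure too short to build a graph (need >= 2 residues)")

    frames = [local_frame(r) for r in structure.residues]
    dihedrals = backbone_dihedrals(structure)
    ca = structure.ca_coords()
    neighbor_idx = _knn(ca, k)
    kk = neighbor_idx.shape[1]

    nodes = np.zeros((L, NODE_DIM))
    for i, r in enumerate(structure.residues):
        sc_dir, sc_rbf = sidechain_centroid_features(r, frames[i])
        nodes[i] = np.concatenate([aa_one_hot(r.aa), dihedrals[i], sc_dir, sc_rbf])

    edges = np.zeros((L, kk, EDGE_DIM))
    for i in range(L):
        for e, j in enumerate(neighbor_idx[i]):
            delta = ca[j] - ca[i]
            d = float(np.linalg.norm(delta))
            direction = frames[i].to_local(delta / d) if d > 1e-8 else np.zeros(3)
            quat = frame_quaternion(frames[i], frames[j])
            offset = int(np.clip(j - i, -RELPOS_CLIP, RELPOS_CLIP))
            relpos = np.zeros(2 * RELPOS_CLIP + 1)
            relpos[offset + RELPOS_CLIP] = 1.0
            edges[i, e] = np.concatenate(
                [rbf_encode(d, rbf_centers, rbf_width), direction, quat, relpos]
            )

    return ResidueGraph(
        node_features=nodes,
        neighbor_idx=neighbor_idx,
        edge_features=edges,
        k=k,
        sequence=structure.sequence,
    )
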