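"""Protein structure containers and PDB/mmCIF I/O.

The in-memory model is deliberately small: an ordered list of residues, each
carrying its backbone heavy atoms (N, CA, C, O) and any side-chain heavy
atoms. Hydrogens, waters and hetero ligands are never loaded. Reading goes
through gemmi, which handles both PDB and mmCIF; writing emits plain
fixed-column PDB ATOM records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical one-letter codes in the fixed column order used for one-hot
#: encodings throughout the package; index 20 is the UNK class.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNK = "X"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE[UNK] = "UNK"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """A single amino-acid residue with heavy-atom coordinates in Å."""

    index: int
    aa: str
    backbone: dict[str, np.ndarray]
    sidechain_coords: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=float)
    )
    sidechain_elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in AMINO_ACIDS and self.aa != UNK:
            raise ValueError(f"unknown amino acid code {self.aa!r}")
        self.sidechain_coords = np.asarray(self.sidechain_coords, dtype=float).reshape(-1, 3)

    @property
    def has_full_backbone(self) -> bool:
        return all(name in self.backbone for name in ("N", "CA", "C"))

    def heavy_atoms(self) -> tuple[np.ndarray, list[str]]:
        """All heavy-atom coordinates and their element symbols."""
        coords = [self.backbone[n] for n in BACKBONE_ATOMS if n in self.backbone]
        elements = [n[0] for n in BACKBONE_ATOMS if n in self.backbone]
        if len(self.sidechain_coords):
            coords.extend(self.sidechain_coords)
            elements.extend(self.sidechain_elements)
        return np.asarray(coords, dtype=float), elements


@dataclass
class ProteinStructure:
    """An ordered single chain of residues.

    Residue indices are strictly increasing; ``resolution`` is in Å or None
    when the experiment did not report one (e.g. NMR entries).
    """

    chain_id: str
    residues: list[Residue]
    resolution: float | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a structure needs at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.backbone["CA"] for r in self.residues], dtype=float)

    def heavy_atoms(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Flat heavy-atom coordinates, elements, and owning residue position.

        The third array maps each atom back to the 0-based position of its
        residue in ``self.residues`` (not the author-assigned index).
        """
        coords, elements, owner = [], [], []
        for pos, res in enumerate(self.residues):
            c, e = res.heavy_atoms()
            coords.append(c)
            elements.extend(e)
            owner.extend([pos] * len(c))
        return np.concatenate(coords), elements, np.asarray(owner, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy under the rigid motion x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = []
        for r in self.residues:
            residues.append(
                Residue(
                    index=r.index,
                    aa=r.aa,
                    backbone={k: R @ v + t for k, v in r.backbone.items()},
                    sidechain_coords=(r.sidechain_coords @ R.T + t)
                    if len(r.sidechain_coords)
                    else np.zeros((0, 3)),
                    sidechain_elements=list(r.sidechain_elements),
                )
            )
        return ProteinStructure(self.chain_id, residues, self.resolution)


def _pick_altloc(atoms) -> dict:
    """Resolve alternate locations: highest occupancy, ties to altloc 'A'."""
    best: dict = {}
    for atom in atoms:
        key = atom.name
        if key not in best:
            best[key] = atom
            continue
        cur = best[key]
        if atom.occupancy > cur.occupancy or (
            atom.occupancy == cur.occupancy and (atom.altloc or "A") < (cur.altloc or "A")
        ):
            best[key] = atom
    return best


def read_structure(path: str | Path, chain: str | None = None) -> ProteinStructure:
    """Read one protein chain from a PDB or mmCIF file.

    Only the first model is used. Waters and non-polymer hetero groups are
    skipped; non-canonical amino acids are mapped to the UNK class. When
    ``chain`` is None the first chain containing amino acids is taken.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    model = st[0]

    target = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residues = []
        for pos, res in enumerate(ch):
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = (info is not None and info.is_amino_acid()) or res.name in THREE_TO_ONE
            if not is_aa and not any(a.name == "CA" for a in res):
                continue
            atoms = _pick_altloc(a for a in res if a.element.name != "H")
            backbone = {
                name: np.array([atoms[name].pos.x, atoms[name].pos.y, atoms[name].pos.z])
                for name in BACKBONE_ATOMS
                if name in atoms
            }
            sc = [a for n, a in atoms.items() if n not in BACKBONE_ATOMS]
            residues.append(
                Residue(
                    index=pos,
                    aa=THREE_TO_ONE.get(res.name, UNK),
                    backbone=backbone,
                    sidechain_coords=np.array(
                        [[a.pos.x, a.pos.y, a.pos.z] for a in sc]
                    ).reshape(-1, 3),
                    sidechain_elements=[a.element.name for a in sc],
                )
            )
        if residues:
            target = ProteinStructure(ch.name, residues, resolution)
            break
    if target is None:
        raise ValueError(f"no amino-acid chain {chain!r} found in {path}")
    return target


_SC_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CI", "CJ"]


def write_pdb(structures: ProteinStructure | list[ProteinStructure], path: str | Path) -> None:
    """Write one or more chains as fixed-column PDB ATOM records.

    Coordinates are rounded to the format's 3-decimal precision. A REMARK 2
    line records the resolution when present.
    """
    if isinstance(structures, ProteinStructure):
        structures = [structures]
    lines = []
    res0 = structures[0].resolution
    if res0 is not None:
        lines.append(f"REMARK   2 RESOLUTION. {res0:7.2f} ANGSTROMS.")
    serial = 1
    for st in structures:
        for res in st.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            atoms: list[tuple[str, str, np.ndarray]] = [
                (name, name[0], res.backbone[name])
                for name in BACKBONE_ATOMS
                if name in res.backbone
            ]
            for i, (xyz, el) in enumerate(zip(res.sidechain_coords, res.sidechain_elements)):
                name = _SC_NAMES[i] if i < len(_SC_NAMES) else f"X{i}"
                atoms.append((name, el, xyz))
            for name, element, xyz in atoms:
                pad = name.ljust(3) if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d}  {pad:<3s} {resname:<3s} {st.chain_id[:1]}"
                    f"{res.index + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
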