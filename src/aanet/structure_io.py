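"""PDB parsing into residue nodes, ligand atom sets, and conformer series.

Each residue becomes one network node positioned at the geometric center of
its heavy side-chain atoms (backbone N/CA/C/O and terminal OXT excluded,
CB included); glycine, which has no side-chain heavy atom, falls back to its
CA position.  Hydrogens are discarded and the highest-occupancy alternate
location is kept.  Non-water HETATM groups are collected as named ligands
for atom-contact analysis; they never contribute network nodes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import Atom, DisorderedAtom
from Bio.PDB.Residue import Residue

from .potentials import map_residue_code

__all__ = [
    "ResidueNode",
    "ProteinStructure",
    "ConformerSeries",
    "read_structure",
    "read_conformer_series",
    "side_chain_centroid",
    "radius_of_gyration",
]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D"}

#: CA-CA separation beyond which consecutive residues are treated as a chain
#: break (no peptide bond), suppressing the covalent network link.
CHAIN_BREAK_CA_DISTANCE = 4.5


@dataclass(frozen=True)
class ResidueNode:
    """One network node: a residue represented by its side-chain centroid."""

    chain_id: str
    seq_index: int            # 0-based position along the parsed roster
    pdb_resnum: str           # author residue number + insertion code
    res_type: str             # three-letter code as found in the file
    centroid: np.ndarray      # Å
    n_sidechain_atoms: int
    ca: np.ndarray | None = None  # CA position, used for chain-break checks
    resseq: int = 0           # numeric author residue number

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"non-finite centroid for {self}")
        if self.n_sidechain_atoms < 1:
            raise ValueError("node must average at least one atom")


@dataclass
class ProteinStructure:
    """A parsed single-conformer structure: nodes, heavy atoms, ligands."""

    nodes: list[ResidueNode]
    atom_coords: np.ndarray          # (n_atoms, 3), protein heavy atoms
    atom_elements: list[str]
    atom_names: list[str]
    atom_node_index: np.ndarray      # (n_atoms,) index into nodes
    atom_masses: np.ndarray          # (n_atoms,) atomic masses
    ligands: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (k,3)
    ligand_elements: dict[str, list[str]] = field(default_factory=dict)
    model_id: int = 0
    source: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([n.centroid for n in self.nodes])

    def roster(self) -> list[tuple[str, str]]:
        """(chain_id, res_type) sequence used for conformer compatibility."""
        return [(n.chain_id, n.res_type) for n in self.nodes]

    def nodes_table(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "chain": [n.chain_id for n in self.nodes],
                "resnum": [n.pdb_resnum for n in self.nodes],
                "type": [n.res_type for n in self.nodes],
                "x": [n.centroid[0] for n in self.nodes],
                "y": [n.centroid[1] for n in self.nodes],
                "z": [n.centroid[2] for n in self.nodes],
                "n_sidechain_atoms": [n.n_sidechain_atoms for n in self.nodes],
            }
        )


@dataclass
class ConformerSeries:
    """Ordered conformers sharing one residue roster (e.g. MD snapshots)."""

    frames: list[ProteinStructure]
    frame_labels: list[str]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _select_altloc(atom: Atom | DisorderedAtom) -> Atom:
    """Highest-occupancy alternate location; ties resolved toward altloc A."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    return max(
        children,
        key=lambda a: ((a.get_occupancy() or 0.0), a.get_altloc() == "A"),
    )


def _heavy_atoms(residue: Residue) -> list[Atom]:
    out = []
    for atom in residue:
        atom = _select_altloc(atom)
        element = (atom.element or "").strip().upper()
        if element in _HYDROGEN_ELEMENTS:
            continue
        out.append(atom)
    return out


def side_chain_centroid(residue: Residue) -> tuple[np.ndarray, int] | None:
    """Unweighted mean of heavy side-chain atom coordinates.

    Returns ``(centroid, n_atoms_averaged)``; glycine and any residue whose
    side-chain heavy atoms are unresolved fall back to the CA coordinate
    (counted as one atom).  ``None`` when the residue has no usable atom.
    """
    atoms = _heavy_atoms(residue)
    side = [a for a in atoms if a.get_name().strip() not in _BACKBONE_ATOMS]
    if side:
        coords = np.array([a.get_coord() for a in side], dtype=float)
        return coords.mean(axis=0), len(side)
    ca = next((a for a in atoms if a.get_name().strip() == "CA"), None)
    if ca is not None:
        return np.asarray(ca.get_coord(), dtype=float), 1
    if atoms:  # no CA resolved either: fall back to all heavy atoms
        coords = np.array([a.get_coord() for a in atoms], dtype=float)
        return coords.mean(axis=0), len(atoms)
    return None


def _is_water(resname: str) -> bool:
    return resname.strip().upper() in _WATER_NAMES


def _build_structure(model, chain_filter, lenient: bool, source: str) -> ProteinStructure:
    nodes: list[ResidueNode] = []
    coords: list[np.ndarray] = []
    elements: list[str] = []
    names: list[str] = []
    node_index: list[int] = []
    masses: list[float] = []
    ligands: dict[str, np.ndarray] = {}
    ligand_elements: dict[str, list[str]] = {}

    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for residue in chain:
            resname = residue.get_resname().strip().upper()
            hetfield, resseq, icode = residue.id
            if _is_water(resname) or hetfield == "W":
                continue
            mapped = map_residue_code(resname, lenient=True)
            if mapped is None and hetfield == " ":
                # ATOM record with an unknown residue name
                if lenient:
                    warnings.warn(
                        f"skipping unmappable residue {resname} "
                        f"{chain.id}{resseq}{icode.strip()}"
                    )
                    continue
                raise ValueError(
                    f"unmappable residue {resname} {chain.id}{resseq}"
                )
            if mapped is None:
                # HETATM group that is not a (variant) amino acid: a ligand
                key = f"{resname}:{chain.id}:{resseq}"
                latoms = _heavy_atoms(residue)
                if latoms:
                    ligands[key] = np.array(
                        [a.get_coord() for a in latoms], dtype=float
                    )
                    ligand_elements[key] = [
                        (a.element or "?").strip().upper() for a in latoms
                    ]
                continue

            sc = side_chain_centroid(residue)
            if sc is None:
                warnings.warn(
                    f"skipping residue {resname} {chain.id}{resseq}: no usable atoms"
                )
                continue
            centroid, n_side = sc
            atoms = _heavy_atoms(residue)
            ca = next((a for a in atoms if a.get_name().strip() == "CA"), None)
            node = ResidueNode(
                chain_id=chain.id,
                seq_index=len(nodes),
                pdb_resnum=f"{resseq}{icode.strip()}",
                res_type=resname,
                centroid=centroid,
                n_sidechain_atoms=n_side,
                ca=None if ca is None else np.asarray(ca.get_coord(), float),
                resseq=int(resseq),
            )
            idx = len(nodes)
            nodes.append(node)
            for a in atoms:
                coords.append(np.asarray(a.get_coord(), dtype=float))
                elements.append((a.element or "?").strip().upper())
                names.append(a.get_name().strip())
                node_index.append(idx)
                masses.append(float(a.mass) if np.isfinite(a.mass) else 12.0)

    if not nodes:
        raise ValueError(f"no protein residues found in {source!r}")
    return ProteinStructure(
        nodes=nodes,
        atom_coords=np.array(coords, dtype=float).reshape(len(coords), 3),
        atom_elements=elements,
        atom_names=names,
        atom_node_index=np.array(node_index, dtype=int),
        atom_masses=np.array(masses, dtype=float),
        ligands=ligands,
        ligand_elements=ligand_elements,
        model_id=model.serial_num if model.serial_num else model.id + 1,
        source=source,
    )


def _parse_models(path: str | Path):
    path = Path(path)
    parser = PDBParser(QUIET=True)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            structure = parser.get_structure(path.stem, fh)
    else:
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    # order by MODEL record serial number when present
    models.sort(key=lambda m: m.serial_num if m.serial_num else m.id + 1)
    return models


def read_structure(
    path: str | Path,
    model: int | None = None,
    chain_filter: Sequence[str] | None = None,
    *,
    lenient: bool = True,
) -> ProteinStructure:
    """Parse one conformer from a PDB file.

    Parameters
    ----------
    model
        MODEL record serial number to extract; ``None`` takes the first.
    chain_filter
        Restrict to these chain identifiers (default: all protein chains).
    lenient
        Skip unmappable residues with a warning instead of raising.
    """
    models = _parse_models(path)
    if not models:
        raise ValueError(f"no models found in {path!r}")
    if model is None:
        chosen = models[0]
    else:
        by_serial = {
            (m.serial_num if m.serial_num else m.id + 1): m for m in models
        }
        if model not in by_serial:
            raise ValueError(
                f"model {model} not present in {path!r}; "
                f"available: {sorted(by_serial)}"
            )
        chosen = by_serial[model]
    return _build_structure(chosen, chain_filter, lenient, str(path))


def read_conformer_series(
    source: str | Path | Iterable[str | Path],
    stride: int = 1,
    chain_filter: Sequence[str] | None = None,
) -> ConformerSeries:
    """Read an ordered conformer series from a multi-model file or file list.

    All frames must share one residue roster (same chains, residue types and
    counts); a mismatch is a hard error naming the first divergent residue.
    ``stride`` keeps every ``stride``-th frame.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames: list[ProteinStructure] = []
    labels: list[str] = []
    if isinstance(source, (str, Path)):
        for m in _parse_models(source):
            frames.append(_build_structure(m, chain_filter, True, str(source)))
            labels.append(f"model{frames[-1].model_id}")
    else:
        for p in source:
            frames.append(read_structure(p, chain_filter=chain_filter))
            labels.append(Path(p).name)
    if not frames:
        raise ValueError("empty conformer series")

    ref = frames[0].roster()
    for k, frame in enumerate(frames[1:], start=1):
        roster = frame.roster()
        if roster != ref:
            n = min(len(roster), len(ref))
            for i in range(n):
                if roster[i] != ref[i]:
                    raise ValueError(
                        f"conformer roster mismatch at frame {k}, node {i}: "
                        f"{roster[i]} vs {ref[i]}"
                    )
            raise ValueError(
                f"conformer roster length mismatch at frame {k}: "
                f"{len(roster)} vs {len(ref)} residues"
            )
    frames = frames[::stride]
    labels = labels[::stride]
    return ConformerSeries(frames=frames, frame_labels=labels)


def radius_of_gyration(structure: ProteinStructure, mode: str = "atoms") -> float:
    """Radius of gyration in Å.

    ``atoms`` mode: mass-weighted RMS distance of protein heavy atoms from
    their center of mass.  ``centroids`` mode: unweighted RMS distance of the
    node centroids from their mean — cheaper, used for per-frame profiling.
    """
    if mode == "atoms":
        pts = structure.atom_coords
        w = structure.atom_masses
    elif mode == "centroids":
        pts = structure.centroids
        w = np.ones(len(pts))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(pts) == 0:
        raise ValueError("no points for radius of gyration")
    center = np.average(pts, axis=0, weights=w)
    sq = np.sum((pts - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))
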