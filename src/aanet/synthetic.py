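"""Synthetic structure generators: the package's self-contained test bed.

Three generators cover every pipeline stage without any external download:

* :func:`make_compact_chain` — a self-avoiding bead chain (one pseudo-atom
  per residue, consecutive beads at the 3.8 Å virtual-bond length) biased
  toward its running centroid so it packs into a globule whose radius of
  gyration follows the Rg ~ 2.2 n^0.38 scaling of folded proteins.  It
  stands in for sets of real globular structures.
* :func:`make_expansion_series` — uniform coordinate scaling of a base
  structure about its centroid, a minimal surrogate for an unfolding
  pathway: contacts break monotonically as the structure loosens.
* :func:`make_toy_complex` — a two-lobe chain joined by a narrow bridge
  with a multi-atom HETATM ligand docked beside the bridge: the bridge
  residues acquire extreme betweenness, and the ligand placement guarantees
  at least one residue with direct ligand contacts and a high-centrality
  residue whose ligand interaction is mediated by a neighbour (one-hop).

These are geometric fixtures, not physical protein models: there is no
backbone geometry, no secondary structure, and residue types are sampled
independently of position.  All randomness flows through one seeded
generator; a given spec + seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import ConformerSeries, ProteinStructure, ResidueNode

__all__ = [
    "SyntheticSpec",
    "make_compact_chain",
    "make_expansion_series",
    "make_toy_complex",
    "write_pdb",
    "write_series_pdb",
]

BOND_LENGTH = 3.8          # Å, consecutive-bead (virtual CA-CA) separation

#: Largest uniform dilation that keeps consecutive beads within the peptide
#: chain-break threshold (4.5 Å).  Real unfolding never severs the backbone,
#: so the dilation surrogate only models unfolding below this factor.
MAX_INTACT_EXPANSION = 4.5 / BOND_LENGTH

#: Average amino-acid composition of globular proteins (percent).
DEFAULT_COMPOSITION: dict[str, float] = {
    "ALA": 8.25, "ARG": 5.53, "ASN": 4.06, "ASP": 5.45, "CYS": 1.37,
    "GLN": 3.93, "GLU": 6.75, "GLY": 7.07, "HIS": 2.27, "ILE": 5.96,
    "LEU": 9.66, "LYS": 5.84, "MET": 2.42, "PHE": 3.86, "PRO": 4.70,
    "SER": 6.56, "THR": 5.34, "TRP": 1.08, "TYR": 2.92, "VAL": 6.87,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic chain; same spec + seed -> same structure."""

    n_residues: int
    seed: int = 0
    residue_composition: dict[str, float] | None = None  # sampling weights
    sequence: tuple[str, ...] | None = None              # explicit override
    bead_min_separation: float = 4.0                     # Å, non-bonded floor
    bond_length: float = BOND_LENGTH
    target_compactness: float = 1.0   # multiplies the Rg ~ 2.2 n^0.38 target
    #: Dirichlet concentration scaling for chain-level composition drift.
    #: Proteins differ in bulk composition (membrane vs soluble, rich vs poor
    #: in hydrophobics); sampling each chain's composition from a Dirichlet
    #: around the average emulates that heterogeneity.  ``None`` disables it.
    composition_concentration: float | None = 50.0
    #: Hydrophobic-core mixing noise (kcal/mol on the Fauchère–Pliska scale).
    #: Residue types are assigned to beads by burial depth — hydrophobic
    #: inward, polar outward — with this much Gaussian noise on the
    #: hydrophobicity ranking; globular proteins bury their hydrophobics and
    #: the network's attractive core links come from exactly that layering.
    #: ``None`` assigns types independently of position.
    core_mixing: float | None = 0.8


def _sample_sequence(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    if spec.sequence is not None:
        if len(spec.sequence) != spec.n_residues:
            raise ValueError("explicit sequence length != n_residues")
        return list(spec.sequence)
    comp = spec.residue_composition or DEFAULT_COMPOSITION
    codes = sorted(comp)
    p = np.array([comp[c] for c in codes], dtype=float)
    p /= p.sum()
    if spec.composition_concentration is not None:
        p = rng.dirichlet(p * spec.composition_concentration)
    return [codes[i] for i in rng.choice(len(codes), size=spec.n_residues, p=p)]


def _biased_saw(
    n: int,
    centers: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    bond_length: float,
    min_sep: float,
    start: np.ndarray | None = None,
    max_restarts: int = 60,
) -> np.ndarray:
    """Self-avoiding walk pulled toward per-step target centers.

    ``centers`` is an (n, 3) schedule of attraction points; ``radius`` sets
    how hard the pull reacts to excursions.  Placement failure after bounded
    backtracking and restarts raises with advice to loosen compactness.
    """
    for _ in range(max_restarts):
        pos = np.empty((n, 3))
        pos[0] = centers[0] if start is None else start
        i, backtracks = 1, 0
        while 0 < i < n:
            placed = False
            for _attempt in range(80):
                # pull back only when the walker strays outside the target
                # sphere, so the interior stays an unbiased random walk
                v = centers[i] - pos[i - 1]
                dist_out = np.linalg.norm(v)
                excess = max(0.0, dist_out - radius)
                pull = (v / dist_out) * (excess / bond_length) if dist_out > 1e-9 else 0.0
                direction = rng.normal(size=3) + 1.2 * pull
                norm = np.linalg.norm(direction)
                if norm < 1e-12:
                    continue
                cand = pos[i - 1] + bond_length * direction / norm
                if i > 1:
                    d = np.linalg.norm(pos[: i - 1] - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                pos[i] = cand
                placed = True
                break
            if placed:
                i += 1
            else:
                i = max(1, i - 3)   # back out of the dead end
                backtracks += 1
                if backtracks > 25 * n:
                    break
        if i == n:
            return pos
    raise RuntimeError(
        "bead placement failed; loosen target_compactness or min separation"
    )


def _structure_from_beads(
    positions: np.ndarray,
    sequence: list[str],
    chain_id: str = "A",
    source: str = "synthetic",
) -> ProteinStructure:
    nodes = [
        ResidueNode(
            chain_id=chain_id,
            seq_index=i,
            pdb_resnum=str(i + 1),
            res_type=sequence[i],
            centroid=positions[i].copy(),
            n_sidechain_atoms=1,
            ca=positions[i].copy(),
            resseq=i + 1,
        )
        for i in range(len(sequence))
    ]
    n = len(nodes)
    return ProteinStructure(
        nodes=nodes,
        atom_coords=positions.copy(),
        atom_elements=["C"] * n,
        atom_names=["CA"] * n,
        atom_node_index=np.arange(n),
        atom_masses=np.full(n, 12.011),
        ligands={},
        ligand_elements={},
        model_id=1,
        source=source,
    )


def target_radius_of_gyration(n: int) -> float:
    """Empirical folded-protein scaling Rg ~ 2.2 n^0.38 (Å)."""
    return 2.2 * n ** 0.38


def _assign_by_burial(
    sequence: list[str],
    positions: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> list[str]:
    """Reassign sampled residue types along the burial axis.

    Beads are ranked by distance from the globule center; the sampled types
    are ranked by Fauchère–Pliska hydrophobicity perturbed with Gaussian
    noise of scale ``sigma``, and paired rank-to-rank — a noisy hydrophobic
    core, the layering folded globular proteins actually show.
    """
    from .potentials import _FP_HYDROPHOBICITY

    center = positions.mean(axis=0)
    radial = np.linalg.norm(positions - center, axis=1)
    burial_order = np.argsort(radial)                 # innermost first
    scores = np.array([_FP_HYDROPHOBICITY[t] for t in sequence])
    scores = scores + rng.normal(scale=sigma, size=len(sequence))
    hydrophobic_order = np.argsort(-scores)           # most hydrophobic first
    out = list(sequence)
    for bead, res in zip(burial_order, hydrophobic_order):
        out[bead] = sequence[res]
    return out


def make_compact_chain(spec: SyntheticSpec) -> ProteinStructure:
    """Generate one compact self-avoiding chain from a :class:`SyntheticSpec`."""
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(spec.seed)
    sequence = _sample_sequence(spec, rng)
    rg_target = spec.target_compactness * target_radius_of_gyration(spec.n_residues)
    # uniform density in a sphere of radius R has Rg = R * sqrt(3/5)
    sphere_radius = rg_target * np.sqrt(5.0 / 3.0)
    centers = np.zeros((spec.n_residues, 3))
    pos = _biased_saw(
        spec.n_residues,
        centers,
        sphere_radius,
        rng,
        spec.bond_length,
        spec.bead_min_separation,
        start=np.array([rg_target * 0.5, 0.0, 0.0]),
    )
    if spec.core_mixing is not None and spec.sequence is None:
        sequence = _assign_by_burial(sequence, pos, spec.core_mixing, rng)
    return _structure_from_beads(pos, sequence, source=f"synthetic-chain-seed{spec.seed}")


def make_expansion_series(
    base: ProteinStructure, factors: "list[float] | np.ndarray"
) -> ConformerSeries:
    """Uniformly scale ``base`` about its centroid mean, one frame per factor."""
    import warnings

    factors = list(factors)
    if any(f < 1.0 for f in factors):
        raise ValueError("expansion factors must be >= 1")
    if any(b < a for a, b in zip(factors, factors[1:])):
        raise ValueError("expansion factors must be non-decreasing")
    if factors and factors[-1] > MAX_INTACT_EXPANSION:
        warnings.warn(
            f"expansion beyond {MAX_INTACT_EXPANSION:.3f} stretches the "
            "virtual backbone past the chain-break threshold; frames will "
            "contain severed chains"
        )
    center = base.centroids.mean(axis=0)
    frames: list[ProteinStructure] = []
    labels: list[str] = []
    for k, f in enumerate(factors):
        def scale(x: np.ndarray) -> np.ndarray:
            return center + f * (np.asarray(x) - center)

        nodes = [
            ResidueNode(
                chain_id=nd.chain_id,
                seq_index=nd.seq_index,
                pdb_resnum=nd.pdb_resnum,
                res_type=nd.res_type,
                centroid=scale(nd.centroid),
                n_sidechain_atoms=nd.n_sidechain_atoms,
                ca=None if nd.ca is None else scale(nd.ca),
                resseq=nd.resseq,
            )
            for nd in base.nodes
        ]
        frames.append(
            ProteinStructure(
                nodes=nodes,
                atom_coords=scale(base.atom_coords),
                atom_elements=list(base.atom_elements),
                atom_names=list(base.atom_names),
                atom_node_index=base.atom_node_index.copy(),
                atom_masses=base.atom_masses.copy(),
                ligands={k2: scale(v) for k2, v in base.ligands.items()},
                ligand_elements={k2: list(v) for k2, v in base.ligand_elements.items()},
                model_id=k + 1,
                source=f"{base.source}-x{f:g}",
            )
        )
        labels.append(f"x{f:g}")
    return ConformerSeries(frames=frames, frame_labels=labels)


def _dumbbell_chain(
    seed_seq, lobe_size: int, bridge_size: int, lobe_separation: float
) -> ProteinStructure:
    """Two compact lobes joined by a straight narrow bridge of beads."""
    rng = np.random.default_rng(seed_seq)
    n = 2 * lobe_size + bridge_size
    center_a = np.zeros(3)
    center_b = np.array([lobe_separation, 0.0, 0.0])
    rg_lobe = target_radius_of_gyration(lobe_size)

    centers = np.zeros((n, 3))
    centers[:lobe_size] = center_a
    for k in range(bridge_size):
        t = (k + 1) / (bridge_size + 1)
        centers[lobe_size + k] = center_a + t * (center_b - center_a)
    centers[lobe_size + bridge_size:] = center_b

    spec = SyntheticSpec(n_residues=n, seed=0)
    sequence = _sample_sequence(spec, rng)
    pos = _biased_saw(
        n, centers, rg_lobe * np.sqrt(5.0 / 3.0), rng,
        spec.bond_length, spec.bead_min_separation,
        start=np.array([-rg_lobe * 0.4, 0.0, 0.0]),
    )
    return _structure_from_beads(pos, sequence)


def make_toy_complex(
    seed: int = 0,
    lobe_size: int = 55,
    bridge_size: int = 3,
    lobe_separation: float = 34.0,
    ligand_atoms: int = 5,
    contact_cutoff: float = 4.5,
    z_threshold: float = 3.0,
    max_attempts: int = 25,
) -> ProteinStructure:
    """Dumbbell chain with a docked multi-atom HETATM ligand.

    The narrow bridge carries all inter-lobe shortest paths, so bridge-zone
    residues reach extreme betweenness (Z above ``z_threshold``).  The
    construction then verifies itself: it computes the betweenness Z-scores
    of the bare chain, takes the top-Z residue u, and docks the ligand in
    contact range of one of u's network neighbours while keeping every
    ligand atom out of contact range of u.  The result therefore contains,
    by construction, at least one residue with direct ligand contacts and a
    significant-Z residue whose ligand interaction is mediated by a
    neighbour (one-hop).  Geometry attempts that fail the Z gate are
    redrawn deterministically from the seed.
    """
    from .graph_metrics import betweenness, betweenness_zscores
    from .network_build import build_network, distance_matrix
    from .potentials import load_potential_table

    table = load_potential_table()
    for attempt in range(max_attempts):
        ss = np.random.SeedSequence([seed, attempt])
        try:
            structure = _dumbbell_chain(ss, lobe_size, bridge_size, lobe_separation)
        except RuntimeError:
            continue
        structure.source = f"synthetic-complex-seed{seed}"
        net = build_network(structure, table)
        z = betweenness_zscores(betweenness(distance_matrix(net, 1)))
        u = int(np.argmax(z))
        if z[u] < z_threshold:
            continue
        pos = np.array([nd.centroid for nd in net.node_roster])
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt, 7]))
        neighbours = np.where(net.adjacency[u] == 1)[0]
        # try surface-most neighbours first: easier to dock against
        center = pos.mean(axis=0)
        neighbours = neighbours[
            np.argsort(-np.linalg.norm(pos[neighbours] - center, axis=1))
        ]
        placement = None
        for j in neighbours:
            for _ in range(200):
                d = rng.normal(size=3)
                d += 1.2 * (pos[j] - pos[u]) / np.linalg.norm(pos[j] - pos[u])
                d /= np.linalg.norm(d)
                cand = pos[j] + 3.2 * d
                dist_all = np.linalg.norm(pos - cand, axis=1)
                if dist_all[u] <= contact_cutoff + 1.6:
                    continue
                mask = np.ones(len(pos), dtype=bool)
                mask[j] = False
                if dist_all[mask].min() <= 3.2:
                    continue
                placement = (int(j), cand)
                break
            if placement is not None:
                break
        if placement is None:
            continue
        _, lig_center = placement
        offsets = rng.normal(scale=0.45, size=(ligand_atoms, 3))
        offsets[0] = 0.0
        norms = np.linalg.norm(offsets, axis=1)
        too_far = norms > 0.9
        offsets[too_far] *= (0.9 / norms[too_far])[:, None]
        structure.ligands = {"LIG:A:900": lig_center + offsets}
        structure.ligand_elements = {"LIG:A:900": ["C"] * ligand_atoms}
        return structure
    raise RuntimeError(
        "could not realise a toy complex meeting the Z gate; "
        "increase max_attempts or adjust lobe/bridge sizes"
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _atom_record(
    serial: int, name: str, resname: str, chain: str, resseq: int,
    xyz: np.ndarray, element: str, hetatm: bool = False,
) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    name_fmt = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{rec}{serial:5d} {name_fmt}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def _structure_records(structure: ProteinStructure) -> str:
    lines: list[str] = []
    serial = 1
    for i, xyz in enumerate(structure.atom_coords):
        node = structure.nodes[structure.atom_node_index[i]]
        lines.append(
            _atom_record(
                serial, structure.atom_names[i], node.res_type, node.chain_id,
                node.resseq, xyz, structure.atom_elements[i],
            )
        )
        serial += 1
    if structure.nodes:
        lines.append("TER\n")
    for key, xyz_arr in structure.ligands.items():
        resname, chain, resseq = key.split(":")
        for a, xyz in enumerate(xyz_arr):
            elem = structure.ligand_elements[key][a]
            lines.append(
                _atom_record(
                    serial, f"{elem}{a + 1}", resname, chain, int(resseq),
                    xyz, elem, hetatm=True,
                )
            )
            serial += 1
    return "".join(lines)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a single-model PDB file re-readable by ``read_structure``."""
    Path(path).write_text(_structure_records(structure) + "END\n")


def write_series_pdb(series: ConformerSeries, path: str | Path) -> None:
    """Write a multi-model PDB file, one MODEL per frame in order."""
    out = []
    for k, frame in enumerate(series.frames, start=1):
        out.append(f"MODEL     {k:4d}\n")
        out.append(_structure_records(frame))
        out.append("ENDMDL\n")
    out.append("END\n")
    Path(path).write_text("".join(out))
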