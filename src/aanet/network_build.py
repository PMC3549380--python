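"""Build weighted amino-acid networks and their inter-node distance matrices.

Two residues are linked when their side-chain centroids lie within a cutoff
r_c (default 6.5 Å, the radius used in deriving the contact potential), and
the link carries the contact energy w_ij of the two residue types.  Sequence
neighbours (i, i±1 within an unbroken chain) are covalently bonded: their
link always exists and carries weight 0.

Three ways of turning a weight into a graph distance are provided:

* definition 1 — attractive links (w < 0) use the reciprocal form
  1/(1 - w) ("similar" weight: stronger attraction, shorter distance);
  repulsive links (w > 0) use the linear form 1 + w ("dissimilar" weight);
  covalent links (w = 0) have distance 1.
* definition 2 — every link is treated as dissimilar: (1 + w) / 2.19.
* definition 3 — every link is treated as similar: 1/(1 - w).

Definition 1 mixes both conventions and is the model's default; the other
two exist for comparison.  Unlinked pairs carry an infinite sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .potentials import ContactPotentialTable, lookup_weight
from .structure_io import CHAIN_BREAK_CA_DISTANCE, ProteinStructure, ResidueNode

__all__ = [
    "AminoAcidNetwork",
    "DistanceMatrix",
    "build_network",
    "distance_matrix",
    "distance_def1",
    "distance_def2",
    "distance_def3",
]

DEFAULT_CUTOFF = 6.5        # Å, side-chain centroid contact cutoff
DEFAULT_NORM_CONSTANT = 2.19  # definition-2 divisor, 1 + |min w|
DEFAULT_CLAMP_EPS = 1e-6


@dataclass
class AminoAcidNetwork:
    """Unweighted and weighted adjacency of one conformer."""

    cutoff: float
    centroid_dist: np.ndarray       # (N, N) r_ij in Å
    adjacency: np.ndarray           # (N, N) 0/1
    weighted_adjacency: np.ndarray  # (N, N) a_ij * w_ij, covalent links 0
    weights: np.ndarray             # (N, N) w_ij on links (0 off-link)
    covalent: np.ndarray            # (N, N) bool, covalent backbone links
    node_roster: list[ResidueNode]

    @property
    def n_nodes(self) -> int:
        return len(self.node_roster)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class DistanceMatrix:
    """Pairwise link distances d_ij under one weight->distance definition."""

    definition_id: int
    d: np.ndarray                   # (N, N); np.inf marks "no direct link"
    norm_constant: float = DEFAULT_NORM_CONSTANT
    clamp_eps: float = DEFAULT_CLAMP_EPS
    clamp_count: int = 0            # unordered pairs clamped to clamp_eps

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]


def _covalent_pairs(nodes: list[ResidueNode]) -> list[tuple[int, int]]:
    """Sequence-neighbour pairs forming peptide bonds.

    Consecutive roster entries in the same chain with consecutive author
    numbering; a numbering gap or a CA-CA separation above 4.5 Å marks a
    chain break and suppresses the bond.
    """
    pairs = []
    for i in range(len(nodes) - 1):
        a, b = nodes[i], nodes[i + 1]
        if a.chain_id != b.chain_id:
            continue
        if b.resseq - a.resseq not in (0, 1):
            continue
        if a.ca is not None and b.ca is not None:
            if np.linalg.norm(a.ca - b.ca) > CHAIN_BREAK_CA_DISTANCE:
                continue
        pairs.append((i, i + 1))
    return pairs


def build_network(
    nodes: list[ResidueNode] | ProteinStructure,
    table: ContactPotentialTable,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    lenient: bool = True,
) -> AminoAcidNetwork:
    """Construct the network from residue nodes and the potential table.

    A link exists for centroid separations strictly below ``cutoff`` and for
    covalent sequence neighbours (always, with weight 0).  Nodes whose
    residue type cannot be mapped to a standard one are dropped in lenient
    mode (with a warning at parse time) and raise otherwise.
    """
    if isinstance(nodes, ProteinStructure):
        nodes = nodes.nodes
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to build a network")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    kept: list[ResidueNode] = []
    for n in nodes:
        if lookup_weight(table, n.res_type, n.res_type, lenient=lenient) is None:
            continue  # unmappable residue skipped (lenient mode)
        kept.append(n)
    nodes = kept
    n = len(nodes)
    centroids = np.array([nd.centroid for nd in nodes])
    r = squareform(pdist(centroids))

    adjacency = ((r < cutoff).astype(np.int8))
    np.fill_diagonal(adjacency, 0)

    # per-pair contact energies (type-dependent only)
    w = np.zeros((n, n))
    type_codes = [nd.res_type for nd in nodes]
    unique = sorted(set(type_codes))
    energy = {
        (a, b): lookup_weight(table, a, b, lenient=False)
        for a in unique
        for b in unique
    }
    idx = np.array([unique.index(t) for t in type_codes])
    lut = np.zeros((len(unique), len(unique)))
    for i, a in enumerate(unique):
        for j, b in enumerate(unique):
            lut[i, j] = energy[(a, b)]
    w = lut[np.ix_(idx, idx)]

    covalent = np.zeros((n, n), dtype=bool)
    for i, j in _covalent_pairs(nodes):
        covalent[i, j] = covalent[j, i] = True
        adjacency[i, j] = adjacency[j, i] = 1  # bond exists even past cutoff

    weights = adjacency * w          # raw type energies on every link
    weighted = weights.copy()
    weighted[covalent] = 0.0         # covalent bonds carry zero weight

    return AminoAcidNetwork(
        cutoff=float(cutoff),
        centroid_dist=r,
        adjacency=adjacency,
        weighted_adjacency=weighted,
        weights=weights,
        covalent=covalent,
        node_roster=nodes,
    )


def distance_matrix(
    network: AminoAcidNetwork,
    definition: int = 1,
    norm_constant: float = DEFAULT_NORM_CONSTANT,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> DistanceMatrix:
    """Distance matrix under definition 1, 2 or 3 (see module docstring)."""
    if definition not in (1, 2, 3):
        raise ValueError(f"unknown distance definition {definition}")
    a = network.adjacency
    w = network.weighted_adjacency
    linked = a == 1
    d = np.full(a.shape, np.inf)
    np.fill_diagonal(d, 0.0)
    clamp_count = 0

    if definition == 1:
        neg, zero, pos = (linked & (w < 0), linked & (w == 0), linked & (w > 0))
        d[neg] = 1.0 / (1.0 - w[neg])
        d[zero] = 1.0
        d[pos] = 1.0 + w[pos]
    elif definition == 2:
        vals = (1.0 + w[linked]) / norm_constant
        n_clamped = int(np.count_nonzero(vals <= 0))
        vals = np.where(vals <= 0, clamp_eps, vals)
        d[linked] = vals
        clamp_count = n_clamped // 2
    else:
        if np.any(w[linked] >= 1.0):
            raise AssertionError("definition 3 is singular for w >= 1")
        d[linked] = 1.0 / (1.0 - w[linked])

    return DistanceMatrix(
        definition_id=definition,
        d=d,
        norm_constant=norm_constant,
        clamp_eps=clamp_eps,
        clamp_count=clamp_count,
    )


def distance_def1(network: AminoAcidNetwork) -> DistanceMatrix:
    return distance_matrix(network, 1)


def distance_def2(
    network: AminoAcidNetwork,
    norm_constant: float = DEFAULT_NORM_CONSTANT,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> DistanceMatrix:
    return distance_matrix(network, 2, norm_constant, clamp_eps)


def distance_def3(network: AminoAcidNetwork) -> DistanceMatrix:
    return distance_matrix(network, 3)


def export_edge_list(
    network: AminoAcidNetwork, dm: DistanceMatrix | None = None
) -> "pd.DataFrame":
    """Edge table: one row per unordered linked pair."""
    import pandas as pd

    rows = []
    nodes = network.node_roster
    ii, jj = np.where(np.triu(network.adjacency, k=1))
    for i, j in zip(ii, jj):
        row = {
            "chain_i": nodes[i].chain_id,
            "resnum_i": nodes[i].pdb_resnum,
            "chain_j": nodes[j].chain_id,
            "resnum_j": nodes[j].pdb_resnum,
            "r_ij": network.centroid_dist[i, j],
            "w_ij": network.weighted_adjacency[i, j],
            "covalent": bool(network.covalent[i, j]),
        }
        if dm is not None:
            row[f"d_def{dm.definition_id}"] = dm.d[i, j]
        rows.append(row)
    return pd.DataFrame(rows)


def export_adjacency_mtx(network: AminoAcidNetwork, path: str | Path) -> None:
    """Write the 0/1 adjacency as a Matrix Market sparse file."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(str(path), sparse.csr_matrix(network.adjacency))
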