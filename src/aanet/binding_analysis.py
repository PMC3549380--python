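"""Hot-spot identification in protein–ligand complexes.

Residues whose betweenness Z-score reaches a significance threshold
(default 3.0) are candidate hot spots.  Each candidate is classified by its
atom-contact topology relative to the bound ligand:

* ``direct``      — the residue itself has heavy-atom contacts with the
                    ligand within the contact cutoff;
* ``one-hop``     — no direct contact, but a network neighbour of the
                    residue does (the neighbour "mediates" the interaction);
* ``unconnected`` — neither.

Contacts are counts of heavy-atom pairs (any element except hydrogen;
backbone atoms included on the residue side) within the cutoff, default
4.5 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .graph_metrics import NodeMetrics
from .network_build import AminoAcidNetwork
from .structure_io import ProteinStructure

__all__ = ["AtomContactMap", "Hotspot", "HotspotReport", "atom_contacts", "hotspot_report"]

DEFAULT_CONTACT_CUTOFF = 4.5   # Å, heavy-atom contact criterion
DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class AtomContactMap:
    """Heavy-atom contact counts: residue–ligand and residue–residue."""

    contact_cutoff: float
    residue_ligand_counts: np.ndarray      # (N,) summed over all ligands
    per_ligand_counts: dict[str, np.ndarray]
    residue_residue_counts: np.ndarray     # (N, N) symmetric


@dataclass
class Hotspot:
    node_index: int
    chain_id: str
    pdb_resnum: str
    res_type: str
    zscore: float
    classification: str                    # direct | one-hop | unconnected
    ligand_contacts: int
    mediators: list[tuple[str, int, int]] = field(default_factory=list)
    # (mediator residue label, residue-residue contacts, mediator-ligand contacts)


@dataclass
class HotspotReport:
    z_threshold: float
    contact_cutoff: float
    hotspots: list[Hotspot]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "chain": h.chain_id,
                    "resnum": h.pdb_resnum,
                    "type": h.res_type,
                    "Z": h.zscore,
                    "class": h.classification,
                    "ligand_contacts": h.ligand_contacts,
                    "mediators": ";".join(
                        f"{m[0]}(rr={m[1]},lig={m[2]})" for m in h.mediators
                    ),
                }
                for h in self.hotspots
            ]
        )


def atom_contacts(
    structure: ProteinStructure,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> AtomContactMap:
    """Count heavy-atom pairs within ``contact_cutoff``.

    Residue–ligand counts use every protein heavy atom (backbone included)
    against every ligand heavy atom.  Residue–residue counts are raw pair
    counts between distinct residues, sequence neighbours included.
    """
    n = structure.n_nodes
    coords = structure.atom_coords
    node_idx = structure.atom_node_index

    per_ligand: dict[str, np.ndarray] = {}
    lig_counts = np.zeros(n, dtype=int)
    if not structure.ligands:
        warnings.warn("structure has no ligand; residue-ligand counts are all zero")
    else:
        tree = cKDTree(coords)
        for name, lig_xyz in structure.ligands.items():
            counts = np.zeros(n, dtype=int)
            for hits in cKDTree(lig_xyz).query_ball_tree(tree, contact_cutoff):
                for a in hits:
                    counts[node_idx[a]] += 1
            per_ligand[name] = counts
            lig_counts += counts

    rr = np.zeros((n, n), dtype=int)
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(contact_cutoff):
        i, j = node_idx[a], node_idx[b]
        if i != j:
            rr[i, j] += 1
            rr[j, i] += 1

    return AtomContactMap(
        contact_cutoff=float(contact_cutoff),
        residue_ligand_counts=lig_counts,
        per_ligand_counts=per_ligand,
        residue_residue_counts=rr,
    )


def hotspot_report(
    metrics: NodeMetrics,
    contacts: AtomContactMap,
    network: AminoAcidNetwork,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> HotspotReport:
    """Classify every residue with Z >= ``z_threshold``.

    A candidate with ligand contacts is ``direct``; otherwise, if any of its
    network neighbours touches the ligand, it is ``one-hop`` and the
    mediating residues are listed with their supporting contact counts;
    otherwise ``unconnected``.
    """
    nodes = network.node_roster
    if len(metrics.zscore) != len(nodes):
        raise ValueError("metrics and network node counts differ")
    hotspots: list[Hotspot] = []
    for i, z in enumerate(metrics.zscore):
        if z < z_threshold:
            continue
        lig = int(contacts.residue_ligand_counts[i])
        mediators: list[tuple[str, int, int]] = []
        if lig > 0:
            cls = "direct"
        else:
            for j in np.where(network.adjacency[i] == 1)[0]:
                jl = int(contacts.residue_ligand_counts[j])
                if jl > 0:
                    label = f"{nodes[j].res_type}{nodes[j].chain_id}{nodes[j].pdb_resnum}"
                    rr = int(contacts.residue_residue_counts[i, j])
                    mediators.append((label, rr, jl))
            mediators.sort(key=lambda m: (-m[1], -m[2]))
            cls = "one-hop" if mediators else "unconnected"
        hotspots.append(
            Hotspot(
                node_index=i,
                chain_id=nodes[i].chain_id,
                pdb_resnum=nodes[i].pdb_resnum,
                res_type=nodes[i].res_type,
                zscore=float(z),
                classification=cls,
                ligand_contacts=lig,
                mediators=mediators,
            )
        )
    return HotspotReport(
        z_threshold=float(z_threshold),
        contact_cutoff=contacts.contact_cutoff,
        hotspots=hotspots,
    )
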