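from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from aanet.network_build import AminoAcidNetwork, DistanceMatrix
from aanet.potentials import load_potential_table
from aanet.structure_io import ResidueNode
from aanet.synthetic import SyntheticSpec, make_compact_chain, make_toy_complex


@pytest.fixture(scope="session")
def table():
    return load_potential_table()


@pytest.fixture(scope="session")
def small_chain():
    return make_compact_chain(SyntheticSpec(n_residues=60, seed=7))


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=1)


def make_fake_nodes(n: int) -> list[ResidueNode]:
    """Placeholder roster for networks assembled directly from matrices."""
    return [
        ResidueNode(
            chain_id="A",
            seq_index=i,
            pdb_resnum=str(i + 1),
            res_type="ALA",
            centroid=np.array([float(i), 0.0, 0.0]),
            n_sidechain_atoms=1,
            resseq=i + 1,
        )
        for i in range(n)
    ]


def network_from_matrices(adjacency, weights, covalent=None) -> AminoAcidNetwork:
    """Assemble an AminoAcidNetwork directly from adjacency/weight matrices."""
    n = adjacency.shape[0]
    adjacency = np.asarray(adjacency, dtype=np.int8)
    weights = np.asarray(weights, dtype=float)
    if covalent is None:
        covalent = np.zeros((n, n), dtype=bool)
    weighted = weights * adjacency
    weighted[covalent] = 0.0
    return AminoAcidNetwork(
        cutoff=6.5,
        centroid_dist=np.zeros((n, n)),
        adjacency=adjacency,
        weighted_adjacency=weighted,
        weights=weights * adjacency,
        covalent=covalent,
        node_roster=make_fake_nodes(n),
    )


def distance_from_matrix(d: np.ndarray, definition_id: int = 1) -> DistanceMatrix:
    """Wrap an explicit distance matrix (np.inf marks absent links)."""
    return DistanceMatrix(definition_id=definition_id, d=np.asarray(d, dtype=float))
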