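"""Adjacency spectra and graph energy.

The graph energy E_pi(G) is the sum of the absolute eigenvalues of the 0/1
adjacency matrix — classically, total pi-electron energy in Hückel theory.
The adjacency matrix of an undirected simple graph is real symmetric, so
the spectrum is computed with a symmetric eigensolver and is exactly real;
it satisfies sum(lambda) = 0 and sum(lambda^2) = 2|E|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import networkx as nx
import numpy as np

__all__ = ["SpectralResult", "adjacency_matrix", "spectrum", "graph_energy"]


@dataclass(frozen=True)
class SpectralResult:
    eigenvalues: np.ndarray  # ascending
    energy: float

    @property
    def n(self) -> int:
        return self.eigenvalues.size


def adjacency_matrix(graph: nx.Graph) -> np.ndarray:
    """Symmetric 0/1 adjacency matrix, nodes in sorted order."""
    return nx.to_numpy_array(graph, nodelist=sorted(graph.nodes()), dtype=float)


def spectrum(graph: nx.Graph) -> SpectralResult:
    """Eigenvalues of the adjacency matrix and the graph energy."""
    if graph.number_of_nodes() == 0:
        return SpectralResult(np.empty(0), 0.0)
    eig = np.linalg.eigvalsh(adjacency_matrix(graph))
    return SpectralResult(eig, float(np.abs(eig).sum()))


def graph_energy(graph: nx.Graph) -> float:
    """E_pi(G) = sum_i |lambda_i| of the adjacency spectrum."""
    return spectrum(graph).energy
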