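"""Independent brute-force oracles for the topological descriptors.

Deliberately naive implementations (exhaustive enumeration over a
networkx graph) kept separate from the package so descriptor tests
compare two unrelated code paths.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
from rdkit import Chem


def heavy_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    return g


def eccen_oracle(mol: Chem.Mol) -> int:
    g = heavy_graph(mol)
    if g.number_of_nodes() < 2:
        return 0
    total = 0
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        total += max(lengths.values()) * g.degree(node)
    return total


def chi_path_oracle(mol: Chem.Mol, order: int) -> float:
    """Sum over simple paths with `order` edges of 1/sqrt(prod degrees)."""
    g = heavy_graph(mol)
    deg = dict(g.degree())
    seen = set()
    total = 0.0

    def extend(path: list[int]) -> None:
        nonlocal total
        if len(path) == order + 1:
            key = tuple(path) if path[0] < path[-1] else tuple(reversed(path))
            if key not in seen:
                seen.add(key)
                prod = 1.0
                for n in path:
                    prod *= deg[n]
                total += 1.0 / math.sqrt(prod)
            return
        for nb in g.neighbors(path[-1]):
            if nb not in path:
                extend(path + [nb])

    if order == 0:
        return sum(1.0 / math.sqrt(d) for d in deg.values() if d > 0)
    for start in g.nodes:
        extend([start])
    return total


def chi_path_cluster_oracle(mol: Chem.Mol, order: int) -> float:
    """Exhaustive edge-subset enumeration + path-cluster classification."""
    g = heavy_graph(mol)
    deg = dict(g.degree())
    edges = list(g.edges)
    total = 0.0
    for combo in itertools.combinations(edges, order):
        sub = nx.Graph(combo)
        if not nx.is_connected(sub):
            continue
        sdeg = [d for _, d in sub.degree()]
        if max(sdeg) < 3:
            continue
        # pure star: center adjacent to every edge, all others leaves
        if max(sdeg) == order and sorted(sdeg)[:-1] == [1] * (len(sdeg) - 1):
            continue
        prod = 1.0
        for n in sub.nodes:
            prod *= deg[n]
        total += 1.0 / math.sqrt(prod)
    return total


def mden13_oracle(mol: Chem.Mol) -> float:
    g = heavy_graph(mol)
    primary = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 7 and a.GetDegree() == 1]
    tertiary = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 7 and a.GetDegree() == 3]
    pairs = [(i, j) for i in primary for j in tertiary]
    if not pairs:
        return 0.0
    n = len(pairs)
    prod = 1.0
    for i, j in pairs:
        prod *= nx.shortest_path_length(g, i, j)
    g_mean = prod ** (1.0 / (2 * n))
    return n / g_mean**2
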