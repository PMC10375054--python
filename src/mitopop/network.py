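"""Haplotype networks: minimum spanning network and median-joining.

The minimum spanning network (MSN) is the union of all minimum spanning
trees of the complete Hamming-distance graph over haplotypes: an edge of
weight w is included iff its endpoints lie in different components of the
subgraph of strictly lighter edges (with an optional tolerance epsilon, in
mutational steps, that relaxes "strictly lighter" to "lighter by more than
epsilon").

Median joining iteratively augments the haplotype set with quasi-median
(Steiner-like) vectors of triples that are close in the current MSN, which
shortens the network by routing connections through inferred unsampled
intermediates, then prunes median vectors that no longer reduce the total
network length.  Only variable columns enter the computation (invariant
columns carry no information) and all sites are weighted equally.
Haplotypes with ambiguous bases at variable sites remain nodes but are
excluded from median generation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst

from .alignment import MISSING, encode_sequence
from .errors import ConfigurationError, InputError
from .haplotypes import HaplotypeTable

__all__ = ["HaploNetwork", "minimum_spanning_network", "median_joining"]

_MAX_MEDIANS = 5000


@dataclass
class HaploNetwork:
    """Nodes (observed haplotypes and inferred median vectors) plus weighted edges.

    Edge weights are mutational steps (Hamming distance over sites where both
    endpoint sequences are unambiguous).  The graph is connected and contains
    every observed haplotype; median vectors carry frequency 0.
    """

    graph: nx.Graph
    populations: tuple[str, ...] = ()

    @property
    def n_medians(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["is_median"])

    def total_length(self) -> float:
        """Total weight of a minimum spanning tree over all network nodes."""
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return float(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    def nodes_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.graph.nodes(data=True):
            row = {
                "name": name,
                "frequency": d["frequency"],
                "is_median": d["is_median"],
            }
            for pop, c in zip(self.populations, d.get("pop_counts", ())):
                row[pop] = c
            rows.append(row)
        return pd.DataFrame(rows).set_index("name")

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "steps": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "steps"])

    def write_tsv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.nodes_frame().to_csv(nodes_path, sep="\t")
        self.edges_frame().to_csv(edges_path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d.pop("pop_counts", None)
            d.pop("codes", None)
        nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _as_named_sequences(haplotypes):
    """Normalise input to (names, sequences, frequencies, pop_counts, populations)."""
    if isinstance(haplotypes, HaplotypeTable):
        return (
            list(haplotypes.names),
            list(haplotypes.sequences),
            [int(t) for t in haplotypes.totals()],
            [tuple(int(c) for c in row) for row in haplotypes.counts],
            tuple(haplotypes.populations),
        )
    names, seqs = [], []
    for name, seq in haplotypes:
        names.append(str(name))
        seqs.append(str(seq).upper())
    if not names:
        raise InputError("no haplotypes given")
    if len(set(names)) != len(names):
        raise InputError("haplotype names must be unique")
    return names, seqs, [1] * len(names), [()] * len(names), ()


def _variable_columns(codes: np.ndarray) -> np.ndarray:
    cols = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        vals = set(col[col != MISSING].tolist())
        if len(vals) >= 2:
            cols.append(j)
    return np.asarray(cols, dtype=int)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    both = (a != MISSING) & (b != MISSING)
    return int(np.sum((a != b) & both))


def _distance_matrix(code_rows: list[np.ndarray]) -> np.ndarray:
    n = len(code_rows)
    d = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(code_rows[i], code_rows[j])
    return d


def _mst_length(d: np.ndarray) -> float:
    if d.shape[0] <= 1:
        return 0.0
    return float(_csgraph_mst(d + 1.0 - np.eye(d.shape[0])).sum()) - (d.shape[0] - 1)
    # +1 offset keeps zero-weight edges visible to the sparse MST routine


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.p[self.find(a)] = self.find(b)


def _msn_edges(d: np.ndarray, epsilon: float = 0.0) -> list[tuple[int, int, float]]:
    """Edges of the (epsilon-relaxed) union of all minimum spanning trees."""
    n = d.shape[0]
    edges = sorted(
        ((d[i, j], i, j) for i in range(n - 1) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    uf = _UnionFind(n)
    kept: list[tuple[int, int, float]] = []
    ptr = 0
    for w in sorted({e[0] for e in edges}):
        # union everything strictly lighter than w - epsilon
        while ptr < len(edges) and edges[ptr][0] < w - epsilon:
            uf.union(edges[ptr][1], edges[ptr][2])
            ptr += 1
        for wt, i, j in edges:
            if wt == w and uf.find(i) != uf.find(j):
                kept.append((i, j, w))
    return kept


def _build_network(
    names, full_seqs, freqs, pop_counts, populations, code_rows, epsilon
) -> HaploNetwork:
    d = _distance_matrix(code_rows)
    g = nx.Graph()
    for i, name in enumerate(names):
        g.add_node(
            name,
            sequence=full_seqs[i],
            frequency=freqs[i],
            pop_counts=tuple(pop_counts[i]),
            is_median=bool(name.startswith("mv") and freqs[i] == 0),
        )
    for i, j, w in _msn_edges(d, epsilon):
        g.add_edge(names[i], names[j], weight=float(w))
    return HaploNetwork(graph=g, populations=tuple(populations))


def minimum_spanning_network(haplotypes, epsilon: float = 0.0) -> HaploNetwork:
    """Union of all minimum spanning trees over the haplotype Hamming graph.

    ``haplotypes`` may be a :class:`~mitopop.haplotypes.HaplotypeTable` or an
    iterable of (name, sequence) pairs.
    """
    names, seqs, freqs, pop_counts, populations = _as_named_sequences(haplotypes)
    code_rows = [encode_sequence(s) for s in seqs]
    return _build_network(names, seqs, freqs, pop_counts, populations, code_rows, epsilon)


def _quasi_medians(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> list[tuple]:
    """Quasi-median vectors of a triple: per site the majority value, or all
    three values where the triple is fully discordant (capped expansion)."""
    options: list[tuple[int, ...]] = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            options.append((int(x),))
        elif y == z:
            options.append((int(y),))
        else:
            options.append((int(x), int(y), int(z)))
    n_combo = 1
    for o in options:
        n_combo *= len(o)
        if n_combo > 27:
            return []
    return [tuple(v) for v in itertools.product(*options)]


def median_joining(
    haplotypes, epsilon: float = 0.0, max_rounds: int = 50
) -> HaploNetwork:
    """Median-joining network over observed haplotypes.

    Builds the epsilon-relaxed MSN, adds quasi-median vectors of triples
    that share at least two MSN links, iterates to a fixed point, then
    removes median vectors whose deletion leaves the total network length
    unchanged.  Deterministic given input order (candidate medians are added
    in lexicographic order, pruning scans names lexicographically).
    """
    if epsilon < 0:
        raise ConfigurationError("epsilon must be >= 0")
    names, seqs, freqs, pop_counts, populations = _as_named_sequences(haplotypes)
    all_codes = np.vstack([encode_sequence(s) for s in seqs])
    var_cols = _variable_columns(all_codes)
    backbone = encode_sequence(seqs[0])

    if len(names) == 1 or len(var_cols) == 0:
        code_rows = [all_codes[i] for i in range(len(names))]
        return _build_network(
            names, seqs, freqs, pop_counts, populations, code_rows, epsilon
        )

    obs_var = [tuple(int(v) for v in all_codes[i, var_cols]) for i in range(len(names))]
    usable = [i for i, row in enumerate(obs_var) if MISSING not in row]
    if len(usable) < len(names):
        warnings.warn(
            "haplotypes with ambiguous bases at variable sites are excluded "
            "from median computation"
        )

    node_vecs: dict[str, tuple[int, ...]] = dict(zip(names, obs_var))
    median_vecs: dict[str, tuple[int, ...]] = {}
    known = set(obs_var)
    mv_serial = 0

    def vec_dist(u: tuple, v: tuple) -> int:
        return sum(
            1 for x, y in zip(u, v) if x != y and x != MISSING and y != MISSING
        )

    for _ in range(max_rounds):
        current = list(node_vecs.items()) + list(median_vecs.items())
        labels = [nm for nm, _ in current]
        vecs = [v for _, v in current]
        d = np.zeros((len(vecs), len(vecs)))
        for i in range(len(vecs) - 1):
            for j in range(i + 1, len(vecs)):
                d[i, j] = d[j, i] = vec_dist(vecs[i], vecs[j])
        adj: dict[int, set[int]] = {i: set() for i in range(len(vecs))}
        for i, j, _w in _msn_edges(d, epsilon):
            adj[i].add(j)
            adj[j].add(i)
        # triples with at least two of the three links present
        median_ok = {
            i
            for i, nm in enumerate(labels)
            if nm in median_vecs or MISSING not in vecs[i]
        }
        new_medians: set[tuple[int, ...]] = set()
        for i, j, k in itertools.combinations(sorted(median_ok), 3):
            links = (j in adj[i]) + (k in adj[i]) + (k in adj[j])
            if links < 2:
                continue
            for med in _quasi_medians(
                np.asarray(vecs[i]), np.asarray(vecs[j]), np.asarray(vecs[k])
            ):
                if med not in known:
                    new_medians.add(med)
        if not new_medians:
            break
        for med in sorted(new_medians):
            mv_serial += 1
            median_vecs[f"mv{mv_serial}"] = med
            known.add(med)
            if len(median_vecs) > _MAX_MEDIANS:
                warnings.warn("median-vector limit reached; stopping augmentation")
                new_medians = set()
                break
        if not new_medians:
            break
    else:
        warnings.warn("median joining did not converge within max_rounds")

    # prune median vectors that do not shorten the network
    def length_of(med_names: list[str]) -> float:
        vecs = list(node_vecs.values()) + [median_vecs[m] for m in med_names]
        d = np.zeros((len(vecs), len(vecs)))
        for i in range(len(vecs) - 1):
            for j in range(i + 1, len(vecs)):
                d[i, j] = d[j, i] = vec_dist(vecs[i], vecs[j])
        return _mst_length(d)

    retained = sorted(median_vecs)
    changed = True
    while changed:
        changed = False
        base_len = length_of(retained)
        for m in list(retained):
            trial = [x for x in retained if x != m]
            if length_of(trial) <= base_len:
                retained = trial
                changed = True
                break

    # assemble final network over observed + retained medians
    final_names = list(names)
    final_seqs = list(seqs)
    final_freqs = list(freqs)
    final_pc = list(pop_counts)
    code_rows = [all_codes[i] for i in range(len(names))]
    n_pops = len(populations)
    for m in retained:
        vec = median_vecs[m]
        full = backbone.copy()
        full[var_cols] = vec
        final_names.append(m)
        final_seqs.append("".join("ACGTN"[v] for v in full))
        final_freqs.append(0)
        final_pc.append(tuple([0] * n_pops))
        code_rows.append(full)
    return _build_network(
        final_names, final_seqs, final_freqs, final_pc, populations, code_rows, epsilon
    )
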