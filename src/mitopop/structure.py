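"""Population structure: pairwise distances, AMOVA, pairwise Phi_ST, NJ trees.

The two-level analysis of molecular variance (AMOVA) partitions squared
pairwise molecular distances into among- and within-population variance
components.  With raw pairwise difference counts d_ij and populations
p = 1..P of sizes n_p (N total):

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_p sum_{i<j in p} d_ij^2 / n_p
    SS_among  = SS_total - SS_within
    Vb        = SS_within / (N - P)
    Va        = (SS_among / (P - 1) - Vb) / nbar,
                nbar = (N - sum_p n_p^2 / N) / (P - 1)
    Phi_ST    = Va / (Va + Vb)

Significance comes from permuting individuals among populations, with the
(b + 1) / (m + 1) p-value estimator so a permutation p is never exactly 0.
Negative Phi_ST estimates (sampling noise around 0) are reported as
computed, never truncated.

The distance backbone is the raw number of pairwise differences
("number of differences" in Arlequin's terminology); at COI-like divergence
(pi ~ 0.002) model corrections are negligible.

The neighbor-joining tree uses the Studier-Keppler formulation of
Saitou & Nei's algorithm; negative branch lengths are clamped to zero with
the excess transferred to the sister branch so the joined pair's distance
is preserved.  Bootstrap support is by site resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import MISSING, SequenceAlignment
from .errors import ConfigurationError, InputError, UndefinedStatisticError

__all__ = [
    "PairwiseDistanceMatrix",
    "pairwise_diff_comparable",
    "pairwise_difference_matrix",
    "AmovaResult",
    "amova",
    "pairwise_phist",
    "dxy",
    "PairwiseStructureResult",
    "pairwise_structure",
    "NJTree",
    "nj_tree",
    "bootstrap_support",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def pairwise_diff_comparable(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(differences, comparable-sites) count matrices for an encoded alignment.

    Entry (i, j) of the first matrix is the number of sites where sequences
    i and j are both unambiguous and differ; the second matrix counts the
    sites where both are unambiguous.  Both are symmetric with zero and L
    on their diagonals respectively.
    """
    n, L = m.shape
    valid = m != MISSING
    diffs = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diffs[i, i + 1 :] = ((m[i] != m[i + 1 :]) & both).sum(axis=1)
        comp[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    comp += comp.T
    np.fill_diagonal(comp, valid.sum(axis=1))
    return diffs, comp


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric non-negative distance matrix with labels and zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("distance matrix is not symmetric")
        if (self.matrix < 0).any():
            raise InputError("distances must be non-negative")
        if not np.allclose(np.diag(self.matrix), 0):
            raise InputError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def pairwise_difference_matrix(aln: SequenceAlignment) -> PairwiseDistanceMatrix:
    """Raw pairwise difference counts between all sequences (pairwise masking)."""
    diffs, _ = pairwise_diff_comparable(aln.matrix())
    return PairwiseDistanceMatrix(labels=aln.ids, matrix=diffs.astype(float))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Two-level AMOVA decomposition with permutation p-value."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    va: float
    vb: float
    phi_st: float
    p_value: float  # NaN when n_permutations == 0 or Phi_ST undefined
    n_permutations: int

    @property
    def pct_among(self) -> float:
        return 100.0 * self.va / (self.va + self.vb)

    @property
    def pct_within(self) -> float:
        return 100.0 * self.vb / (self.va + self.vb)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations", "total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "sum_of_squares": [self.ss_among, self.ss_within, self.ss_total],
                "variance_component": [self.va, self.vb, self.va + self.vb],
                "pct_variation": [self.pct_among, self.pct_within, 100.0],
                "phi_st": [self.phi_st, np.nan, np.nan],
                "p_value": [self.p_value, np.nan, np.nan],
            }
        )


def _group_indices(populations) -> tuple[list[str], list[np.ndarray]]:
    labels: dict[str, list[int]] = {}
    for i, p in enumerate(populations):
        labels.setdefault(p, []).append(i)
    return list(labels), [np.asarray(v) for v in labels.values()]


def _amova_components(d2: np.ndarray, groups: list[np.ndarray]):
    """(Va, Vb, SS_among, SS_within, SS_total) for one grouping."""
    n_total = sum(len(g) for g in groups)
    n_pops = len(groups)
    ss_total = d2.sum() / (2.0 * n_total)
    ss_within = sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)
    ss_among = ss_total - ss_within
    vb = ss_within / (n_total - n_pops)
    nbar = (n_total - sum(len(g) ** 2 for g in groups) / n_total) / (n_pops - 1)
    va = (ss_among / (n_pops - 1) - vb) / nbar
    return va, vb, ss_among, ss_within, ss_total


def _phi(va: float, vb: float) -> float:
    tot = va + vb
    return np.nan if tot == 0 else va / tot


def amova(
    dist: PairwiseDistanceMatrix,
    populations,
    n_perm: int = 10000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on squared pairwise distances with a permutation test.

    Parameters
    ----------
    dist
        Individual-by-individual distance matrix.
    populations
        Population label per individual, aligned with ``dist.labels``.
    n_perm
        Number of permutations of individuals among populations (0 = skip;
        p-value is then NaN).
    seed
        Seed for the permutation stream.
    """
    populations = list(populations)
    if len(populations) != dist.n:
        raise InputError("populations length does not match distance matrix")
    pop_names, groups = _group_indices(populations)
    if len(groups) < 2:
        raise UndefinedStatisticError("AMOVA requires >= 2 populations")
    n_total = dist.n
    d2 = dist.matrix**2
    va, vb, ss_a, ss_w, ss_t = _amova_components(d2, groups)
    phi_obs = _phi(va, vb)
    if np.isnan(phi_obs):
        warnings.warn("all pairwise distances are zero: Phi_ST undefined")
        p = np.nan
        n_perm = 0
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in groups]
        hits = 0
        idx = np.arange(n_total)
        for _ in range(n_perm):
            rng.shuffle(idx)
            start = 0
            perm_groups = []
            for s in sizes:
                perm_groups.append(idx[start : start + s])
                start += s
            va_p, vb_p, *_ = _amova_components(d2, perm_groups)
            if _phi(va_p, vb_p) >= phi_obs:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    else:
        p = np.nan
    return AmovaResult(
        df_among=len(groups) - 1,
        df_within=n_total - len(groups),
        ss_among=ss_a,
        ss_within=ss_w,
        ss_total=ss_t,
        va=va,
        vb=vb,
        phi_st=phi_obs,
        p_value=p,
        n_permutations=n_perm,
    )


def pairwise_phist(
    dist: PairwiseDistanceMatrix,
    populations,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi_ST (2-population AMOVA per pair) with permutation p-values.

    Returns (phi_st, p_values) as symmetric DataFrames over population labels.
    Negative estimates are reported as computed.
    """
    populations = list(populations)
    pop_names, groups = _group_indices(populations)
    k = len(pop_names)
    phi = np.full((k, k), 0.0)
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(k - 1):
        for b in range(a + 1, k):
            idx = np.concatenate([groups[a], groups[b]])
            sub = PairwiseDistanceMatrix(
                labels=tuple(dist.labels[i] for i in idx),
                matrix=dist.matrix[np.ix_(idx, idx)],
            )
            labs = [populations[i] for i in idx]
            res = amova(
                sub, labs, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
            )
            phi[a, b] = phi[b, a] = res.phi_st
            pvals[a, b] = pvals[b, a] = res.p_value
    phi_df = pd.DataFrame(phi, index=pop_names, columns=pop_names)
    p_df = pd.DataFrame(pvals, index=pop_names, columns=pop_names)
    return phi_df, p_df


def dxy(aln: SequenceAlignment, pop_a: str, pop_b: str) -> float:
    """Average per-site between-population divergence (uncorrected, masked).

    Mean over all inter-population sequence pairs of the fraction of
    comparable sites at which the pair differs.
    """
    sub_a = aln.subset(pop_a)
    sub_b = aln.subset(pop_b)
    ma, mb = sub_a.matrix(), sub_b.matrix()
    fractions = []
    for i in range(ma.shape[0]):
        both = (ma[i] != MISSING) & (mb != MISSING)
        comp = both.sum(axis=1).astype(float)
        d = ((ma[i] != mb) & both).sum(axis=1)
        ok = comp > 0
        fractions.extend((d[ok] / comp[ok]).tolist())
    if not fractions:
        raise UndefinedStatisticError("no comparable inter-population pairs")
    return float(np.mean(fractions))


@dataclass
class PairwiseStructureResult:
    """Pairwise Phi_ST / p-value / divergence matrices (Table-4-style bundle)."""

    populations: tuple[str, ...]
    phi_st: pd.DataFrame
    p_values: pd.DataFrame
    p_values_holm: pd.DataFrame
    d_xy: pd.DataFrame

    def combined_table(self) -> pd.DataFrame:
        """Phi_ST below the diagonal, d_xy above (conventional layout)."""
        pops = list(self.populations)
        out = pd.DataFrame("", index=pops, columns=pops, dtype=object)
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    out.loc[a, b] = f"{self.phi_st.loc[a, b]:.5f}"
                elif i < j:
                    out.loc[a, b] = f"{self.d_xy.loc[a, b]:.4f}"
        return out


def pairwise_structure(
    aln: SequenceAlignment, n_perm: int = 10000, seed: int | None = None
) -> PairwiseStructureResult:
    """Pairwise Phi_ST with raw and Holm-adjusted p-values, plus d_xy."""
    from statsmodels.stats.multitest import multipletests

    dist = pairwise_difference_matrix(aln)
    phi, pvals = pairwise_phist(dist, aln.populations, n_perm=n_perm, seed=seed)
    pops = list(phi.index)
    dmat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            dmat.loc[a, b] = dmat.loc[b, a] = dxy(aln, a, b)
    holm = pvals.copy()
    iu = np.triu_indices(len(pops), k=1)
    raw = pvals.to_numpy()[iu]
    if np.isfinite(raw).all() and len(raw):
        adj = multipletests(raw, method="holm")[1]
        h = holm.to_numpy()
        h[iu] = adj
        h.T[iu] = adj
        holm = pd.DataFrame(h, index=pops, columns=pops)
    return PairwiseStructureResult(
        populations=tuple(pops),
        phi_st=phi,
        p_values=pvals,
        p_values_holm=holm,
        d_xy=dmat,
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class NJTree:
    """Unrooted tree with branch lengths, backed by a networkx graph.

    Leaves are the input labels; internal nodes are integers.  Provides
    Newick export, split (bipartition) extraction, and leaf-to-leaf path
    lengths for additivity checks.
    """

    def __init__(self, graph: nx.Graph, leaves: tuple[str, ...]):
        self.graph = graph
        self.leaves = tuple(leaves)

    def path_length_matrix(self) -> pd.DataFrame:
        out = pd.DataFrame(0.0, index=self.leaves, columns=self.leaves)
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="length"))
        for a in self.leaves:
            for b in self.leaves:
                out.loc[a, b] = lengths[a][b]
        return out

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the first leaf."""
        anchor = self.leaves[0]
        out: set[frozenset] = set()
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {x for x in nx.node_connected_component(g, u) if x in set(self.leaves)}
            if anchor in side:
                side = set(self.leaves) - side
            if 2 <= len(side) <= len(self.leaves) - 2:
                out.add(frozenset(side))
        return out

    def newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string (rooted arbitrarily at the highest-degree internal
        node); optional bootstrap supports become internal node labels."""
        leafset = set(self.leaves)
        internal = [n for n in self.graph.nodes if n not in leafset]
        root = max(internal, key=lambda n: self.graph.degree(n)) if internal else self.leaves[0]
        anchor = self.leaves[0]

        def label_for(node, parent) -> str:
            if support is None:
                return ""
            g = self.graph.copy()
            g.remove_edge(node, parent)
            side = {x for x in nx.node_connected_component(g, node) if x in leafset}
            if anchor in side:
                side = leafset - side
            key = frozenset(side)
            if key in support:
                return f"{support[key]:.0f}"
            return ""

        def rec(node, parent) -> str:
            children = [x for x in self.graph.neighbors(node) if x != parent]
            if not children:  # leaf
                bl = self.graph[node][parent]["length"]
                return f"{node}:{bl:.6g}"
            inner = ",".join(rec(c, node) for c in children)
            if parent is None:
                return f"({inner});"
            bl = self.graph[node][parent]["length"]
            return f"({inner}){label_for(node, parent)}:{bl:.6g}"

        return rec(root, None)


def nj_tree(dist: PairwiseDistanceMatrix) -> NJTree:
    """Neighbor-joining (Studier-Keppler) tree from a distance matrix.

    Deterministic: ties in the Q criterion are broken by scan order over the
    current node list.  Negative branch lengths are clamped to zero and the
    excess moved to the sister branch, preserving the pair's joined distance.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 2:
        raise UndefinedStatisticError("NJ requires >= 2 taxa")
    g = nx.Graph()
    if n == 2:
        g.add_edge(labels[0], labels[1], length=float(dist.matrix[0, 1]))
        return NJTree(g, tuple(labels))

    D = dist.matrix.astype(float).copy()
    nodes: list = list(labels)
    next_internal = 0
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q matrix; pick first minimum in scan order for determinism
        best = None
        best_q = np.inf
        for i in range(m - 1):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, transferring the excess to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = next_internal
        next_internal += 1
        g.add_edge(nodes[i], new, length=float(li))
        g.add_edge(nodes[j], new, length=float(lj))
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.zeros((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [new]
        D = D_next
    final = max(float(D[0, 1]), 0.0)
    g.add_edge(nodes[0], nodes[1], length=final)
    return NJTree(g, tuple(labels))


def bootstrap_support(
    aln: SequenceAlignment,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[NJTree, dict[frozenset, float]]:
    """Site-resampling bootstrap support for the NJ tree of an alignment.

    Builds the NJ tree on the full alignment's pairwise difference matrix,
    then resamples columns with replacement ``n_reps`` times; the support of
    each split is the percentage of replicate trees containing it.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    base = nj_tree(pairwise_difference_matrix(aln))
    targets = base.splits()
    hits = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    m = aln.matrix()
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        mb = m[:, cols]
        diffs, _ = pairwise_diff_comparable(mb)
        rep = nj_tree(PairwiseDistanceMatrix(aln.ids, diffs.astype(float)))
        rep_splits = rep.splits()
        for s in targets:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * h / n_reps for s, h in hits.items()}
    return base, support
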