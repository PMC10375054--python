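"""Single-locus coalescent simulation and deterministic test fixtures.

A lightweight backwards-in-time simulator for a haploid, non-recombining
locus (mtDNA scaling: theta = 2Nu per sequence, time in units of N
generations, so a pair of lineages in one deme coalesces at rate 1 and
accumulates differences at rate theta per unit of scaled time).  Supported
demographies:

* constant population size;
* sudden expansion: at scaled time ``tau_event`` in the past the population
  size drops (looking backwards) by ``growth_factor``, i.e. the present-day
  population is ``growth_factor`` times larger than the ancestral one.  In
  mutational time units this change happened tau = theta * tau_event before
  present, which is exactly the tau of the mismatch-distribution model;
* finite island model: ``n_demes`` demes exchanging migrants at scaled rate
  ``migration`` (= Nm) per lineage, optionally combined with a sudden
  expansion applied to every deme.

Mutations are dropped on branches as a Poisson process at rate theta/2 per
lineage per unit of scaled time, under either an infinite-sites model (every
mutation hits a fresh column) or finite-sites Jukes-Cantor.

The module also provides the fixture generators used throughout the test
suite: an alignment exactly consistent with a published haplotype-by-locality
count table for six localities of 65 barnacles each (390 sequences, 84
haplotypes, 683 bp), and a six-deme "study-like" simulation with high gene
flow and a recent expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .alignment import SequenceAlignment
from .errors import ConfigurationError

__all__ = [
    "Constant",
    "SuddenExpansion",
    "Island",
    "CoalescentParams",
    "Genealogy",
    "SimulatedDataset",
    "simulate_coalescent",
    "simulate_genealogy",
    "branch_statistics",
    "pairwise_differences_from_genealogy",
    "mismatch_from_genealogy",
    "simulate_fujian_like",
    "table1_fixture",
    "TABLE1_POPULATIONS",
    "TABLE1_COUNTS",
]


# ---------------------------------------------------------------------------
# Demography descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Constant:
    """Constant-size panmictic population."""


@dataclass(frozen=True)
class SuddenExpansion:
    """Instantaneous size change at ``tau_event`` (scaled time) in the past.

    ``growth_factor`` > 1 means the present population is larger than the
    ancestral one (coalescence is ``growth_factor`` times faster before the
    event, looking backwards in time).
    """

    tau_event: float
    growth_factor: float


@dataclass(frozen=True)
class Island:
    """Finite island model; optional sudden expansion applied to all demes.

    With ``merge_at_event`` the demes coalesce into a single (small)
    ancestral population at ``tau_event``: the colonisation scenario in
    which today's demes all derive from one expanding source population.
    """

    n_demes: int
    migration: float  # scaled rate Nm per lineage
    tau_event: float | None = None
    growth_factor: float = 1.0
    merge_at_event: bool = False


Demography = Union[Constant, SuddenExpansion, Island]


@dataclass
class CoalescentParams:
    """Parameters of one simulation run.

    theta is the scaled mutation rate per sequence (2Nu, haploid scaling).
    """

    n_per_deme: tuple[int, ...]
    theta: float
    demography: Demography = field(default_factory=Constant)
    L: int = 683
    mutation_model: str = "infinite_sites"  # or "finite_sites_JC"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_per_deme = tuple(int(x) for x in np.atleast_1d(self.n_per_deme))
        if any(x < 1 for x in self.n_per_deme):
            raise ConfigurationError("all deme sample sizes must be positive")
        if self.theta <= 0:
            raise ConfigurationError("theta must be > 0")
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if self.mutation_model not in ("infinite_sites", "finite_sites_JC"):
            raise ConfigurationError(
                f"unknown mutation model {self.mutation_model!r}"
            )
        if isinstance(self.demography, Island):
            if self.demography.n_demes != len(self.n_per_deme):
                raise ConfigurationError(
                    "island n_demes does not match len(n_per_deme)"
                )
            if self.demography.migration < 0:
                raise ConfigurationError("migration rate must be >= 0")
            if self.demography.migration == 0 and self.demography.n_demes > 1:
                raise ConfigurationError(
                    "island model with Nm = 0 and > 1 deme never finds a common ancestor"
                )
        elif len(self.n_per_deme) != 1:
            raise ConfigurationError("multiple demes require the island demography")
        if isinstance(self.demography, (SuddenExpansion, Island)):
            tau = getattr(self.demography, "tau_event", None)
            if tau is not None and tau < 0:
                raise ConfigurationError("tau_event must be >= 0")
            if getattr(self.demography, "growth_factor", 1.0) <= 0:
                raise ConfigurationError("growth_factor must be > 0")


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Coalescent tree: nodes 0..n-1 are leaves, node 2n-2 is the root.

    ``parent[i]`` is -1 for the root; node ids increase with creation time,
    so iterating in id order is a valid postorder (children before parents).
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_demes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        nz = np.arange(self.n_nodes - 1)
        bl[nz] = self.time[self.parent[nz]] - self.time[nz]
        return bl

    def leaf_membership(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves): leaves descending from each node."""
        memb = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        memb[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for i in range(self.n_nodes - 1):
            memb[self.parent[i]] |= memb[i]
        return memb

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1):
            ch[self.parent[i]].append(i)
        return ch


def simulate_genealogy(
    n_per_deme,
    rng: np.random.Generator,
    migration: float = 0.0,
    tau_event: float | None = None,
    growth_factor: float = 1.0,
    merge_at_event: bool = False,
) -> Genealogy:
    """Structured coalescent genealogy under a piecewise-constant size history.

    Time is in units of the (present-day) deme size; coalescence within a
    deme occurs at rate C(k, 2) multiplied by ``growth_factor`` for times
    older than ``tau_event``.
    """
    n_per_deme = [int(x) for x in np.atleast_1d(n_per_deme)]
    n = sum(n_per_deme)
    n_demes = len(n_per_deme)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    leaf_demes = np.concatenate(
        [np.full(k, d, dtype=np.int64) for d, k in enumerate(n_per_deme)]
    )
    demes: list[list[int]] = []
    nid = 0
    for k in n_per_deme:
        demes.append(list(range(nid, nid + k)))
        nid += k
    next_node = n
    t = 0.0
    k_left = n
    merged = False
    while k_left > 1:
        ancestral = tau_event is not None and t >= tau_event
        if ancestral and merge_at_event and not merged:
            demes = [[x for d in demes for x in d]]
            n_demes = 1
            merged = True
        factor = growth_factor if ancestral else 1.0
        coal_rates = [factor * len(d) * (len(d) - 1) / 2.0 for d in demes]
        mig_rate = migration * k_left if n_demes > 1 else 0.0
        total = sum(coal_rates) + mig_rate
        if total == 0:
            raise ConfigurationError(
                "no events possible: isolated lineages cannot coalesce"
            )
        dt = rng.exponential(1.0 / total)
        if tau_event is not None and t < tau_event <= t + dt:
            t = tau_event  # rate change; redraw by memorylessness
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        event_deme = None
        for d, cr in enumerate(coal_rates):
            acc += cr
            if u < acc:
                event_deme = d
                break
        if event_deme is not None:
            members = demes[event_deme]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            parent[a] = parent[b] = next_node
            times[next_node] = t
            members.remove(a)
            members.remove(b)
            members.append(next_node)
            next_node += 1
            k_left -= 1
        else:
            # migration: pick a lineage uniformly, move it to another deme
            flat = [(d, x) for d, members in enumerate(demes) for x in members]
            d, x = flat[rng.integers(len(flat))]
            choices = [e for e in range(n_demes) if e != d]
            target = choices[rng.integers(len(choices))]
            demes[d].remove(x)
            demes[target].append(x)
    return Genealogy(parent=parent, time=times, n_leaves=n, leaf_demes=leaf_demes)


def _demography_args(demography: Demography) -> dict:
    if isinstance(demography, Constant):
        return dict(migration=0.0, tau_event=None, growth_factor=1.0)
    if isinstance(demography, SuddenExpansion):
        return dict(
            migration=0.0,
            tau_event=demography.tau_event,
            growth_factor=demography.growth_factor,
        )
    if isinstance(demography, Island):
        return dict(
            migration=demography.migration,
            tau_event=demography.tau_event,
            growth_factor=demography.growth_factor,
            merge_at_event=demography.merge_at_event,
        )
    raise ConfigurationError(f"unknown demography: {demography!r}")


# ---------------------------------------------------------------------------
# Mutations and summary statistics on the genealogy
# ---------------------------------------------------------------------------


def mutation_counts(
    gen: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson mutation counts on the branch above each node (rate theta/2)."""
    return rng.poisson(0.5 * theta * gen.branch_lengths())


def branch_statistics(gen: Genealogy, muts: np.ndarray) -> tuple[int, float, int]:
    """(S, k_hat, n_haplotypes) under infinite sites, without building sequences.

    Every mutation segregates (all branches subtend a proper leaf subset),
    k_hat follows from per-branch leaf counts, and two leaves share a
    haplotype iff the tree path between them carries no mutation.
    """
    n = gen.n_leaves
    if n == 1:
        return 0, 0.0, 1
    memb = gen.leaf_membership()
    desc = memb.sum(axis=1)
    nonroot = np.arange(gen.n_nodes - 1)
    s = int(muts[nonroot].sum())
    pairs = n * (n - 1) / 2.0
    k_hat = float(
        np.sum(muts[nonroot] * desc[nonroot] * (n - desc[nonroot])) / pairs
    )
    # haplotype classes: contract mutation-free branches
    find_parent = np.arange(gen.n_nodes)

    def find(x: int) -> int:
        while find_parent[x] != x:
            find_parent[x] = find_parent[find_parent[x]]
            x = find_parent[x]
        return x

    for i in nonroot:
        if muts[i] == 0:
            find_parent[find(i)] = find(gen.parent[i])
    n_hap = len({find(i) for i in range(n)})
    return s, k_hat, n_hap


def pairwise_differences_from_genealogy(
    gen: Genealogy, muts: np.ndarray
) -> np.ndarray:
    """Leaf-by-leaf pairwise difference counts implied by branch mutations."""
    n = gen.n_leaves
    memb = gen.leaf_membership()
    d = np.zeros((n, n))
    for i in range(gen.n_nodes - 1):
        if muts[i]:
            x = memb[i].astype(float)
            d += muts[i] * (x[:, None] != x[None, :])
    return d


def mismatch_from_genealogy(gen: Genealogy, muts: np.ndarray) -> np.ndarray:
    """Normalised mismatch distribution implied by branch mutations."""
    d = pairwise_differences_from_genealogy(gen, muts)
    iu = np.triu_indices(gen.n_leaves, k=1)
    vals = d[iu].astype(int)
    freq = np.bincount(vals, minlength=int(vals.max()) + 1 if len(vals) else 1)
    return freq / freq.sum()


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def _build_sequences(
    gen: Genealogy,
    muts: np.ndarray,
    L: int,
    model: str,
    rng: np.random.Generator,
) -> list[str]:
    bases = "ACGT"
    total = int(muts[: gen.n_nodes - 1].sum())
    if model == "infinite_sites":
        if total > L:
            raise ConfigurationError(
                f"{total} mutations exceed {L} sites: increase L or use finite_sites_JC"
            )
        positions = rng.choice(L, size=total, replace=False)
    else:
        positions = rng.integers(0, L, size=total)
    # assign positions to branches in node order
    offsets = np.zeros(gen.n_nodes, dtype=int)
    np.cumsum(muts[: gen.n_nodes - 1], out=offsets[1:])
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    children = gen.children()
    seqs: dict[int, np.ndarray] = {}
    stack: list[tuple[int, np.ndarray]] = [(gen.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node < gen.n_leaves:
            seqs[node] = seq
        for child in children[node]:
            cs = seq.copy()
            for p in positions[offsets[child] : offsets[child] + muts[child]]:
                cs[p] = (cs[p] + 1 + rng.integers(3)) % 4
            stack.append((child, cs))
    return [
        "".join(bases[b] for b in seqs[i]) for i in range(gen.n_leaves)
    ]


@dataclass
class SimulatedDataset:
    """Alignment plus the true genealogy and parameters that produced it."""

    alignment: SequenceAlignment
    genealogy: Genealogy
    mutations: np.ndarray  # per-branch counts, indexed by child node
    params: CoalescentParams


def simulate_coalescent(params: CoalescentParams) -> SimulatedDataset:
    """Simulate an alignment under the given coalescent model.

    Bit-identical output for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    args = _demography_args(params.demography)
    gen = simulate_genealogy(params.n_per_deme, rng, **args)
    muts = mutation_counts(gen, params.theta, rng)
    seqs = _build_sequences(gen, muts, params.L, params.mutation_model, rng)
    n_demes = len(params.n_per_deme)
    width = len(str(gen.n_leaves))
    ids = tuple(f"s{i + 1:0{width}d}" for i in range(gen.n_leaves))
    pops = tuple(
        f"D{gen.leaf_demes[i] + 1}" if n_demes > 1 else "pop1"
        for i in range(gen.n_leaves)
    )
    aln = SequenceAlignment(ids=ids, populations=pops, sequences=tuple(seqs))
    return SimulatedDataset(alignment=aln, genealogy=gen, mutations=muts, params=params)


# ---------------------------------------------------------------------------
# Study-like six-deme simulation
# ---------------------------------------------------------------------------

#: Locality labels of the emulated sampling design.
TABLE1_POPULATIONS = ("ND", "FZ", "PT", "QZ", "XM", "ZZ")


def simulate_fujian_like(
    seed: int | None = None,
    n_per_deme: int = 65,
    L: int = 683,
    theta: float = 12.0,
    migration: float = 50.0,
    tau_event: float = 1.0 / 12.0,
    growth_factor: float = 50.0,
) -> SimulatedDataset:
    """Six demes x 65 samples of a 683-site locus, high gene flow, recent expansion.

    Defaults emulate a COI-like dataset: six demes exchanging migrants at
    Nm = 50 (so population structure is negligible), all founded from a
    single ancestral population 50x smaller at scaled time ``tau_event``
    (mutational time tau = theta * tau_event = 1.0).  The resulting
    genealogies are star-like: typically one dominant haplotype above 40%
    relative frequency, per-deme haplotype diversity roughly 0.4-0.85 and
    per-deme nucleotide diversity roughly 0.0005-0.004.
    """
    params = CoalescentParams(
        n_per_deme=(n_per_deme,) * 6,
        theta=theta,
        demography=Island(
            n_demes=6,
            migration=migration,
            tau_event=tau_event,
            growth_factor=growth_factor,
            merge_at_event=True,
        ),
        L=L,
        mutation_model="infinite_sites",
        seed=seed,
    )
    ds = simulate_coalescent(params)
    # relabel demes with the study's locality names
    aln = ds.alignment
    relabel = dict(zip((f"D{i + 1}" for i in range(6)), TABLE1_POPULATIONS))
    ds.alignment = SequenceAlignment(
        ids=aln.ids,
        populations=tuple(relabel[p] for p in aln.populations),
        sequences=aln.sequences,
    )
    return ds


# ---------------------------------------------------------------------------
# Haplotype-count-table fixture
# ---------------------------------------------------------------------------

# 84 haplotypes x 6 localities (ND, FZ, PT, QZ, XM, ZZ); column sums are 65,
# the grand total is 390, the most frequent haplotype totals 224, and 59
# haplotypes are confined to a single locality.
TABLE1_COUNTS = np.array(
    [
        [1, 0, 0, 3, 3, 2],    # H1
        [30, 42, 32, 36, 47, 37],  # H2
        [0, 0, 0, 0, 0, 2],    # H3
        [0, 0, 0, 0, 0, 2],    # H4
        [1, 2, 2, 3, 0, 2],    # H5
        [0, 0, 0, 2, 0, 5],    # H6
        [0, 0, 0, 0, 0, 1],    # H7
        [1, 0, 0, 0, 0, 1],    # H8
        [2, 2, 4, 4, 0, 5],    # H9
        [0, 1, 0, 0, 0, 1],    # H10
        [0, 0, 0, 0, 0, 1],    # H11
        [0, 0, 0, 0, 0, 1],    # H12
        [2, 0, 0, 0, 2, 1],    # H13
        [0, 0, 0, 0, 0, 1],    # H14
        [0, 0, 0, 0, 0, 1],    # H15
        [0, 1, 2, 0, 0, 1],    # H16
        [1, 0, 0, 0, 3, 1],    # H17
        [0, 0, 0, 0, 1, 0],    # H18
        [1, 0, 0, 1, 3, 0],    # H19
        [0, 0, 0, 0, 1, 0],    # H20
        [0, 0, 0, 0, 1, 0],    # H21
        [0, 0, 0, 0, 1, 0],    # H22
        [0, 0, 0, 0, 1, 0],    # H23
        [0, 0, 0, 0, 1, 0],    # H24
        [0, 0, 0, 0, 1, 0],    # H25
        [2, 3, 3, 4, 0, 0],    # H26
        [0, 0, 0, 1, 0, 0],    # H27
        [0, 0, 0, 1, 0, 0],    # H28
        [2, 0, 0, 1, 0, 0],    # H29
        [0, 0, 0, 1, 0, 0],    # H30
        [0, 0, 0, 1, 0, 0],    # H31
        [0, 0, 0, 1, 0, 0],    # H32
        [0, 0, 0, 1, 0, 0],    # H33
        [0, 0, 0, 1, 0, 0],    # H34
        [0, 0, 0, 1, 0, 0],    # H35
        [0, 0, 0, 1, 0, 0],    # H36
        [0, 0, 0, 1, 0, 0],    # H37
        [0, 0, 0, 1, 0, 0],    # H38
        [1, 0, 1, 0, 0, 0],    # H39
        [0, 0, 1, 0, 0, 0],    # H40
        [0, 0, 1, 0, 0, 0],    # H41
        [0, 0, 1, 0, 0, 0],    # H42
        [0, 0, 1, 0, 0, 0],    # H43
        [0, 0, 1, 0, 0, 0],    # H44
        [0, 0, 1, 0, 0, 0],    # H45
        [0, 0, 1, 0, 0, 0],    # H46
        [1, 0, 1, 0, 0, 0],    # H47
        [0, 0, 1, 0, 0, 0],    # H48
        [0, 0, 1, 0, 0, 0],    # H49
        [0, 0, 1, 0, 0, 0],    # H50
        [0, 1, 1, 0, 0, 0],    # H51
        [0, 1, 1, 0, 0, 0],    # H52
        [0, 1, 1, 0, 0, 0],    # H53
        [0, 1, 1, 0, 0, 0],    # H54
        [0, 1, 1, 0, 0, 0],    # H55
        [0, 1, 1, 0, 0, 0],    # H56
        [0, 1, 1, 0, 0, 0],    # H57
        [0, 1, 1, 0, 0, 0],    # H58
        [0, 1, 1, 0, 0, 0],    # H59
        [0, 1, 1, 0, 0, 0],    # H60
        [1, 0, 0, 0, 0, 0],    # H61
        [1, 0, 0, 0, 0, 0],    # H62
        [1, 0, 0, 0, 0, 0],    # H63
        [1, 0, 0, 0, 0, 0],    # H64
        [1, 0, 0, 0, 0, 0],    # H65
        [1, 0, 0, 0, 0, 0],    # H66
        [1, 0, 0, 0, 0, 0],    # H67
        [1, 0, 0, 0, 0, 0],    # H68
        [1, 0, 0, 0, 0, 0],    # H69
        [1, 0, 0, 0, 0, 0],    # H70
        [1, 0, 0, 0, 0, 0],    # H71
        [1, 0, 0, 0, 0, 0],    # H72
        [1, 0, 0, 0, 0, 0],    # H73
        [1, 0, 0, 0, 0, 0],    # H74
        [1, 0, 0, 0, 0, 0],    # H75
        [1, 0, 0, 0, 0, 0],    # H76
        [1, 0, 0, 0, 0, 0],    # H77
        [1, 0, 0, 0, 0, 0],    # H78
        [1, 0, 0, 0, 0, 0],    # H79
        [1, 0, 0, 0, 0, 0],    # H80
        [0, 1, 0, 0, 0, 0],    # H81
        [0, 1, 0, 0, 0, 0],    # H82
        [0, 1, 0, 0, 0, 0],    # H83
        [0, 1, 0, 0, 0, 0],    # H84
    ],
    dtype=int,
)


def _fixture_haplotype_sequences(L: int = 683) -> list[str]:
    """84 distinct stop-free sequences whose differences sit in the first
    100 columns.

    The backbone is the codon CTA repeated and is assigned to the second
    haplotype (the most frequent one in the count table), so the fixture's
    haplotype network is a star centred on the dominant haplotype, as in the
    real data; every other haplotype substitutes G at its own column.  A
    single substitution in a CTA codon can never create a stop codon
    (TAA/TAG require two changes), so every sequence translates cleanly in
    frame 0 under the invertebrate mitochondrial code, and any two
    haplotypes differ at 1 or 2 sites.
    """
    base = ("CTA" * (L // 3 + 1))[:L]
    seqs = []
    pos = 0
    for i in range(84):
        if i == 1:
            seqs.append(base)
            continue
        seqs.append(base[:pos] + "G" + base[pos + 1 :])
        pos += 1
    return seqs


def table1_fixture(L: int = 683) -> SequenceAlignment:
    """Alignment exactly consistent with the 84 x 6 haplotype count table.

    Sequences are arbitrary but fixed (synthetic stand-ins for the real,
    unpublished haplotype sequences); every count-based statistic -- sample
    sizes, haplotype totals, sharing, haplotype diversity -- reproduces the
    published values.  Records are ordered haplotype-major so collapsing
    re-assigns the same H1..H84 names.
    """
    seqs = _fixture_haplotype_sequences(L)
    ids: list[str] = []
    pops: list[str] = []
    out: list[str] = []
    serial = {p: 0 for p in TABLE1_POPULATIONS}
    for h, row in enumerate(TABLE1_COUNTS):
        for j, pop in enumerate(TABLE1_POPULATIONS):
            for _ in range(int(row[j])):
                serial[pop] += 1
                ids.append(f"{pop}_{serial[pop]:03d}")
                pops.append(pop)
                out.append(seqs[h])
    return SequenceAlignment(ids=tuple(ids), populations=tuple(pops), sequences=tuple(out))
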