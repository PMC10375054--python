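"""Collapsing aligned sequences into haplotypes and sharing statistics.

For a non-recombining haploid marker, individuals carrying an identical
sequence share a haplotype.  Sequences are grouped by exact (uppercase)
string match: records containing ambiguous bases are therefore merged only
with byte-identical records, never wildcard-matched into a compatible
haplotype.  Haplotypes are named H1, H2, ... in order of first appearance
in the input, which makes naming deterministic given record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .errors import InputError, UndefinedStatisticError


@dataclass
class HaplotypeTable:
    """Distinct haplotypes x populations count matrix.

    Invariants: every haplotype has total count >= 1, sequences are pairwise
    distinct, and the grand total equals the number of sequences collapsed.
    """

    names: tuple[str, ...]
    sequences: tuple[str, ...]
    counts: np.ndarray  # shape (k, n_populations), non-negative ints
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.names)
        if self.counts.shape != (k, len(self.populations)):
            raise InputError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{k} haplotypes x {len(self.populations)} populations"
            )
        if (self.counts < 0).any():
            raise InputError("haplotype counts must be non-negative")
        if k and (self.counts.sum(axis=1) < 1).any():
            raise InputError("every haplotype must have total count >= 1")
        if len(set(self.sequences)) != len(self.sequences):
            raise InputError("haplotype sequences must be pairwise distinct")

    @property
    def k(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.names)

    @property
    def n(self) -> int:
        """Total number of sequences represented."""
        return int(self.counts.sum())

    def totals(self) -> np.ndarray:
        """Per-haplotype total counts across populations."""
        return self.counts.sum(axis=1)

    def population_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Count matrix as a DataFrame with a Total column (Table-1 layout)."""
        df = pd.DataFrame(self.counts, index=list(self.names), columns=list(self.populations))
        df["Total"] = self.totals()
        df.index.name = "Haplotype"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_fasta(self, path: str | Path, wrap: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")

    def to_alignment(self) -> SequenceAlignment:
        """Re-expand to one record per sampled sequence (inverse of collapsing).

        Record ids are synthetic (``H3_ND_2``); the multiset of
        (population, sequence) pairs equals that of the collapsed input.
        """
        ids, pops, seqs = [], [], []
        for name, seq, row in zip(self.names, self.sequences, self.counts):
            for pop, c in zip(self.populations, row):
                for j in range(int(c)):
                    ids.append(f"{name}_{pop}_{j + 1}")
                    pops.append(pop)
                    seqs.append(seq)
        return SequenceAlignment(tuple(ids), tuple(pops), tuple(seqs))


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeTable:
    """Group identical sequences into haplotypes (exact string match).

    Names are assigned H1, H2, ... in order of first appearance.
    """
    pops = aln.population_labels
    pop_index = {p: j for j, p in enumerate(pops)}
    order: dict[str, int] = {}
    rows: list[list[int]] = []
    for pop, seq in zip(aln.populations, aln.sequences):
        if seq not in order:
            order[seq] = len(order)
            rows.append([0] * len(pops))
        rows[order[seq]][pop_index[pop]] += 1
    sequences = tuple(order)  # insertion order
    return HaplotypeTable(
        names=tuple(f"H{i + 1}" for i in range(len(sequences))),
        sequences=sequences,
        counts=np.array(rows, dtype=int),
        populations=pops,
    )


@dataclass
class SharingProfile:
    """How many populations each haplotype occurs in, and the private/shared split."""

    n_localities: np.ndarray  # per haplotype, >= 1
    n_private: int  # exactly one population
    n_shared: int  # two or more populations


def sharing_profile(table: HaplotypeTable) -> SharingProfile:
    occ = (table.counts > 0).sum(axis=1)
    private = int(np.sum(occ == 1))
    shared = int(np.sum(occ >= 2))
    return SharingProfile(n_localities=occ, n_private=private, n_shared=shared)


@dataclass
class DominantHaplotype:
    name: str
    total: int
    frequency_pct: float  # 100 * total / N
    n_populations: int


def dominant_haplotype(table: HaplotypeTable) -> DominantHaplotype:
    """Most frequent haplotype overall; ties broken by name (input) order."""
    if table.k < 1:
        raise UndefinedStatisticError("empty haplotype table")
    totals = table.totals()
    i = int(np.argmax(totals))  # argmax returns the first maximum -> name order
    return DominantHaplotype(
        name=table.names[i],
        total=int(totals[i]),
        frequency_pct=100.0 * totals[i] / table.n,
        n_populations=int((table.counts[i] > 0).sum()),
    )


def per_population_haplotype_counts(table: HaplotypeTable) -> pd.DataFrame:
    """Per population: sample size n and number of haplotypes present (N_H)."""
    sizes = table.population_sizes()
    if (sizes == 0).any():
        empty = [p for p, s in zip(table.populations, sizes) if s == 0]
        raise UndefinedStatisticError(f"population(s) with zero samples: {empty}")
    return pd.DataFrame(
        {
            "n": sizes,
            "n_haplotypes": (table.counts > 0).sum(axis=0),
        },
        index=list(table.populations),
    )
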