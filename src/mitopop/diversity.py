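"""Haplotype diversity, nucleotide diversity and mean pairwise differences.

Estimators
----------
Haplotype (gene) diversity uses Nei's unbiased estimator

    h = n (1 - sum_i p_i^2) / (n - 1),

the probability that two sequences drawn without replacement carry
different haplotypes.  Nucleotide diversity pi is the mean over all
unordered pairs of the per-site proportion of differing positions, with
pairwise masking: for each pair only sites where both sequences carry an
unambiguous base are compared.  k_hat is the unnormalised mean number of
pairwise differences, the quantity the mismatch distribution is built on.

"Average" diversity across populations is the unweighted arithmetic mean
of the per-population values (not the pooled-sample statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .errors import UndefinedStatisticError
from .haplotypes import HaplotypeTable
from .structure import pairwise_diff_comparable


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts.

    Parameters
    ----------
    counts
        Iterable of positive integer counts, one per haplotype.
    """
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires n >= 2")
    return float(n * (1.0 - np.sum((c / n) ** 2)) / (n - 1.0))


def nucleotide_diversity(
    aln: SequenceAlignment, population: str = "all"
) -> tuple[float, float]:
    """(pi, k_hat) for one population (or the pooled sample).

    pi averages, over all unordered pairs, the fraction of differing sites
    among the pair's comparable (both-unambiguous) sites; k_hat averages the
    raw difference counts.  Pairs with no comparable sites are excluded from
    the pi average.
    """
    sub = aln.subset(population)
    if sub.n_sequences < 2:
        raise UndefinedStatisticError(
            f"nucleotide diversity requires >= 2 sequences (population {population!r})"
        )
    diffs, comp = pairwise_diff_comparable(sub.matrix())
    iu = np.triu_indices(sub.n_sequences, k=1)
    d = diffs[iu].astype(float)
    c = comp[iu].astype(float)
    k_hat = float(d.mean())
    usable = c > 0
    if not usable.any():
        raise UndefinedStatisticError("no pair of sequences shares a comparable site")
    pi = float(np.mean(d[usable] / c[usable]))
    return pi, k_hat


@dataclass
class DiversityStats:
    """Per-population diversity summary (one row of a Table-2-style report)."""

    population: str
    n: int
    n_haplotypes: int
    h: float
    pi: float
    k_hat: float


def summarize_diversity(
    table: HaplotypeTable, aln: SequenceAlignment
) -> pd.DataFrame:
    """Per-population diversity plus the unweighted across-population mean.

    Returns a DataFrame indexed by population with columns
    ``n, n_haplotypes, h, pi, k_hat`` and a final ``mean`` row holding the
    unweighted arithmetic means of h, pi and k_hat.  Values are kept at full
    precision; round on output (h to 3 decimals, pi to 5) if mirroring a
    printed table.
    """
    rows: list[DiversityStats] = []
    for j, pop in enumerate(table.populations):
        counts = table.counts[:, j]
        counts = counts[counts > 0]
        pi, k_hat = nucleotide_diversity(aln, pop)
        rows.append(
            DiversityStats(
                population=pop,
                n=int(counts.sum()),
                n_haplotypes=int(len(counts)),
                h=haplotype_diversity(counts),
                pi=pi,
                k_hat=k_hat,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("population")
    df.loc["mean"] = {
        "n": np.nan,
        "n_haplotypes": np.nan,
        "h": df["h"].mean(),
        "pi": df["pi"].mean(),
        "k_hat": df["k_hat"].mean(),
    }
    return df
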