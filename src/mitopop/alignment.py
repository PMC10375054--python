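"""Aligned-FASTA input and per-site alignment summaries.

This module is the entry point of the toolkit: it loads an aligned set of
haploid sequences (a single non-recombining mtDNA locus, all records equal
length) together with a sample-to-population map, and provides the per-site
bookkeeping that the downstream statistics are built on: base composition,
classification of sites as invariant / singleton / parsimony-informative,
and screening of reading frames for premature stop codons (the standard
pseudogene/numt sanity check for protein-coding mitochondrial fragments).

Conventions
-----------
* Sequences are normalised to uppercase on input.
* ``N``, ``-`` and any IUPAC ambiguity code other than A/C/G/T are treated
  as missing and masked per site.  The site itself is kept, so the
  coordinate frame of the alignment (e.g. 683 columns for a COI fragment)
  is preserved; whole columns are never deleted.
* Arrays inside the package are 0-based; sites are reported 1-based in all
  tabular output.  Reading frames are given as 0-based offsets (0, 1, 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import (
    AlignmentError,
    ConfigurationError,
    InputError,
    PopulationMapError,
    UndefinedStatisticError,
)

#: Canonical base order used for all integer encodings.
BASES = "ACGT"

#: Integer code for a masked (ambiguous or gap) position.
MISSING = 4

_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@dataclass
class SequenceAlignment:
    """An aligned set of haploid sequences with a population label per record.

    Invariants enforced on construction: at least one record, all sequences
    of identical length, unique record ids.
    """

    ids: tuple[str, ...]
    populations: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.populations = tuple(str(p) for p in self.populations)
        self.sequences = tuple(str(s).upper() for s in self.sequences)
        if len(self.ids) == 0:
            raise InputError("alignment contains no sequences")
        if not (len(self.ids) == len(self.populations) == len(self.sequences)):
            raise AlignmentError("ids, populations and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)} differ"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentError("sequences have zero length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids are not unique")
        self._matrix = np.vstack([encode_sequence(s) for s in self.sequences])

    # -- basic properties ------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of aligned sites (columns)."""
        return len(self.sequences[0])

    @property
    def population_labels(self) -> tuple[str, ...]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return tuple(seen)

    def matrix(self) -> np.ndarray:
        """Integer-coded alignment, shape (n_sequences, length); treat as read-only."""
        return self._matrix

    # -- subsetting ------------------------------------------------------

    def subset(self, population: str) -> "SequenceAlignment":
        """Records belonging to one population ("all" returns self)."""
        if population == "all":
            return self
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise PopulationMapError(f"no sequences for population {population!r}")
        return SequenceAlignment(
            ids=tuple(self.ids[i] for i in idx),
            populations=tuple(self.populations[i] for i in idx),
            sequences=tuple(self.sequences[i] for i in idx),
        )

    # -- output ----------------------------------------------------------

    def write_fasta(self, path: str | Path, wrap: int = 70) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f">{rid}\n")
                if wrap:
                    for i in range(0, len(seq), wrap):
                        fh.write(seq[i : i + wrap] + "\n")
                else:
                    fh.write(seq + "\n")

    def write_popmap(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# id\tpopulation\n")
            for rid, pop in zip(self.ids, self.populations):
                fh.write(f"{rid}\t{pop}\n")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (id, population); '#' comment lines are skipped."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise PopulationMapError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            rid, pop = parts[0].strip(), parts[1].strip()
            if rid in mapping:
                raise PopulationMapError(f"{path}: duplicate id {rid!r}")
            mapping[rid] = pop
    if not mapping:
        raise PopulationMapError(f"{path}: population map is empty")
    return mapping


def read_fasta(path: str | Path, popmap: str | Path | Mapping[str, str]) -> SequenceAlignment:
    """Read an aligned FASTA plus population map into a validated alignment.

    Parameters
    ----------
    path
        FASTA file (wrapped or single-line records).
    popmap
        Path to a 2-column TSV (id, population) or an in-memory mapping.
        Every FASTA id must be present in the map.
    """
    mapping = popmap if isinstance(popmap, Mapping) else read_popmap(popmap)
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(str(record.seq))
    if not ids:
        raise InputError(f"{path}: no FASTA records found")
    missing = [i for i in ids if i not in mapping]
    if missing:
        raise PopulationMapError(
            f"ids missing from population map: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    return SequenceAlignment(
        ids=tuple(ids),
        populations=tuple(mapping[i] for i in ids),
        sequences=tuple(seqs),
    )


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------


def base_composition(aln: SequenceAlignment) -> dict[str, float]:
    """Pooled proportions of A, T, C, G over all unambiguous positions.

    N, gaps and other ambiguity codes are ignored.  The returned fractions
    sum to 1 (within floating-point rounding).
    """
    m = aln.matrix()
    counts = np.bincount(m[m != MISSING], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedStatisticError(
            "base composition undefined: alignment contains no unambiguous bases"
        )
    frac = counts / total
    # report in the conventional A, T, C, G order
    return {"A": frac[0], "T": frac[3], "C": frac[1], "G": frac[2]}


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

INVARIANT = "invariant"
SINGLETON = "singleton"
PARSIMONY_INFORMATIVE = "parsimony_informative"
EXCLUDED = "excluded"


@dataclass
class SiteClassification:
    """Per-site categories plus the usual polymorphism totals.

    ``S = n_singleton + n_parsimony_informative`` and the four categories
    partition the alignment columns.
    """

    categories: np.ndarray  # dtype=str, length L

    @property
    def length(self) -> int:
        return len(self.categories)

    def _count(self, cat: str) -> int:
        return int(np.sum(self.categories == cat))

    @property
    def n_invariant(self) -> int:
        return self._count(INVARIANT)

    @property
    def n_singleton(self) -> int:
        return self._count(SINGLETON)

    @property
    def n_parsimony_informative(self) -> int:
        return self._count(PARSIMONY_INFORMATIVE)

    @property
    def n_excluded(self) -> int:
        return self._count(EXCLUDED)

    @property
    def n_variable(self) -> int:
        """S: total number of variable (segregating) sites."""
        return self.n_singleton + self.n_parsimony_informative

    def variable_sites(self) -> np.ndarray:
        """0-based indices of variable columns."""
        return np.flatnonzero(
            (self.categories == SINGLETON) | (self.categories == PARSIMONY_INFORMATIVE)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"site": np.arange(1, self.length + 1), "category": self.categories}
        )


def classify_sites(aln: SequenceAlignment) -> SiteClassification:
    """Classify every column as invariant / singleton / parsimony-informative / excluded.

    Only unambiguous bases count.  A column with fewer than two unambiguous
    bases is *excluded*; a column with >= 2 distinct bases is variable, and a
    variable column is *parsimony informative* iff at least two bases each
    occur at least twice, otherwise it is a *singleton* site.
    """
    m = aln.matrix()
    counts = np.stack([(m == b).sum(axis=0) for b in range(4)])  # 4 x L
    n_unambiguous = counts.sum(axis=0)
    n_distinct = (counts > 0).sum(axis=0)
    n_repeated = (counts >= 2).sum(axis=0)

    cats = np.full(aln.length, INVARIANT, dtype="<U21")
    excluded = n_unambiguous < 2
    variable = ~excluded & (n_distinct >= 2)
    informative = variable & (n_repeated >= 2)
    cats[excluded] = EXCLUDED
    cats[variable] = SINGLETON
    cats[informative] = PARSIMONY_INFORMATIVE
    return SiteClassification(categories=cats)


def write_site_report(sc: SiteClassification, path: str | Path) -> None:
    """Write the per-site classification as a 2-column TSV (1-based sites)."""
    sc.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reading-frame screening
# ---------------------------------------------------------------------------


def _stop_positions(seq: str, frame: int, stop_codons: frozenset[str]) -> list[int]:
    ungapped = seq.replace("-", "")
    codons = [
        ungapped[i : i + 3]
        for i in range(frame, len(ungapped) - 2, 3)
    ]
    # the final (possibly terminal) codon is not screened
    return [i + 1 for i, c in enumerate(codons[:-1]) if c in stop_codons]


def _stop_table(code: int) -> frozenset[str]:
    try:
        table = unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ConfigurationError(f"unsupported genetic code id: {code}") from exc
    return frozenset(table.stop_codons)


def best_frame(aln: SequenceAlignment, code: int = 5) -> int:
    """Reading frame (0, 1 or 2) minimising the total number of in-frame stops."""
    stops = _stop_table(code)
    totals = [
        sum(len(_stop_positions(s, f, stops)) for s in aln.sequences) for f in (0, 1, 2)
    ]
    return int(np.argmin(totals))


def check_orf(
    aln: SequenceAlignment, frame: int | str = "auto", code: int = 5
) -> dict[str, list[int]]:
    """Screen every sequence for premature in-frame stop codons.

    Parameters
    ----------
    frame
        0-based frame offset, or ``"auto"`` to pick the frame minimising the
        total number of stops across all sequences.
    code
        NCBI genetic code id; default 5 (invertebrate mitochondrial), under
        which AGA/AGG encode serine rather than terminating translation.

    Returns
    -------
    dict mapping sequence id to the 1-based codon indices of stop codons
    occurring before the final codon.  Empty lists everywhere = pass.
    """
    stops = _stop_table(code)
    if frame == "auto":
        frame = best_frame(aln, code)
    if frame not in (0, 1, 2):
        raise ConfigurationError(f"frame must be 0, 1, 2 or 'auto'; got {frame!r}")
    return {
        rid: _stop_positions(seq, frame, stops)
        for rid, seq in zip(aln.ids, aln.sequences)
    }
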