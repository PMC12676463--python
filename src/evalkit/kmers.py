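"""Exact canonical k-mer metrics for graph completeness and duplication.

The duplication metric probes a graph (or any sequence set) with k-mers
drawn from single-copy marker genes. Marker k-mers are first restricted to
those occurring exactly once in every input assembly ("universal unique"
k-mers); the retained probes are then classified in the target as unique
(count 1), multiply occurring (count > 1) or absent (count 0). A well-built
graph keeps most probes unique; duplication inflates the multi fraction and
under-representation inflates the absent fraction.

Counting is exact on canonical k-mers (lexicographic minimum of a window
and its reverse complement), which makes "uniquely mapped" deterministic
and strand-independent. Windows containing N (or any non-ACGT letter) are
skipped. k-mers are counted within records only — junction-spanning k-mers
between graph segments are not generated, which can slightly overstate the
absent fraction for probes straddling a node boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ParameterError
from .seq import revcomp

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _windows(sequence: str, k: int) -> Iterable[str]:
    """Yield all ACGT-only windows of length k (uppercased)."""
    seq = sequence.upper()
    last_bad = -1  # index of the most recent non-ACGT character
    for i, ch in enumerate(seq):
        if ch not in _BASES:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            yield seq[start : i + 1]


@dataclass
class KmerCounter:
    """Exact canonical k-mer counts at a fixed k."""

    k: int
    counts: Counter = field(default_factory=Counter)

    def add_sequence(self, sequence: str) -> None:
        for window in _windows(sequence, self.k):
            self.counts[canonical(window)] += 1

    def count(self, kmer: str) -> int:
        return self.counts[canonical(kmer)]

    def __len__(self) -> int:
        return len(self.counts)


def extract_kmers(sequence: str, k: int) -> KmerCounter:
    """Count canonical k-mers over every clean window of one sequence."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    counter = KmerCounter(k)
    counter.add_sequence(sequence)
    return counter


def count_sequences(sequences: Iterable[str], k: int) -> KmerCounter:
    """Pooled canonical k-mer counts over a collection of sequences."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    counter = KmerCounter(k)
    for seq in sequences:
        counter.add_sequence(seq)
    return counter


@dataclass
class MarkerSet:
    """Named single-copy marker sequences (completeness/duplication probes)."""

    markers: dict[str, str]

    def __len__(self) -> int:
        return len(self.markers)

    def kmers(self, k: int) -> KmerCounter:
        return count_sequences(self.markers.values(), k)


@dataclass
class DuplicationReport:
    """Classification of universal-unique marker k-mers in a target."""

    n_markers: int
    n_kmers_universal_unique: int
    n_unique: int
    n_multi: int
    n_absent: int

    @property
    def fraction_unique(self) -> float:
        return self.n_unique / self.n_kmers_universal_unique

    @property
    def fraction_multi(self) -> float:
        return self.n_multi / self.n_kmers_universal_unique

    @property
    def fraction_absent(self) -> float:
        return self.n_absent / self.n_kmers_universal_unique


def universal_unique_filter(
    marker_kmers: KmerCounter,
    assemblies: list[Iterable[str]],
    k: int | None = None,
) -> set[str]:
    """Marker k-mers occurring exactly once in every input assembly.

    A k-mer absent from any assembly, or present more than once in any
    assembly, is excluded: unique mapping to all genomes requires a single
    occurrence everywhere.
    """
    if not assemblies:
        raise ParameterError("at least one assembly is required")
    k = k if k is not None else marker_kmers.k
    retained = set(marker_kmers.counts)
    for assembly in assemblies:
        counts = count_sequences(assembly, k).counts
        retained = {km for km in retained if counts[km] == 1}
        if not retained:
            break
    return retained


def duplication_report(
    universal_kmers: set[str],
    target: Iterable[str],
    k: int,
    n_markers: int = 0,
) -> DuplicationReport:
    """Classify universal-unique k-mers by their count in the target set."""
    if not universal_kmers:
        raise ParameterError("universal k-mer set is empty; fractions undefined")
    counts = count_sequences(target, k).counts
    n_unique = n_multi = n_absent = 0
    for km in universal_kmers:
        c = counts[km]
        if c == 0:
            n_absent += 1
        elif c == 1:
            n_unique += 1
        else:
            n_multi += 1
    return DuplicationReport(
        n_markers=n_markers,
        n_kmers_universal_unique=len(universal_kmers),
        n_unique=n_unique,
        n_multi=n_multi,
        n_absent=n_absent,
    )


def marker_presence(
    markers: MarkerSet,
    sample_sequence: str,
    k: int = 21,
    presence_threshold: float = 0.8,
) -> dict[str, str]:
    """Call each marker 'present' or 'missing' in one sample sequence.

    A marker is present when at least ``presence_threshold`` of its distinct
    canonical k-mers occur (count >= 1) in the sample. Markers shorter than
    k are skipped with a warning. This is a k-mer containment substitute for
    lifting gene annotations onto a reconstructed assembly.
    """
    if not 0 < presence_threshold <= 1:
        raise ParameterError("presence_threshold must be in (0, 1]")
    sample_kmers = set(extract_kmers(sample_sequence, k).counts)
    calls: dict[str, str] = {}
    for mid, seq in markers.markers.items():
        probe = set(extract_kmers(seq, k).counts)
        if not probe:
            logger.warning("marker %s shorter than k=%d; skipped", mid, k)
            continue
        shared = len(probe & sample_kmers)
        calls[mid] = "present" if shared / len(probe) >= presence_threshold else "missing"
    return calls


def assembly_representation(
    assembly: Iterable[str], path_seq: str, k: int = 21
) -> float:
    """Fraction of an assembly's distinct canonical k-mers found in a path.

    A k-mer containment substitute for alignment-based coverage of an input
    assembly by its reconstruction from the graph; 1.0 means every assembly
    k-mer survives in the path sequence.
    """
    assembly_kmers = set(count_sequences(assembly, k).counts)
    if not assembly_kmers:
        raise ParameterError("assembly yields no k-mers at this k")
    path_kmers = set(extract_kmers(path_seq, k).counts)
    return len(assembly_kmers & path_kmers) / len(assembly_kmers)
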