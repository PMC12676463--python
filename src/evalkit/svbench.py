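"""Truth-vs-call SV benchmarking and multi-callset merging.

Matching follows the conventions of SV benchmarking tools: a call and a
truth record may match when they sit on the same chromosome, have the same
type class (insertion-like vs deletion-like), start within ``refdist``
bases of each other, have size similarity min/max >= ``min_size_sim``, and
— when both alleles carry explicit inserted sequence — sequence similarity
(1 - normalized edit distance) >= ``min_seq_sim``. Records shorter than
``sizemin`` are excluded from both sets before matching. Matching is
one-to-one and greedy in ascending (position distance, size dissimilarity)
order, which equals the optimal assignment on all but adversarial inputs.

A single TP count is reported (each matched pair is one TP), a deliberate
simplification of the separate base/call TP bookkeeping some tools use.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .errors import ParameterError
from .variants import TYPE_CLASS, VariantRecord, VariantSet


@dataclass(frozen=True)
class MatchParams:
    """Matching thresholds; defaults mirror widely used benchmarking defaults."""

    refdist: int = 500
    min_size_sim: float = 0.7
    min_seq_sim: float = 0.7
    sizemin: int = 50

    def __post_init__(self):
        if self.refdist < 0 or self.sizemin < 0:
            raise ParameterError("distances must be >= 0")
        for p in (self.min_size_sim, self.min_seq_sim):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("similarity thresholds must be in [0, 1]")


@dataclass
class BenchResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def size_similarity(a: int, b: int) -> float:
    """min/max ratio of two absolute SV lengths (0 when either is 0)."""
    la, lb = abs(a), abs(b)
    if la == 0 or lb == 0:
        return 1.0 if la == lb else 0.0
    return min(la, lb) / max(la, lb)


def _inserted_seq(rec: VariantRecord) -> str | None:
    """Explicit inserted sequence of an insertion record, if available."""
    alt = rec.alts[0]
    if alt.startswith("<"):
        return None
    if len(alt) > len(rec.ref):
        return alt[len(rec.ref):] if alt.startswith(rec.ref) else alt
    return None


def sequence_similarity(a: str, b: str) -> float:
    """1 - normalized edit distance between two allele sequences."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _compatible(call: VariantRecord, truth: VariantRecord, p: MatchParams) -> tuple | None:
    """Return (pos distance, 1 - size sim) if the pair may match, else None."""
    if call.chrom != truth.chrom:
        return None
    tc, tt = TYPE_CLASS[call.vtype], TYPE_CLASS[truth.vtype]
    if tc != tt or tc in ("SNP", "MNP"):
        return None
    dist = abs(call.pos - truth.pos)
    if dist > p.refdist:
        return None
    ssim = size_similarity(call.svlen, truth.svlen)
    if ssim < p.min_size_sim:
        return None
    if tc == "INS":
        sa, sb = _inserted_seq(call), _inserted_seq(truth)
        if sa is not None and sb is not None:
            if sequence_similarity(sa, sb) < p.min_seq_sim:
                return None
    return (dist, 1.0 - ssim)


def match_sets(
    calls: VariantSet, truth: VariantSet, params: MatchParams = MatchParams()
) -> tuple[BenchResult, dict[str, list[str]]]:
    """Benchmark a call set against a truth set.

    Returns a :class:`BenchResult` and per-record labels: ``labels['calls']``
    holds 'TP'/'FP' per call record (input order, post size filter) and
    ``labels['truth']`` holds 'TP'/'FN' per truth record.
    """
    call_recs = [r for r in calls.records if abs(r.svlen) >= params.sizemin]
    truth_recs = [r for r in truth.records if abs(r.svlen) >= params.sizemin]
    candidates = []
    for ci, c in enumerate(call_recs):
        for ti, t in enumerate(truth_recs):
            key = _compatible(c, t, params)
            if key is not None:
                candidates.append((key, ci, ti))
    candidates.sort(key=lambda x: (x[0], x[1], x[2]))
    call_used = [False] * len(call_recs)
    truth_used = [False] * len(truth_recs)
    tp = 0
    for _, ci, ti in candidates:
        if not call_used[ci] and not truth_used[ti]:
            call_used[ci] = truth_used[ti] = True
            tp += 1
    result = BenchResult(
        tp=tp, fp=call_used.count(False), fn=truth_used.count(False)
    )
    labels = {
        "calls": ["TP" if u else "FP" for u in call_used],
        "truth": ["TP" if u else "FN" for u in truth_used],
    }
    return result, labels


# ---------------------------------------------------------------------------
# Multi-callset merging


@dataclass(frozen=True)
class ClusterParams:
    max_dist: int = 1000
    min_size_sim: float = 0.7
    require_same_type: bool = True


@dataclass
class Cluster:
    """A merged variant: member records tagged by the set they came from."""

    members: list[tuple[str, VariantRecord]] = field(default_factory=list)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(name for name, _ in self.members)


def cluster_multisets(
    sets: dict[str, VariantSet], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """Single-linkage clustering of the union of two or more call sets.

    Two records link when they share a chromosome, lie within ``max_dist``,
    have size similarity >= ``min_size_sim`` and (optionally) the same type
    class. Transitive chains merge, as in distance-based SV mergers.
    """
    if len(sets) < 2:
        raise ParameterError("merging requires at least two call sets")
    tagged = [
        (name, rec) for name, vset in sets.items() for rec in vset.records
    ]
    parent = list(range(len(tagged)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, (_, rec) in enumerate(tagged):
        by_chrom[rec.chrom].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: tagged[i][1].pos)
        for a_pos, i in enumerate(idxs):
            ri = tagged[i][1]
            for j in idxs[a_pos + 1 :]:
                rj = tagged[j][1]
                if rj.pos - ri.pos > params.max_dist:
                    break
                if params.require_same_type and (
                    TYPE_CLASS[ri.vtype] != TYPE_CLASS[rj.vtype]
                ):
                    continue
                if size_similarity(ri.svlen, rj.svlen) < params.min_size_sim:
                    continue
                union(i, j)
    groups: dict[int, Cluster] = defaultdict(Cluster)
    for i, (name, rec) in enumerate(tagged):
        groups[find(i)].members.append((name, rec))
    return list(groups.values())


def intersection_counts(clusters: list[Cluster]) -> dict[frozenset[str], int]:
    """Cluster counts per exact support signature (UpSet-style table)."""
    table: dict[frozenset[str], int] = defaultdict(int)
    for cl in clusters:
        table[cl.support] += 1
    return dict(table)
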