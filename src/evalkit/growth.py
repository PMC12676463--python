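"""Node-coverage histograms and pangenome growth curves.

For a graph with n samples, the growth curve under a (coverage c, quorum q)
threshold reports, for each subset size m = 1..n, the expected number of
nodes (and base pairs) carried by at least t(m) = max(c, ceil(q*m), 1) of a
random m-subset of samples. The conventional threshold pairs are 1/0 (pan),
2/0 (shell), 1/1 (core), 1/0.5 and 1/0.1.

Exact mode computes the expectation in closed form: a node carried by k of
the n samples is counted at subset size m with probability
P[X >= t(m)] where X ~ Hypergeometric(n, k, m). Monte-Carlo mode averages
counts over random orderings of the samples and converges to the exact
curve; it exists mainly as an internal cross-check and for statistics the
closed form does not cover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .errors import ParameterError
from .gfa import PangenomeGraph


@dataclass
class CoverageMap:
    """Per-node distinct-sample coverage for one graph.

    Coverage counts samples, not paths: multiple haplotype paths of one
    sample traversing a node contribute a single unit.
    """

    node_samples: dict[str, frozenset[str]]
    node_lengths: dict[str, int]
    n_samples: int
    samples: list[str]

    @property
    def coverage(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.node_samples.items()}


@dataclass(frozen=True)
class GrowthSpec:
    """A coverage/quorum threshold pair, conventionally written c/q."""

    coverage: int = 1
    quorum: float = 0.0

    def __post_init__(self):
        if self.coverage < 0:
            raise ParameterError("coverage must be >= 0")
        if not 0.0 <= self.quorum <= 1.0:
            raise ParameterError("quorum must be in [0, 1]")

    def threshold(self, m: int) -> int:
        """Required carrier count among m drawn samples (never below 1)."""
        # round() guards ceil against float noise in q*m (e.g. 0.1*3)
        return max(self.coverage, math.ceil(round(self.quorum * m, 9)), 1)

    @classmethod
    def parse(cls, text: str) -> "GrowthSpec":
        """Parse the conventional 'c/q' notation, e.g. '1/0.5'."""
        try:
            c, q = text.split("/")
            return cls(int(c), float(q))
        except ValueError as exc:
            raise ParameterError(f"cannot parse growth spec {text!r}") from exc


#: The five conventional threshold pairs reported for pangenome graphs.
DEFAULT_SPECS = tuple(
    GrowthSpec.parse(s) for s in ("1/0", "2/0", "1/1", "1/0.5", "1/0.1")
)


@dataclass
class GrowthCurve:
    spec: GrowthSpec
    m: list[int]
    expected_nodes: list[float]
    expected_bp: list[float]


def node_sample_coverage(
    graph: PangenomeGraph, exclude_samples: set[str] | None = None
) -> CoverageMap:
    """Distinct-sample coverage of every node.

    ``exclude_samples`` drops reference or scaffold paths from the sample
    universe before counting (haplotypes-only analysis).
    """
    if not graph.paths:
        raise ParameterError("graph has no paths; coverage undefined")
    exclude = exclude_samples or set()
    samples = [s for s in graph.samples if s not in exclude]
    if not samples:
        raise ParameterError("all samples excluded; coverage undefined")
    node_samples: dict[str, set[str]] = {sid: set() for sid in graph.segments}
    for p in graph.paths:
        if p.sample in exclude:
            continue
        for sid, _ in p.steps:
            node_samples[sid].add(p.sample)
    return CoverageMap(
        node_samples={sid: frozenset(s) for sid, s in node_samples.items()},
        node_lengths={sid: len(seg) for sid, seg in graph.segments.items()},
        n_samples=len(samples),
        samples=samples,
    )


def coverage_histogram(cov: CoverageMap) -> dict[int, tuple[int, int]]:
    """Map coverage level -> (node count, total bp), with an explicit 0 bin."""
    hist: dict[int, tuple[int, int]] = {0: (0, 0)}
    for sid, carriers in cov.node_samples.items():
        level = len(carriers)
        n, bp = hist.get(level, (0, 0))
        hist[level] = (n + 1, bp + cov.node_lengths[sid])
    return hist


def growth_curve(
    cov: CoverageMap,
    spec: GrowthSpec,
    mode: str = "exact",
    n_reps: int = 2000,
    seed: int | None = None,
) -> GrowthCurve:
    """Expected qualifying nodes/bp at every subset size m = 1..n."""
    n = cov.n_samples
    if spec.coverage > n and spec.quorum == 0.0:
        warnings.warn(
            f"coverage threshold {spec.coverage} exceeds sample count {n};"
            " curve is identically zero"
        )
    # aggregate nodes by coverage k: multiplicity and bp weight
    count_by_k = np.zeros(n + 1)
    bp_by_k = np.zeros(n + 1)
    for sid, carriers in cov.node_samples.items():
        k = len(carriers)
        count_by_k[k] += 1
        bp_by_k[k] += cov.node_lengths[sid]

    ms = list(range(1, n + 1))
    if mode == "exact":
        exp_nodes, exp_bp = [], []
        for m in ms:
            t = spec.threshold(m)
            ks = np.arange(n + 1)
            # P[X >= t], X ~ Hypergeom(population n, successes k, draws m)
            tail = hypergeom.sf(t - 1, n, ks, m)
            exp_nodes.append(float(tail @ count_by_k))
            exp_bp.append(float(tail @ bp_by_k))
        return GrowthCurve(spec, ms, exp_nodes, exp_bp)

    if mode != "montecarlo":
        raise ParameterError(f"unknown mode {mode!r}")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1 for montecarlo mode")
    if seed is None:
        raise ParameterError("montecarlo mode requires a seed")
    rng = np.random.default_rng(seed)
    index = {s: i for i, s in enumerate(cov.samples)}
    # per node: sorted positions of its carriers under the current ordering
    carrier_idx = [
        (np.array(sorted(index[s] for s in carriers)), cov.node_lengths[sid])
        for sid, carriers in cov.node_samples.items()
        if carriers
    ]
    totals_nodes = np.zeros(n)
    totals_bp = np.zeros(n)
    thresholds = np.array([spec.threshold(m) for m in ms])
    for _ in range(n_reps):
        order = rng.permutation(n)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        for idx, bp in carrier_idx:
            ranks = np.sort(rank[idx])
            # carriers among the first m samples, for each m
            hits = np.searchsorted(ranks, np.arange(1, n + 1), side="left")
            qual = hits >= thresholds
            totals_nodes += qual
            totals_bp += qual * bp
    return GrowthCurve(
        spec, ms, list(totals_nodes / n_reps), list(totals_bp / n_reps)
    )
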