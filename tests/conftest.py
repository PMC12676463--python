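import itertools

import pytest

from evalkit.growth import CoverageMap
from evalkit.synthetic import ClassSpec, SimConfig, simulate
from evalkit.variants import VariantRecord, VariantSet


@pytest.fixture(scope="session")
def bundle():
    """A default-scale synthetic truth bundle shared across tests."""
    return simulate(SimConfig(seed=11))


def tiny_config(seed, n_samples=4, chrom_len=6000, n_chrom=1):
    """A down-scaled simulation config for tests that loop over many seeds."""
    return SimConfig(
        seed=seed,
        n_samples=n_samples,
        n_chrom=n_chrom,
        chrom_len=chrom_len,
        classes={
            "SNP": ClassSpec(5, 1, 1),
            "SMALL_INDEL": ClassSpec(3, 2, 10),
            "DEL": ClassSpec(2, 101, 300),
            "INS": ClassSpec(2, 101, 300),
            "INV": ClassSpec(1, 100, 200),
            "DUP": ClassSpec(1, 100, 200),
        },
        sharing={1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
    )


def brute_force_growth(cov: CoverageMap, spec, weight="nodes"):
    """Average qualifying-node count over ALL m-subsets of samples.

    Exhaustive oracle for the closed-form growth expectation; independent
    of the hypergeometric computation.
    """
    samples = cov.samples
    n = len(samples)
    curve = []
    for m in range(1, n + 1):
        t = spec.threshold(m)
        total = 0.0
        count = 0
        for subset in itertools.combinations(samples, m):
            s = set(subset)
            for sid, carriers in cov.node_samples.items():
                if len(carriers & s) >= t:
                    total += 1 if weight == "nodes" else cov.node_lengths[sid]
            count += 1
        curve.append(total / count)
    return curve


def make_sv(pos, svlen, chrom="chr1", sample="s1", seq=None):
    """An explicit-sequence INS (svlen>0) or DEL (svlen<0) record."""
    if svlen > 0:
        ref, alt = "A", "A" + (seq or "C" * svlen)
    else:
        ref, alt = "A" + "C" * (-svlen), "A"
    return VariantRecord(chrom, pos, ref, (alt,), genotypes={sample: (1,)})


def make_vset(*records):
    return VariantSet(list(records), ["s1"])


def random_sv_set(rng, n=8):
    """A random sorted SV call set with INS/DEL records on two chromosomes."""
    recs = []
    pos = 1
    for _ in range(n):
        pos += int(rng.integers(2000, 9000))
        svlen = int(rng.integers(50, 800)) * (1 if rng.random() < 0.5 else -1)
        recs.append(make_sv(pos, svlen, chrom=f"chr{int(rng.integers(1, 3))}"))
    recs.sort(key=lambda r: (r.chrom, r.pos))
    return make_vset(*recs)


def brute_force_best_tp(calls, truth, params):
    """Maximum one-to-one matching size by exhaustive assignment search.

    Compatibility is re-derived inline (position distance, size-ratio and
    type checks) so the oracle does not share code with the matcher.
    """
    call_recs = [r for r in calls.records if abs(r.svlen) >= params.sizemin]
    truth_recs = [r for r in truth.records if abs(r.svlen) >= params.sizemin]
    pairs = set()
    for i, c in enumerate(call_recs):
        for j, t in enumerate(truth_recs):
            if c.chrom != t.chrom or (c.svlen > 0) != (t.svlen > 0):
                continue
            if abs(c.pos - t.pos) > params.refdist:
                continue
            la, lb = abs(c.svlen), abs(t.svlen)
            if min(la, lb) / max(la, lb) < params.min_size_sim:
                continue
            pairs.add((i, j))
    idx = list(range(len(truth_recs)))
    for m in range(min(len(call_recs), len(truth_recs)), 0, -1):
        for cs in itertools.permutations(range(len(call_recs)), m):
            for ts in itertools.combinations(idx, m):
                if all((c, t) in pairs for c, t in zip(cs, ts)):
                    return m
    return 0


def naive_canonical_count(sequences, kmer):
    """Count occurrences of a k-mer (either strand) in a sequence set by
    direct window scanning — independent of the KmerCounter implementation."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(kmer))
    k = len(kmer)
    total = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if w == kmer or w == rc:
                total += 1
    return total
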