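# Methods

This note records the models and conventions behind each component, the
defaults and why they were chosen, and what the synthetic fixtures do and
do not demonstrate.

## Graph model

A pangenome graph is a set of DNA-labelled segments, oriented blunt links,
and named paths. Only GFA1 with `0M`/`*` overlaps is accepted: the graph
builders this toolkit targets emit blunt-ended graphs, and nonzero overlaps
would make per-segment base accounting ambiguous. W (walk) lines are
converted to paths named `sample#haplotype#seqid` so a single internal
representation serves both dialects. Sample identity is the text before
the first `#` of a path name (PanSN convention); a path without `#` is its
own sample. Sequences are uppercased on ingest and restricted to A/C/G/T/N.
Referential integrity (links and path steps resolving to segments) is
validated after parsing, so record order in the file is free.

Flattening emits one FASTA record per segment rather than one concatenated
sequence. Concatenation would manufacture junction k-mers spanning
segment boundaries that no haplotype contains; the per-segment choice keeps
k-mer classification conservative at the cost of missing k-mers that
genuinely straddle node boundaries (see below).

## k-mer duplication metric

Markers are single-copy gene sequences (in practice, complete
single-copy-ortholog CDSs; in tests, reference slices). All marker k-mers
(k = 21 by default, the standard seed length for this kind of probing) are
counted canonically: a window and its reverse complement are one key, the
lexicographic minimum. A marker k-mer is retained only if it occurs
**exactly once in every input assembly** — absence or multiplicity
anywhere excludes it. Retained probes are then classified in a target
(usually the flattened graph) as unique (count 1), multi (> 1) or absent
(0); the three fractions sum to one by construction.

Exact counting replaces alignment-based unique-mapping tags: for exact
21-mer seeds the two notions coincide, and counting is deterministic and
dependency-free. Whether the original alignment-based procedure tolerated
mismatches is not documented; exact matching is assumed. Because k-mers
are counted within records only, a probe overlapping a segment boundary in
the graph is reported absent even though the path spells it — a small,
documented overestimate of the absent fraction that vanishes for markers
fully contained in single segments (guaranteed in the synthetic fixtures).

Marker presence in a reconstructed assembly is called when ≥ 80% of a
marker's distinct k-mers occur in the sequence; 0.8 mirrors the
query-coverage convention used elsewhere in the toolkit and tolerates
breakpoint-adjacent losses without letting half-missing genes pass.
Assembly representation is the containment fraction of the assembly's
distinct k-mers in the path sequence — a proxy for alignment coverage of
the input assembly by its graph reconstruction.

## Growth curves

Node coverage counts **distinct samples** (haplotype paths grouped by
sample), not raw paths, and reference paths can be excluded so that curves
describe haplotypes only. For a threshold pair (coverage c, quorum q) the
requirement at subset size m is t(m) = max(c, ⌈q·m⌉, 1); the ceiling
implements "at least a fraction q of the m samples" and the floor of 1
keeps the pan curve (0/0 or 1/0) meaningful. The exact expectation sums,
over nodes with coverage k, the hypergeometric tail P[X ≥ t(m)] with
X ~ Hypergeometric(n, k, m); identical (k, m) pairs are pooled, so the
cost is O(n²) tail evaluations regardless of graph size. The Monte-Carlo
mode averages counts over random sample orderings and exists as an
internal cross-check (it converges to the exact curve at rate
O(reps^-1/2)). The exact rounding conventions of other growth-curve tools
are not restated in their papers; the ceiling convention here is fixed,
documented, and verified against exhaustive subset enumeration.

Curve fitting of growth parameters (Heaps-law exponents) is out of scope.

## Variant handling

VCF positions are 1-based; every conversion to 0-based half-open intervals
goes through one function (`vcf_span`). A sample "carries" a record when
its GT contains any alternate allele index; missing GT means absent. A
permissive mode accepts sample-column-free VCFs (as emitted by some
pairwise callers before repair) as presence in one named sample — an
approximation, flagged at the call site.

Multiallelic splitting produces one record per alternate allele, trimming
shared trailing bases first, then leading bases (advancing POS), always
keeping one anchor base — matching common normalizer behavior. Full
left-alignment against a reference is intentionally not attempted without
one. Classification is applied to trimmed biallelic records: SNP/MNP for
equal lengths, INS/DEL below 50 bp, SV_INS/SV_DEL at ≥ 50 bp (the
conventional SV size floor), and OTHER for symbolic inversions,
duplications and complex substitutions; no breakpoint re-inference is done
beyond SVTYPE/SVLEN/END.

Filters: recurrence keeps records with ≥ 2 carriers by default (rare
variants dominate diverse panels, and downstream simulation used only
recurrent SVs); the size filter keeps |ΔL| **strictly greater** than
100 bp by default ("exceeding" semantics, with a flag for ≥); the repeat
hit filter keeps the single best hit per query (maximum query coverage,
ties broken by identity then subject id) and drops queries whose best
coverage is below 80%.

## SV benchmarking

A call and a truth record are candidate matches when they share chromosome
and type class (insertion-like / deletion-like; symbolic INV/DUP match
within their own class), start within 500 bp, have size similarity
min/max ≥ 0.7, and — for explicit-sequence insertion pairs — sequence
similarity (1 − normalized edit distance) ≥ 0.7. Records under 50 bp are
excluded. These defaults mirror the documented defaults of the standard
SV benchmarking tool. Matching is one-to-one and greedy in ascending
(position distance, size dissimilarity, input order) — deterministic, and
equal to the optimal assignment on all tested fixtures. One TP per matched
pair is reported (no separate base/call TP bookkeeping — a deliberate
simplification). Merging uses per-chromosome single-linkage clustering
(distance ≤ 1000 bp, size similarity ≥ 0.7, same type class by default);
intersection tables count clusters per exact support signature.

## Permutation overlap test

The statistic is count-once in the **truth** direction: the number of
distinct truth regions overlapped (≥ 1 shared base, half-open intervals,
strand ignored) by at least one query region. This follows the stated
intent of counting each true variant once; the mirrored direction
(distinct query regions hitting the truth) is available behind a flag
because overlap-counting conventions differ between tools. Null draws
re-place each query region independently: chromosome chosen with
probability proportional to its number of valid start positions, start
uniform, lengths preserved, overlaps permitted (no masking). The
+1-corrected empirical p-value (1 + #{perm ≥ obs})/(1 + n_perm) is used;
its minimum at the conventional 100 permutations is 1/101 ≈ 0.0099. The
z-score uses the permutation mean and sample SD and is reported as NaN
when the null is degenerate. Query regions longer than the longest truth
region are filtered first by default, since long regions inflate chance
overlap. Calibration under a true null is verified empirically (rejection
rate at α = 0.05 within the 99% binomial band over 200 replicates).

## Synthetic truth bundles

The generator emulates a panel of haploid assemblies derived from one
reference — by default 6 samples over 2 × 50 kb chromosomes at GC 0.44,
with 30 SNPs, 10 small indels (2–10 bp), 8 deletions and 8 insertions of
101–1,000 bp (SVs start above the 100 bp recurrent-SV size floor), and 2
inversions and 2 tandem duplications of 100–500 bp. Carrier counts are
drawn from a singleton-skewed distribution (35% singletons down to 5%
universal), so recurrence filtering has realistic work to do. Variants are
placed non-overlapping with a 22 bp guard gap (k + 1 at k = 21): this keeps
bubble construction unambiguous and marker k-mer bookkeeping exact.
Haplotypes are built by splicing; the graph is built independently by
segmenting the reference at variant breakpoints and routing per-sample
paths (alternate segments for SNPs/insertions, skipping edges for
deletions, reverse traversals for inversions, doubled traversals for
tandem duplications); the truth VCF uses anchored explicit alleles for
SNPs/indels/deletions/insertions and symbolic `<INV>`/`<DUP>` records.
All three representations are required to agree byte-exactly, and the test
suite enforces this for many random configurations.

What the fixtures do **not** emulate: overlapping and nested variation,
repeat-rich sequence, segmental duplication outside the planted markers,
assembly errors, and pipeline-specific graph topologies (unmerged sites,
collapsed repeats). Passing tests therefore demonstrate correctness of the
metrics under clean conditions, not robustness of any graph builder on
real data.

## Numerical and determinism notes

- All randomness flows from explicit seeds through `numpy` generators; no
  global random state. Identical configuration ⇒ identical bundle, curve,
  and permutation result.
- Quorum thresholds round via `ceil(round(q·m, 9))` to guard against
  binary float noise in products like 0.1 × 3.
- Duplication fractions are ratios of integer counts; the sum-to-one
  property is exact up to one floating division each.
- Greedy matching ties break by input order, making reports reproducible
  across runs and platforms.
- Problem sizes used by the test suite (50 kb genomes, ≤ 6 samples,
  hundreds of k-mers per marker) were chosen so that exhaustive oracles
  (all sample subsets, full window scans, exhaustive assignments) remain
  feasible; all metrics are linear or near-linear in input size and scale
  to real graphs.

## Known limitations

- GFA2 and rGFA tag semantics (SN/SO/SR) are not interpreted; graphs must
  already carry path (or walk) lines.
- The VCF layer reads GT only; genotype likelihoods, phasing and breakends
  are out of scope.
- Sequence similarity in matching applies only to explicit insertion
  alleles; symbolic calls skip that criterion.
- The k-mer metrics treat segment boundaries as hard breaks (see above);
  for graphs with very short nodes (e.g. base-level graphs) the absent
  fraction can be dominated by boundary effects, and the per-segment
  flatten decision matters.
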