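"""Synthetic variation-graph bundles with exact ground truth.

Generates a random reference genome, implants SNPs, indels and structural
variants (deletions, insertions, inversions, tandem duplications) with a
controlled cross-sample sharing distribution, and emits every downstream
artifact consistently: per-sample haplotype sequences, a truth VCF with
per-sample genotypes, a bubble variation graph with one path per sample
haplotype (plus a reference path), and single-copy marker genes for
k-mer probing.

The default configuration emulates, at desk scale, a panel of six diverged
haploid assemblies built from one reference: SV sizes start above 100 bp
(matching the size filter applied to real call sets before simulation) and
most variants are rare, with a sharing distribution skewed toward
singletons so that a >=2-carrier recurrence filter has something to do.

Variants are placed non-overlapping with a guard gap of k+1 bases so that
bubble construction is unambiguous and marker k-mer bookkeeping is exact;
real assemblies offer no such guarantee, so tests on these bundles probe
correctness of the metrics, not robustness to overlapping variation.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, ParameterError
from .gfa import Link, PangenomeGraph, PathRecord, Segment, write_gfa_file
from .kmers import MarkerSet
from .seq import revcomp, wrap_fasta
from .variants import VariantRecord, VariantSet, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ClassSpec:
    """How many variants of one class to implant and their size range."""

    count: int
    min_size: int
    max_size: int

    def __post_init__(self):
        if self.count < 0 or self.min_size < 1 or self.max_size < self.min_size:
            raise ParameterError(f"invalid class spec {self}")


def _default_classes() -> dict[str, ClassSpec]:
    return {
        "SNP": ClassSpec(30, 1, 1),
        "SMALL_INDEL": ClassSpec(10, 2, 10),
        "DEL": ClassSpec(8, 101, 1000),
        "INS": ClassSpec(8, 101, 1000),
        "INV": ClassSpec(2, 100, 500),
        "DUP": ClassSpec(2, 100, 500),
    }


def _default_sharing() -> dict[int, float]:
    # skewed toward singletons, as observed in diverse real panels
    return {1: 0.35, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.10, 6: 0.05}


@dataclass
class SimConfig:
    n_chrom: int = 2
    chrom_len: int = 50_000
    gc: float = 0.44
    n_samples: int = 6
    classes: dict[str, ClassSpec] = field(default_factory=_default_classes)
    sharing: dict[int, float] = field(default_factory=_default_sharing)
    guard_gap: int = 22  # min spacing between variant footprints (k+1 at k=21)
    seed: int = 0

    def __post_init__(self):
        if self.n_chrom < 1 or self.chrom_len < 100 or self.n_samples < 1:
            raise ParameterError("invalid genome/sample dimensions")
        if not 0.0 <= self.gc <= 1.0:
            raise ParameterError("gc must be in [0, 1]")
        if self.seed is None:
            raise ParameterError("a seed is mandatory")

    @property
    def samples(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class SimVariant:
    """Internal truth record: a replacement on the reference.

    ``start``/``end`` delimit the affected reference interval (0-based,
    half-open; ``start == end`` for insertions). The carried allele is:
    SNP/INS -> ``alt``; DEL -> empty; INV -> reverse complement of the
    interval; DUP -> the interval doubled (tandem).
    """

    vid: str
    chrom: str
    start: int
    end: int
    kind: str  # SNP / INS / DEL / INV / DUP
    alt: str
    carriers: frozenset[str]

    def allele(self, reference: dict[str, str]) -> str:
        region = reference[self.chrom][self.start : self.end]
        if self.kind in ("SNP", "INS"):
            return self.alt
        if self.kind == "DEL":
            return ""
        if self.kind == "INV":
            return revcomp(region)
        if self.kind == "DUP":
            return region * 2
        raise ParameterError(f"unknown variant kind {self.kind!r}")


@dataclass
class TruthBundle:
    """Everything the generator knows about one simulated panel."""

    config: SimConfig
    reference: dict[str, str]
    haplotypes: dict[str, dict[str, str]]  # sample -> chrom -> sequence
    variants: list[SimVariant]
    truth: VariantSet
    graph: PangenomeGraph
    markers: MarkerSet
    marker_positions: dict[str, tuple[str, int]]  # marker id -> (chrom, start)

    def path_name(self, sample: str, chrom: str) -> str:
        return f"{sample}#1#{chrom}"


# ---------------------------------------------------------------------------


def simulate_reference(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Random reference genome with the configured GC content."""
    gc = config.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": "".join(
            _BASES[rng.choice(4, size=config.chrom_len, p=probs)]
        )
        for i in range(config.n_chrom)
    }


def _place_interval(
    rng: np.random.Generator,
    reference: dict[str, str],
    span: int,
    occupied: dict[str, list[tuple[int, int]]],
    gap: int,
    max_tries: int = 2000,
) -> tuple[str, int]:
    """Pick a (chrom, start) for an interval of reference span ``span``.

    Keeps at least ``gap`` bases clear of every existing interval and of
    the chromosome ends (so an anchor base always exists upstream).
    """
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    for _ in range(max_tries):
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        hi = len(reference[chrom]) - gap - span
        if hi <= gap:
            continue
        start = int(rng.integers(gap, hi))
        end = start + span
        if all(
            start >= e + gap or end + gap <= s for s, e in occupied[chrom]
        ):
            occupied[chrom].append((start, end))
            return chrom, start
    raise CapacityError(
        f"could not place an interval of span {span}; genome too small or too full"
    )


def _draw_carriers(
    rng: np.random.Generator, config: SimConfig
) -> frozenset[str]:
    counts = [c for c in sorted(config.sharing) if 1 <= c <= config.n_samples]
    if not counts:
        raise ParameterError("sharing distribution has no usable carrier counts")
    weights = np.array([config.sharing[c] for c in counts], dtype=float)
    k = int(rng.choice(counts, p=weights / weights.sum()))
    chosen = rng.choice(config.n_samples, size=k, replace=False)
    return frozenset(config.samples[i] for i in chosen)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def implant_variants(
    reference: dict[str, str], config: SimConfig, rng: np.random.Generator
) -> list[SimVariant]:
    """Draw non-overlapping variants of every configured class."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in reference}
    variants: list[SimVariant] = []
    vid = 0
    for cls_name, spec in config.classes.items():
        for _ in range(spec.count):
            size = int(rng.integers(spec.min_size, spec.max_size + 1))
            if cls_name == "SNP":
                kind, span = "SNP", 1
            elif cls_name == "SMALL_INDEL":
                kind = "INS" if rng.random() < 0.5 else "DEL"
                span = 0 if kind == "INS" else size
            elif cls_name == "INS":
                kind, span = "INS", 0
            else:  # DEL / INV / DUP
                kind, span = cls_name, size
            chrom, start = _place_interval(
                rng, reference, span, occupied, config.guard_gap
            )
            end = start + span
            if kind == "SNP":
                ref_base = reference[chrom][start]
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            elif kind == "INS":
                alt = _random_seq(rng, size)
            else:
                alt = ""
            vid += 1
            variants.append(
                SimVariant(
                    vid=f"v{vid}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    kind=kind,
                    alt=alt,
                    carriers=_draw_carriers(rng, config),
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.start))
    return variants


def build_haplotype(
    reference: dict[str, str], variants: list[SimVariant], sample: str, chrom: str
) -> str:
    """Splice the variants carried by one sample into one chromosome."""
    chunks = []
    cursor = 0
    seq = reference[chrom]
    for v in sorted(
        (v for v in variants if v.chrom == chrom and sample in v.carriers),
        key=lambda v: v.start,
    ):
        chunks.append(seq[cursor : v.start])
        chunks.append(v.allele(reference))
        cursor = v.end
    chunks.append(seq[cursor:])
    return "".join(chunks)


def truth_variant_set(
    reference: dict[str, str], variants: list[SimVariant], config: SimConfig
) -> VariantSet:
    """Express the internal truth as VCF records.

    SNPs and indels use explicit anchored alleles; inversions and tandem
    duplications use symbolic <INV>/<DUP> with SVTYPE, SVLEN and END.
    """
    samples = config.samples
    records = []
    for v in variants:
        seq = reference[v.chrom]
        genotypes = {s: ((1,) if s in v.carriers else (0,)) for s in samples}
        if v.kind == "SNP":
            rec = VariantRecord(
                v.chrom, v.start + 1, seq[v.start], (v.alt,), id=v.vid,
                genotypes=genotypes,
            )
        elif v.kind == "INS":
            anchor = seq[v.start - 1]
            rec = VariantRecord(
                v.chrom, v.start, anchor, (anchor + v.alt,), id=v.vid,
                info={"SVTYPE": "INS", "SVLEN": len(v.alt)} if len(v.alt) >= 50 else {},
                genotypes=genotypes,
            )
        elif v.kind == "DEL":
            anchor = seq[v.start - 1]
            rec = VariantRecord(
                v.chrom, v.start, anchor + seq[v.start : v.end], (anchor,), id=v.vid,
                info={"SVTYPE": "DEL", "SVLEN": -(v.end - v.start)}
                if v.end - v.start >= 50 else {},
                genotypes=genotypes,
            )
        else:  # INV / DUP, symbolic
            rec = VariantRecord(
                v.chrom, v.start, seq[v.start - 1], (f"<{v.kind}>",), id=v.vid,
                info={"SVTYPE": v.kind, "SVLEN": v.end - v.start, "END": v.end},
                genotypes=genotypes,
            )
        records.append(rec)
    contigs = {c: len(s) for c, s in reference.items()}
    vset = VariantSet(records, samples, contigs)
    vset.sort()
    return vset


def build_bubble_graph(
    reference: dict[str, str],
    variants: list[SimVariant],
    samples: list[str],
    reference_sample: str = "ref",
) -> PangenomeGraph:
    """Segment the reference at variant breakpoints and route per-sample paths.

    Each variant forms a bubble: an alternate segment for SNPs and
    insertions, a skipping edge for deletions, a reverse-orientation
    traversal for inversions and a doubled traversal for tandem
    duplications. One path is emitted per sample per chromosome, plus a
    reference path, all in PanSN naming.
    """
    graph = PangenomeGraph()
    next_id = 1

    def new_segment(seq: str) -> str:
        nonlocal next_id
        sid = str(next_id)
        next_id += 1
        graph.segments[sid] = Segment(sid, seq)
        return sid

    for chrom in reference:
        seq = reference[chrom]
        chrom_vars = [v for v in variants if v.chrom == chrom]
        breaks = sorted({0, len(seq)} | {v.start for v in chrom_vars}
                        | {v.end for v in chrom_vars})
        backbone: list[tuple[int, int, str]] = []
        for s, e in zip(breaks, breaks[1:]):
            backbone.append((s, e, new_segment(seq[s:e])))
        by_interval = {(v.start, v.end): v for v in chrom_vars}
        ins_at = {v.start: v for v in chrom_vars if v.kind == "INS"}
        alt_seg: dict[str, str] = {}
        for v in chrom_vars:
            if v.kind in ("SNP", "INS"):
                alt_seg[v.vid] = new_segment(v.alt)

        def steps_for(carried: set[str]) -> list[tuple[str, str]]:
            steps: list[tuple[str, str]] = []
            for s, e, sid in backbone:
                ins = ins_at.get(s)
                if ins is not None and ins.vid in carried:
                    steps.append((alt_seg[ins.vid], "+"))
                v = by_interval.get((s, e))
                if v is not None and v.vid in carried:
                    if v.kind == "SNP":
                        steps.append((alt_seg[v.vid], "+"))
                    elif v.kind == "DEL":
                        pass
                    elif v.kind == "INV":
                        steps.append((sid, "-"))
                    elif v.kind == "DUP":
                        steps.extend([(sid, "+"), (sid, "+")])
                else:
                    steps.append((sid, "+"))
            return steps

        graph.paths.append(
            PathRecord(f"{reference_sample}#0#{chrom}", steps_for(set()))
        )
        for sample in samples:
            carried = {v.vid for v in chrom_vars if sample in v.carriers}
            graph.paths.append(PathRecord(f"{sample}#1#{chrom}", steps_for(carried)))

    for p in graph.paths:
        for (a, ao), (b, bo) in zip(p.steps, p.steps[1:]):
            graph.links.add(Link(a, ao, b, bo))
    graph.validate()
    return graph


def implant_markers(
    reference: dict[str, str],
    variants: list[SimVariant],
    rng: np.random.Generator,
    n_markers: int = 4,
    marker_len: int = 300,
    guard_gap: int = 22,
) -> tuple[MarkerSet, dict[str, tuple[str, int]]]:
    """Pick single-copy marker genes from variant-free reference windows.

    Each marker is a reference slice far enough from every variant that it
    survives unmodified in every haplotype — the synthetic analogue of
    complete, single-copy ortholog CDS probes.
    """
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in reference}
    for v in variants:
        occupied[v.chrom].append((v.start, v.end))
    markers: dict[str, str] = {}
    positions: dict[str, tuple[str, int]] = {}
    for i in range(n_markers):
        chrom, start = _place_interval(
            rng, reference, marker_len, occupied, guard_gap
        )
        mid = f"marker{i + 1:02d}"
        markers[mid] = reference[chrom][start : start + marker_len]
        positions[mid] = (chrom, start)
    return MarkerSet(markers), positions


def simulate(config: SimConfig) -> TruthBundle:
    """Generate a complete, internally consistent truth bundle."""
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    variants = implant_variants(reference, config, rng)
    haplotypes = {
        sample: {
            chrom: build_haplotype(reference, variants, sample, chrom)
            for chrom in reference
        }
        for sample in config.samples
    }
    truth = truth_variant_set(reference, variants, config)
    graph = build_bubble_graph(reference, variants, config.samples)
    markers, positions = implant_markers(
        reference, variants, rng, guard_gap=config.guard_gap
    )
    return TruthBundle(
        config=config,
        reference=reference,
        haplotypes=haplotypes,
        variants=variants,
        truth=truth,
        graph=graph,
        markers=markers,
        marker_positions=positions,
    )


def duplicated_target(bundle: TruthBundle, plan: dict[str, int]) -> list[str]:
    """Flattened graph segments plus extra marker copies per the plan.

    ``plan`` maps marker id -> number of EXTRA tandem copies appended as
    additional records; used to plant known duplication into a target.
    """
    target = [seg.sequence for seg in bundle.graph.segments.values()]
    for mid, extra in plan.items():
        target.extend([bundle.markers.markers[mid]] * extra)
    return target


# ---------------------------------------------------------------------------
# On-disk bundle


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{wrap_fasta(seq)}")


def write_bundle(bundle: TruthBundle, outdir) -> None:
    """Write reference.fa, samples/*.fa, truth.vcf, graph.gfa, markers.fa,
    and config.json under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(bundle.reference, os.path.join(outdir, "reference.fa"))
    sampledir = os.path.join(outdir, "samples")
    os.makedirs(sampledir, exist_ok=True)
    for sample, chroms in bundle.haplotypes.items():
        write_fasta(
            {bundle.path_name(sample, chrom): seq for chrom, seq in chroms.items()},
            os.path.join(sampledir, f"{sample}.fa"),
        )
    write_vcf(bundle.truth, os.path.join(outdir, "truth.vcf"))
    write_gfa_file(bundle.graph, os.path.join(outdir, "graph.gfa"))
    write_fasta(bundle.markers.markers, os.path.join(outdir, "markers.fa"))
    cfg = dataclasses.asdict(bundle.config)
    cfg["classes"] = {k: dataclasses.asdict(v) for k, v in bundle.config.classes.items()}
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
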