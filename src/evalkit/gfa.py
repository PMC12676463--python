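"""GFA1 pangenome graph model.

Parses, validates, writes and summarizes blunt-ended GFA1 variation graphs
(S/L/P lines, with W walk lines translated to paths), reconstructs haplotype
sequences from named paths, and flattens graphs to per-segment FASTA records.

Only blunt overlaps (``0M`` or ``*``) are accepted: the graph builders this
toolkit evaluates emit blunt-ended graphs, and nonzero overlaps would make
per-segment base counts ambiguous.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError
from .seq import VALID_DNA, natural_key, revcomp

logger = logging.getLogger(__name__)

ORIENTATIONS = ("+", "-")


@dataclass
class Segment:
    """A graph node carrying a DNA sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Link:
    """A directed, oriented edge between two segments (blunt overlap)."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: str = "0M"


@dataclass
class PathRecord:
    """A named walk through the graph; one per haplotype/assembly.

    Path names follow the PanSN convention ``sample#haplotype#chrom`` where
    available; the sample name is the text before the first ``#``, or the
    whole name if there is none.
    """

    name: str
    steps: list[tuple[str, str]]  # (segment id, orientation)

    @property
    def sample(self) -> str:
        return self.name.split("#", 1)[0]


@dataclass
class PangenomeGraph:
    """Segments, links and named paths of one pangenome variation graph."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[Link] = field(default_factory=set)
    paths: list[PathRecord] = field(default_factory=list)

    def path(self, name: str) -> PathRecord:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(f"no path named {name!r} in graph")

    @property
    def samples(self) -> list[str]:
        """Distinct sample names in path order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.paths:
            seen.setdefault(p.sample)
        return list(seen)

    def validate(self) -> None:
        """Raise IntegrityError if a link or path step dangles."""
        for link in self.links:
            for sid in (link.from_id, link.to_id):
                if sid not in self.segments:
                    raise IntegrityError(f"link references unknown segment {sid!r}")
        for p in self.paths:
            if not p.steps:
                raise IntegrityError(f"path {p.name!r} has no steps")
            for sid, _ in p.steps:
                if sid not in self.segments:
                    raise IntegrityError(
                        f"path {p.name!r} references unknown segment {sid!r}"
                    )


@dataclass
class GraphStats:
    n_segments: int
    n_links: int
    n_paths: int
    total_bp: int
    mean_segment_len: float
    min_segment_len: int
    max_segment_len: int


def _clean_sequence(raw: str, lineno: int) -> str:
    seq = raw.upper()
    if not seq or seq == "*":
        raise FormatError(f"line {lineno}: segment without an explicit sequence")
    bad = set(seq) - VALID_DNA
    if bad:
        raise FormatError(
            f"line {lineno}: invalid sequence character(s) {sorted(bad)!r}"
        )
    return seq


def _parse_walk(walk: str, lineno: int) -> list[tuple[str, str]]:
    """Split a W-line walk string ``>s1<s2...`` into oriented steps."""
    steps: list[tuple[str, str]] = []
    token = ""
    orient = ""
    for ch in walk:
        if ch in "><":
            if token:
                steps.append((token, orient))
            orient = "+" if ch == ">" else "-"
            token = ""
        else:
            token += ch
    if token:
        steps.append((token, orient))
    if not steps or any(o == "" for _, o in steps):
        raise FormatError(f"line {lineno}: malformed walk string {walk!r}")
    return steps


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def parse_gfa(source) -> PangenomeGraph:
    """Parse GFA1 text into a :class:`PangenomeGraph`.

    ``source`` may be a file path, an open text handle, or an iterable of
    lines. H/S/L/P lines are recognized; W lines are converted to equivalent
    paths; other record types are skipped with a warning. Referential
    integrity is checked after the whole stream is consumed, so link/path
    lines may precede the segments they mention.
    """
    graph = PangenomeGraph()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: S line needs 3 fields")
            sid = fields[1]
            if not sid:
                raise FormatError(f"line {lineno}: empty segment id")
            if sid in graph.segments:
                raise FormatError(f"line {lineno}: duplicate segment id {sid!r}")
            graph.segments[sid] = Segment(sid, _clean_sequence(fields[2], lineno))
        elif tag == "L":
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: L line needs 6 fields")
            fo, to, overlap = fields[2], fields[4], fields[5]
            if fo not in ORIENTATIONS or to not in ORIENTATIONS:
                raise FormatError(f"line {lineno}: bad orientation in L line")
            if overlap not in ("0M", "*"):
                raise FormatError(
                    f"line {lineno}: only blunt overlaps (0M/*) are supported,"
                    f" got {overlap!r}"
                )
            graph.links.add(Link(fields[1], fo, fields[3], to, overlap))
        elif tag == "P":
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: P line needs 3 fields")
            steps = []
            for step in fields[2].split(","):
                if len(step) < 2 or step[-1] not in ORIENTATIONS:
                    raise FormatError(f"line {lineno}: malformed path step {step!r}")
                steps.append((step[:-1], step[-1]))
            graph.paths.append(PathRecord(fields[1], steps))
        elif tag == "W":
            if len(fields) < 7:
                raise FormatError(f"line {lineno}: W line needs 7 fields")
            name = f"{fields[1]}#{fields[2]}#{fields[3]}"
            graph.paths.append(PathRecord(name, _parse_walk(fields[6], lineno)))
        else:
            logger.warning("line %d: skipping unsupported record type %r", lineno, tag)
    graph.validate()
    return graph


def parse_gfa_text(text: str) -> PangenomeGraph:
    """Parse GFA1 from an in-memory string."""
    return parse_gfa(io.StringIO(text))


def write_gfa(graph: PangenomeGraph) -> str:
    """Serialize a graph to GFA1 text (deterministic field and record order)."""
    out = ["H\tVN:Z:1.0"]
    for sid in sorted(graph.segments, key=natural_key):
        out.append(f"S\t{sid}\t{graph.segments[sid].sequence}")
    for link in sorted(
        graph.links,
        key=lambda l: (natural_key(l.from_id), l.from_orient, natural_key(l.to_id), l.to_orient),
    ):
        out.append(
            f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t{link.to_orient}\t0M"
        )
    for p in graph.paths:
        steps = ",".join(f"{sid}{o}" for sid, o in p.steps)
        out.append(f"P\t{p.name}\t{steps}\t*")
    return "\n".join(out) + "\n"


def write_gfa_file(graph: PangenomeGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_gfa(graph))


def graph_stats(graph: PangenomeGraph) -> GraphStats:
    """Node/edge/path counts and segment-length summary."""
    lengths = [len(s) for s in graph.segments.values()]
    total = sum(lengths)
    return GraphStats(
        n_segments=len(lengths),
        n_links=len(graph.links),
        n_paths=len(graph.paths),
        total_bp=total,
        mean_segment_len=total / len(lengths) if lengths else 0.0,
        min_segment_len=min(lengths) if lengths else 0,
        max_segment_len=max(lengths) if lengths else 0,
    )


def path_sequence(graph: PangenomeGraph, path_name: str) -> str:
    """Spell out the DNA sequence of a named path.

    Segment sequences are concatenated in step order; segments traversed
    with ``-`` orientation contribute their reverse complement.
    """
    p = graph.path(path_name)
    parts = []
    for sid, orient in p.steps:
        seq = graph.segments[sid].sequence
        parts.append(seq if orient == "+" else revcomp(seq))
    return "".join(parts)


def flatten(graph: PangenomeGraph) -> list[SeqRecord]:
    """One FASTA record per segment, natural-sorted by id.

    Per-segment records (rather than one concatenated sequence) avoid
    creating spurious k-mers across segment junctions that no haplotype
    contains.
    """
    return [
        SeqRecord(Seq(graph.segments[sid].sequence), id=sid, description="")
        for sid in sorted(graph.segments, key=natural_key)
    ]
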