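"""Variant model: VCF ingest/emit, normalization, classification, filters.

Implements the filtering rules applied to pangenome call sets before
benchmarking: multiallelic splitting with allele trimming, the >=2-carrier
recurrence rule, the >100 bp size rule, and the top-hit / >=80%
query-coverage rule for repeat classification tables. Also provides the
allele-application routine used to verify that a truth VCF reconstructs
the haplotypes it was derived from.

Positions are 1-based as in VCF; all conversions to 0-based half-open
coordinates go through :func:`vcf_span`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pysam

from .errors import FormatError, ParameterError
from .seq import revcomp

SV_THRESHOLD = 50  # bp; alleles this long or longer are structural variants

_SYMBOLIC_TYPES = {"<INS>": "INS", "<DEL>": "DEL", "<INV>": "INV", "<DUP>": "DUP"}


@dataclass
class VariantRecord:
    """One VCF record (possibly multiallelic) with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    id: str = "."
    info: dict = field(default_factory=dict)  # SVTYPE / SVLEN / END
    genotypes: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise FormatError("REF allele must be nonempty")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_symbolic(self) -> bool:
        return any(a.startswith("<") for a in self.alts)

    @property
    def end(self) -> int:
        """1-based inclusive end: INFO END for symbolic alleles, else REF span."""
        if "END" in self.info:
            return int(self.info["END"])
        return self.pos + len(self.ref) - 1

    @property
    def svlen(self) -> int:
        """Signed length change (alt minus ref); requires a biallelic record."""
        if not self.is_biallelic:
            raise ParameterError("svlen undefined for multiallelic records; split first")
        alt = self.alts[0]
        if alt.startswith("<"):
            if "SVLEN" in self.info:
                v = self.info["SVLEN"]
                return int(v[0] if isinstance(v, (tuple, list)) else v)
            span = self.end - self.pos + 1 if "END" in self.info else None
            if span is None:
                raise FormatError(f"symbolic allele {alt} without SVLEN or END")
            return -span if alt == "<DEL>" else span
        return len(alt) - len(self.ref)

    @property
    def presence(self) -> dict[str, int]:
        """sample -> 1 if the genotype carries any alternate allele."""
        return {
            s: int(any(a is not None and a >= 1 for a in gt))
            for s, gt in self.genotypes.items()
        }

    @property
    def n_carriers(self) -> int:
        return sum(self.presence.values())

    @property
    def vtype(self) -> str:
        return classify(self)


@dataclass
class VariantSet:
    """An ordered collection of records over a fixed sample list."""

    records: list[VariantRecord]
    samples: list[str]
    contigs: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r.chrom, r.pos))


def vcf_span(record: VariantRecord) -> tuple[str, int, int]:
    """0-based half-open genomic span affected by a record.

    For symbolic alleles the span is the event region after the anchor base
    (POS+1 .. END, 1-based); for sequence alleles it is the REF footprint.
    """
    if record.is_symbolic:
        return record.chrom, record.pos, record.end
    return record.chrom, record.pos - 1, record.pos - 1 + len(record.ref)


# ---------------------------------------------------------------------------
# VCF input / output (pysam-backed)

_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Signed length difference">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def parse_vcf(path, permissive_sample: str | None = None) -> VariantSet:
    """Read a VCF 4.x file into a :class:`VariantSet`.

    GT is the only FORMAT field interpreted; INFO SVTYPE/SVLEN/END are
    honored for symbolic alleles. If the file carries no sample columns and
    ``permissive_sample`` is given, every record is treated as present in
    that single sample (an accommodation for pairwise callers that omit
    FORMAT/sample columns). Unsorted input is sorted with a warning.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        contigs = {
            name: c.length for name, c in vf.header.contigs.items() if c.length
        } or None
        records = []
        for rec in vf:
            if rec.alts is None:
                continue
            info = {}
            if "SVTYPE" in rec.info:
                info["SVTYPE"] = str(rec.info["SVTYPE"])
            if "SVLEN" in rec.info:
                v = rec.info["SVLEN"]
                info["SVLEN"] = (
                    tuple(int(x) for x in v) if isinstance(v, (tuple, list)) else int(v)
                )
            if any(a.startswith("<") for a in rec.alts):
                info["END"] = rec.stop  # pysam stop is 0-based exclusive == 1-based END
            genotypes = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                genotypes[s] = tuple(gt) if gt is not None else (None,)
            if not samples and permissive_sample is not None:
                genotypes = {permissive_sample: (1,)}
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    id=rec.id or ".",
                    info=info,
                    genotypes=genotypes,
                )
            )
    if not samples and permissive_sample is not None:
        samples = [permissive_sample]
    keys = [(r.chrom, r.pos) for r in records]
    vset = VariantSet(records, samples, contigs)
    if keys != sorted(keys):
        warnings.warn(f"VCF {path} is unsorted; sorting records")
        vset.sort()
    return vset


def write_vcf(vset: VariantSet, path) -> None:
    """Write a :class:`VariantSet` as uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    for line in _HEADER_LINES:
        header.add_line(line)
    chroms = dict(vset.contigs or {})
    for r in vset.records:
        chroms.setdefault(r.chrom, None)
    for name, length in chroms.items():
        header.contigs.add(name, length=length)
    for s in vset.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in vset.records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.end,
                alleles=(r.ref,) + r.alts,
                id=None if r.id == "." else r.id,
            )
            rec.filter.add("PASS")
            if "SVTYPE" in r.info:
                rec.info["SVTYPE"] = r.info["SVTYPE"]
            if "SVLEN" in r.info:
                v = r.info["SVLEN"]
                rec.info["SVLEN"] = v if isinstance(v, tuple) else (v,)
            for s in vset.samples:
                rec.samples[s]["GT"] = r.genotypes.get(s, (None,))
            out.write(rec)


# ---------------------------------------------------------------------------
# Normalization and classification


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared flanking bases from a ref/alt pair.

    Trims shared trailing bases first, then shared leading bases (advancing
    pos), always keeping at least one base per allele — the behavior of
    common VCF normalizers.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a record into one trimmed biallelic record per alternate allele.

    Genotypes are re-coded per split allele: a sample's allele index equal
    to the split allele becomes 1, any other non-missing allele 0. Per-allele
    SVLEN/SVTYPE INFO values are distributed to their records.
    """
    if record.is_biallelic and not _shares_flank(record.ref, record.alts[0]):
        return [record]
    out = []
    svlen = record.info.get("SVLEN")
    svtype = record.info.get("SVTYPE")
    for i, alt in enumerate(record.alts):
        info = {}
        if svlen is not None:
            info["SVLEN"] = svlen[i] if isinstance(svlen, tuple) else svlen
        if svtype is not None:
            info["SVTYPE"] = svtype
        if "END" in record.info:
            info["END"] = record.info["END"]
        if alt.startswith("<"):
            pos, ref, new_alt = record.pos, record.ref, alt
        else:
            pos, ref, new_alt = trim_alleles(record.pos, record.ref, alt)
            info.pop("END", None)  # REF span defines the end after trimming
        genotypes = {
            s: tuple(
                None if a is None else int(a == i + 1) for a in gt
            )
            for s, gt in record.genotypes.items()
        }
        out.append(
            VariantRecord(
                chrom=record.chrom,
                pos=pos,
                ref=ref,
                alts=(new_alt,),
                id=record.id,
                info=info,
                genotypes=genotypes,
            )
        )
    return out


def _shares_flank(ref: str, alt: str) -> bool:
    if alt.startswith("<") or (len(ref) == 1 and len(alt) == 1):
        return False
    return (len(ref) > 1 and len(alt) > 1) and (ref[-1] == alt[-1] or ref[0] == alt[0])


def classify(record: VariantRecord, sv_threshold: int = SV_THRESHOLD) -> str:
    """Variant type of a biallelic record.

    SNP (1 bp substitution), MNP (multi-base equal-length substitution),
    INS/DEL (length change below ``sv_threshold``), SV_INS/SV_DEL (at or
    above it), OTHER (inversions, duplications and complex alleles).
    """
    if not record.is_biallelic:
        raise ParameterError("classify requires a biallelic record; split first")
    alt = record.alts[0]
    if alt.startswith("<"):
        base = _SYMBOLIC_TYPES.get(alt, "OTHER")
        if base == "INS":
            return "SV_INS" if abs(record.svlen) >= sv_threshold else "INS"
        if base == "DEL":
            return "SV_DEL" if abs(record.svlen) >= sv_threshold else "DEL"
        return "OTHER"
    if record.info.get("SVTYPE") in ("INV", "DUP", "CPX", "BND"):
        return "OTHER"
    _, ref, a = trim_alleles(record.pos, record.ref, alt)
    if len(ref) == len(a):
        return "SNP" if len(ref) == 1 else "MNP"
    if len(ref) > 1 and len(a) > 1:
        return "OTHER"  # complex substitution
    delta = len(a) - len(ref)
    if delta > 0:
        return "SV_INS" if delta >= sv_threshold else "INS"
    return "SV_DEL" if -delta >= sv_threshold else "DEL"


TYPE_CLASS = {
    "SNP": "SNP",
    "MNP": "MNP",
    "INS": "INS",
    "SV_INS": "INS",
    "DEL": "DEL",
    "SV_DEL": "DEL",
    "OTHER": "OTHER",
}


def count_multiallelic(vset: VariantSet) -> int:
    """Number of sites carrying two or more alternate alleles."""
    return sum(1 for r in vset.records if len(r.alts) >= 2)


# ---------------------------------------------------------------------------
# Filters


def recurrence_filter(vset: VariantSet, min_samples: int = 2) -> VariantSet:
    """Keep variants present in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    kept = [r for r in vset.records if r.n_carriers >= min_samples]
    return VariantSet(kept, vset.samples, vset.contigs)


def size_filter(
    vset: VariantSet, min_len: int = 100, strict_greater: bool = True
) -> VariantSet:
    """Keep variants whose absolute length change exceeds ``min_len`` bp."""
    kept = []
    for r in vset.records:
        size = abs(r.svlen)
        if size > min_len or (not strict_greater and size == min_len):
            kept.append(r)
    return VariantSet(kept, vset.samples, vset.contigs)


@dataclass(frozen=True)
class HitRow:
    """One alignment hit from a tabular search report."""

    query: str
    subject: str
    pct_identity: float
    query_coverage: float
    extra: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.query_coverage <= 100.0:
            raise FormatError(
                f"query coverage must be in [0, 100], got {self.query_coverage}"
            )


def read_hit_table(path, qcov_col: int = -1) -> list[HitRow]:
    """Read a tab-separated alignment hit table.

    Columns 1-3 are query id, subject id and percent identity as in the
    standard 12-column tabular alignment format; query coverage is taken
    from ``qcov_col`` (default: the last column, as produced by appending a
    coverage column to the standard format). Extra columns are carried
    through untouched.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"hit table line {lineno}: fewer than 4 columns")
            rows.append(
                HitRow(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    query_coverage=float(parts[qcov_col]),
                    extra=tuple(parts[3:]),
                )
            )
    return rows


def repeat_hit_filter(
    hits: list[HitRow], min_qcov: float = 80.0
) -> dict[str, HitRow]:
    """Best hit per query, keeping queries with coverage >= ``min_qcov``.

    The best hit maximizes query coverage, breaking ties by higher percent
    identity and then lexicographically smaller subject id.
    """
    best: dict[str, HitRow] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None or (
            (hit.query_coverage, hit.pct_identity, _neg_lex(hit.subject))
            > (cur.query_coverage, cur.pct_identity, _neg_lex(cur.subject))
        ):
            best[hit.query] = hit
    return {q: h for q, h in best.items() if h.query_coverage >= min_qcov}


def _neg_lex(s: str) -> tuple:
    """Key making lexicographically smaller strings compare greater."""
    return tuple(-b for b in s.encode())


# ---------------------------------------------------------------------------
# Allele application (truth verification)


def apply_variants(
    reference: dict[str, str], vset: VariantSet, sample: str
) -> dict[str, str]:
    """Apply every variant carried by ``sample`` to the reference.

    Records must be non-overlapping. Sequence alleles are spliced in place;
    symbolic <DEL>/<INV>/<DUP> records act on their POS+1..END region
    (deletion, reverse complement, tandem doubling). REF alleles are
    checked against the reference and a mismatch raises FormatError. This
    is the verification route proving a truth VCF reconstructs the
    haplotypes it describes.
    """
    edits: dict[str, list[tuple[int, int, str]]] = {c: [] for c in reference}
    for r in vset.records:
        if r.presence.get(sample, 0) != 1:
            continue
        if not r.is_biallelic:
            raise ParameterError("apply_variants requires biallelic records")
        alt = r.alts[0]
        chrom = r.chrom
        if chrom not in reference:
            raise FormatError(f"record on unknown contig {r.chrom!r}")
        if alt.startswith("<"):
            start, end = r.pos, r.end  # 0-based event region [POS, END)
            region = reference[chrom][start:end]
            if alt == "<DEL>":
                repl = ""
            elif alt == "<INV>":
                repl = revcomp(region)
            elif alt == "<DUP>":
                repl = region * 2
            else:
                raise ParameterError(f"cannot apply symbolic allele {alt}")
        else:
            start, end = r.pos - 1, r.pos - 1 + len(r.ref)
            if reference[chrom][start:end] != r.ref:
                raise FormatError(
                    f"REF mismatch at {chrom}:{r.pos}: expected {r.ref!r}"
                )
            repl = alt
        edits[chrom].append((start, end, repl))
    out = {}
    for chrom, seq in reference.items():
        chunks = []
        cursor = 0
        for start, end, repl in sorted(edits[chrom]):
            if start < cursor:
                raise ParameterError("overlapping variants cannot be applied")
            chunks.append(seq[cursor:start])
            chunks.append(repl)
            cursor = end
        chunks.append(seq[cursor:])
        out[chrom] = "".join(chunks)
    return out
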