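"""Readers, writers and in-memory containers for the formats the pipeline touches.

Covers FASTA references, SAM/BAM alignments (via pysam), samtools-style pileup
text in two dialects, the tabular variant output, and the simulator truth
table.  All user-visible coordinates are 1-based with fully closed intervals,
following SAM/pileup convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "AlignedRead",
    "BaseObs",
    "IndelObs",
    "PileupColumn",
    "TruthRecord",
    "TruthTable",
    "read_fasta",
    "write_fasta",
    "iterate_alignments",
    "AlignmentStream",
    "write_alignments",
    "read_pileup",
    "pileup_from_reads",
    "write_variants",
    "read_variants",
]

_VALID = "ACGTN"
# uppercase, then squash every non-ACGT letter (IUPAC ambiguity codes, gaps
# written as letters, etc.) to N
_NORM = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
)

CONSUMES_READ = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")
_CIGAR_OPS = "MIDNSHP=X"


# ---------------------------------------------------------------------------
# reference genome

@dataclass
class ReferenceGenome:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        return self.sequences[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Bases of the closed interval [start, end], 1-based."""
        return self.sequences[chrom][start - 1 : end]

    def validate(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = set(seq) - set(_VALID)
            if bad:
                raise ValueError(f"{chrom}: invalid characters {sorted(bad)}")


def normalize_sequence(seq: str) -> str:
    return seq.upper().translate(_NORM)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference, uppercasing and mapping ambiguity codes to N."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = normalize_sequence(str(rec.seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (missing '>' header?)")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# aligned reads

@dataclass
class AlignedRead:
    """One mapped SAM record with parsed CIGAR and per-base qualities.

    ``pos`` is the 1-based leftmost aligned reference coordinate.  ``cigar``
    is an ordered list of ``(length, op)`` with op in MIDNSHP=X.  ``seq`` and
    ``quals`` cover the stored read bases (soft-clipped bases included).
    """

    name: str
    chrom: str
    pos: int
    strand: str  # '+' or '-'
    cigar: list[tuple[int, str]]
    seq: str
    quals: list[int]
    mapq: int = 60
    read_group: str | None = None
    is_paired: bool = False
    is_first_mate: bool = True
    mate_mapped: bool = False
    mate_chrom: str | None = None
    mate_pos: int = 0
    mate_strand: str = "+"
    insert_size: int = 0

    def validate(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.name}: quals/seq length mismatch")
        consumed = sum(n for n, op in self.cigar if op in CONSUMES_READ)
        if consumed != len(self.seq):
            raise ValueError(
                f"{self.name}: CIGAR consumes {consumed} bases, seq is {len(self.seq)}"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def reference_end(self) -> int:
        """Rightmost aligned (reference-consuming) position, 1-based closed."""
        return self.pos + sum(n for n, op in self.cigar if op in CONSUMES_REF) - 1

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][0] if self.cigar and self.cigar[0][1] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][0] if self.cigar and self.cigar[-1][1] == "S" else 0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.pos <= end and self.reference_end >= start

    def copy(self, **changes) -> "AlignedRead":
        out = replace(self, **changes)
        out.cigar = list(out.cigar)
        out.quals = list(out.quals)
        return out


def parse_cigar(text: str) -> list[tuple[int, str]]:
    if text in ("*", ""):
        return []
    out = [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", text)]
    if "".join(f"{n}{op}" for n, op in out) != text:
        raise ValueError(f"malformed CIGAR: {text!r}")
    return out


def cigar_string(cigar: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cigar) if cigar else "*"


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cig = [(n, _CIGAR_OPS[op]) for op, n in (rec.cigartuples or [])]
    rg = None
    if rec.has_tag("RG"):
        rg = rec.get_tag("RG")
    return AlignedRead(
        name=rec.query_name,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        strand="-" if rec.is_reverse else "+",
        cigar=cig,
        seq=rec.query_sequence or "",
        quals=list(rec.query_qualities or []),
        mapq=rec.mapping_quality,
        read_group=rg,
        is_paired=rec.is_paired,
        is_first_mate=(not rec.is_paired) or rec.is_read1,
        mate_mapped=rec.is_paired and not rec.mate_is_unmapped,
        mate_chrom=(
            rec.next_reference_name
            if rec.is_paired and rec.next_reference_id >= 0
            else None
        ),
        mate_pos=rec.next_reference_start + 1 if rec.next_reference_start >= 0 else 0,
        mate_strand="-" if (rec.is_paired and rec.mate_is_reverse) else "+",
        insert_size=rec.template_length,
    )


def _to_pysam(read: AlignedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = read.name
    rec.query_sequence = read.seq
    rec.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.quals)
    )
    rec.reference_id = header.get_tid(read.chrom)
    if rec.reference_id < 0:
        raise ValueError(f"chromosome {read.chrom!r} absent from header")
    rec.reference_start = read.pos - 1
    rec.mapping_quality = read.mapq
    rec.cigartuples = [(_CIGAR_OPS.index(op), n) for n, op in read.cigar]
    flag = 0
    if read.is_paired:
        flag |= 0x1
        flag |= 0x40 if read.is_first_mate else 0x80
        if not read.mate_mapped:
            flag |= 0x8
        if read.mate_strand == "-":
            flag |= 0x20
    if read.strand == "-":
        flag |= 0x10
    rec.flag = flag
    if read.mate_chrom is not None:
        rec.next_reference_id = header.get_tid(read.mate_chrom)
        rec.next_reference_start = read.mate_pos - 1
    else:
        rec.next_reference_id = -1
        rec.next_reference_start = -1
    rec.template_length = read.insert_size
    if read.read_group is not None:
        rec.set_tag("RG", read.read_group)
    return rec


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class AlignmentStream:
    """Iterator over mapped reads of a SAM/BAM file.

    Unmapped records are skipped; their number is available afterwards as
    ``skipped_unmapped``.  ``region`` ("chrom:start-end", 1-based closed)
    restricts to overlapping reads.  When ``reference`` is given, every read
    placed on a chromosome absent from it raises.
    """

    def __init__(
        self,
        path: str | Path,
        region: str | None = None,
        reference: ReferenceGenome | None = None,
    ):
        self.path = str(path)
        self.skipped_unmapped = 0
        self.reference = reference
        if region is not None:
            m = _REGION_RE.match(region)
            if not m:
                raise ValueError(f"bad region {region!r}; expected chrom:start-end")
            self.region: tuple[str, int, int] | None = (
                m.group(1),
                int(m.group(2)),
                int(m.group(3)),
            )
        else:
            self.region = None

    def __iter__(self) -> Iterator[AlignedRead]:
        mode = "rb" if self.path.endswith(".bam") else "r"
        with pysam.AlignmentFile(self.path, mode, check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    self.skipped_unmapped += 1
                    continue
                read = _from_pysam(rec)
                if self.reference is not None and read.chrom not in self.reference.sequences:
                    raise ValueError(
                        f"read {read.name}: chromosome {read.chrom!r} absent from reference"
                    )
                if self.region is not None and not read.overlaps(*self.region):
                    continue
                yield read


def iterate_alignments(
    path: str | Path,
    region: str | None = None,
    reference: ReferenceGenome | None = None,
) -> AlignmentStream:
    return AlignmentStream(path, region=region, reference=reference)


def write_alignments(
    reads: Iterable[AlignedRead],
    header: dict[str, int],
    path: str | Path,
    read_groups: Iterable[str] | None = None,
    program: dict[str, str] | None = None,
) -> None:
    """Write reads as SAM (or BAM when the path ends in .bam).

    ``header`` maps chromosome name to length; ``read_groups`` adds @RG
    records; ``program`` adds one @PG record (provenance stamp).
    """
    head: dict = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in header.items()],
    }
    if read_groups:
        head["RG"] = [{"ID": rg, "SM": rg} for rg in read_groups]
    if program:
        head["PG"] = [program]
    path = str(path)
    mode = "wb" if path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(path, mode, header=head) as fh:
        h = fh.header
        for read in reads:
            fh.write(_to_pysam(read, h))


# ---------------------------------------------------------------------------
# pileup

@dataclass
class BaseObs:
    """One read-base observation at a pileup column ('*' = deletion span)."""

    base: str
    qual: int | None = None
    read_group: str | None = None
    read_name: str | None = None
    read_index: int | None = None  # index into the source read list (in-memory builds)
    read_offset: int | None = None  # 0-based offset of the base in the read
    dist3: int | None = None  # distance of the base from the read 3' end


@dataclass
class IndelObs:
    kind: str  # 'INS' or 'DEL'
    length: int
    seq: str
    read_group: str | None = None
    read_name: str | None = None


@dataclass
class PileupColumn:
    """Per-position stack of read observations.

    ``depth`` is the stated column depth (8th column of classic pileup, 4th of
    mpileup); ``recounted_depth`` is the number of parsed base observations —
    the two are exposed separately.  ``n_end3`` counts reads whose rightmost
    aligned base (their alignment 3' terminus, trailing soft clips included)
    lies at this column; it feeds the indel-frequency denominator.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    obs: list[BaseObs] = field(default_factory=list)
    indels: list[IndelObs] = field(default_factory=list)
    n_end3: int = 0

    @property
    def recounted_depth(self) -> int:
        return len(self.obs)


_DIALECTS = {"consensus10": (10, 7, 8, 9), "mpileup6": (6, 3, 4, 5)}
# dialect -> (min columns, depth col idx, bases idx, quals idx), 0-based


def _decode_bases(
    bases: str, quals: str, ref_base: str, phred_offset: int
) -> tuple[list[BaseObs], list[IndelObs], int]:
    obs: list[BaseObs] = []
    indels: list[IndelObs] = []
    n_end3 = 0
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' + mapping-quality char
            continue
        if c == "$":
            n_end3 += 1
            i += 1
            continue
        if c in ".,ACGTNacgtn*><":
            if c in ".,":
                base = ref_base.upper()
            elif c in "><":
                base = "*"  # reference skip placeholder; treated like a gap
            else:
                base = c.upper()
            q = ord(quals[qi]) - phred_offset if qi < len(quals) else None
            qi += 1
            obs.append(BaseObs(base=base, qual=q))
            i += 1
            # indel observation attached to this read follows immediately
            if i < n and bases[i] in "+-":
                sign = bases[i]
                m = re.match(r"(\d+)", bases[i + 1 :])
                if not m:
                    raise ValueError(f"malformed indel in bases string: {bases[i:]}")
                ln = int(m.group(1))
                seq_start = i + 1 + len(m.group(1))
                seq = bases[seq_start : seq_start + ln]
                indels.append(
                    IndelObs(
                        kind="INS" if sign == "+" else "DEL",
                        length=ln,
                        seq=normalize_sequence(seq),
                    )
                )
                i = seq_start + ln
            if i < n and bases[i] == "$":
                n_end3 += 1
                i += 1
        else:
            raise ValueError(f"unexpected character {c!r} in pileup bases string")
    return obs, indels, n_end3


def read_pileup(
    path: str | Path, dialect: str, phred_offset: int = 33
) -> Iterator[PileupColumn]:
    """Stream columns from a samtools-style pileup text file.

    ``dialect`` must be stated explicitly: "consensus10" (classic 10-column
    pileup; depth in column 8) or "mpileup6" (depth in column 4).  Quality
    characters are decoded with ``phred_offset`` (33 by default, 64 for
    old-style Illumina scaling).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    mincol, di, bi, qi = _DIALECTS[dialect]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < mincol:
                raise ValueError(
                    f"{path}:{lineno}: {len(cols)} columns, "
                    f"dialect {dialect} needs >= {mincol}"
                )
            chrom, pos, ref_base = cols[0], int(cols[1]), cols[2]
            depth = int(cols[di])
            obs, indels, n_end3 = _decode_bases(
                cols[bi], cols[qi], ref_base, phred_offset
            )
            yield PileupColumn(
                chrom=chrom,
                pos=pos,
                ref_base=normalize_sequence(ref_base) if len(ref_base) == 1 else "N",
                depth=depth,
                obs=obs,
                indels=indels,
                n_end3=n_end3,
            )


def pileup_from_reads(
    reads: list[AlignedRead], ref: ReferenceGenome
) -> list[PileupColumn]:
    """Build pileup columns in memory from aligned reads.

    Observations carry back-references (read index and offset) so that error
    correction can edit the source reads.  Deletion-spanned positions get '*'
    observations that count toward depth; insertions and deletions are
    recorded at their anchor column (base preceding the event).
    """
    columns: dict[tuple[str, int], PileupColumn] = {}

    def col(chrom: str, pos: int) -> PileupColumn:
        key = (chrom, pos)
        c = columns.get(key)
        if c is None:
            c = PileupColumn(
                chrom=chrom, pos=pos, ref_base=ref.base(chrom, pos), depth=0
            )
            columns[key] = c
        return c

    for idx, read in enumerate(reads):
        rpos = read.pos
        roff = 0
        L = read.read_length
        for n, op in read.cigar:
            if op in "M=X":
                for k in range(n):
                    c = col(read.chrom, rpos + k)
                    off = roff + k
                    dist3 = (L - 1 - off) if read.strand == "+" else off
                    c.obs.append(
                        BaseObs(
                            base=read.seq[off],
                            qual=read.quals[off],
                            read_group=read.read_group,
                            read_name=read.name,
                            read_index=idx,
                            read_offset=off,
                            dist3=dist3,
                        )
                    )
                rpos += n
                roff += n
            elif op == "I":
                c = col(read.chrom, rpos - 1)
                c.indels.append(
                    IndelObs(
                        kind="INS",
                        length=n,
                        seq=read.seq[roff : roff + n],
                        read_group=read.read_group,
                        read_name=read.name,
                    )
                )
                roff += n
            elif op == "D":
                c = col(read.chrom, rpos - 1)
                c.indels.append(
                    IndelObs(
                        kind="DEL",
                        length=n,
                        seq=ref.slice(read.chrom, rpos, rpos + n - 1),
                        read_group=read.read_group,
                        read_name=read.name,
                    )
                )
                for k in range(n):
                    col(read.chrom, rpos + k).obs.append(
                        BaseObs(
                            base="*",
                            qual=None,
                            read_group=read.read_group,
                            read_name=read.name,
                            read_index=idx,
                        )
                    )
                rpos += n
            elif op == "N":
                rpos += n
            elif op == "S":
                roff += n
            # H, P: nothing consumed
        col(read.chrom, read.reference_end).n_end3 += 1

    out = sorted(columns.values(), key=lambda c: (c.chrom, c.pos))
    for c in out:
        c.depth = len(c.obs)
    return out


# ---------------------------------------------------------------------------
# truth table

@dataclass(frozen=True)
class TruthRecord:
    """One simulator-introduced mutation, in mutated-reference coordinates.

    Alleles are expressed relative to the MUTATED reference (the genome
    against which reads are aligned and variants called): ``ref_allele`` is
    the mutated-reference allele and ``alt_allele`` the allele a perfect
    caller reports (the original genome's allele).  ``orig_pos`` carries the
    original-genome coordinate for provenance.
    """

    chrom: str
    pos: int
    type: str  # SNP / INS / DEL
    ref_allele: str
    alt_allele: str
    orig_pos: int = 0


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def validate(self) -> None:
        keys = [(r.chrom, r.pos) for r in self.records]
        if keys != sorted(keys):
            raise ValueError("truth records not sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) in truth table")

    def by_type(self, kind: str) -> list[TruthRecord]:
        kind = kind.upper()
        if kind == "INDEL":
            return [r for r in self.records if r.type in ("INS", "DEL")]
        return [r for r in self.records if r.type == kind]


_TRUTH_HEADER = ["chrom", "pos", "type", "ref", "alt", "orig_pos"]


def write_truth(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_HEADER) + "\n")
        for r in truth.records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.type}\t{r.ref_allele}\t{r.alt_allele}\t{r.orig_pos}\n"
            )


def read_truth(path: str | Path) -> TruthTable:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, p, t, ref, alt, op = line.rstrip("\n").split("\t")
            records.append(TruthRecord(c, int(p), t, ref, alt, int(op)))
    return TruthTable(records)


# ---------------------------------------------------------------------------
# variant table (defined here to keep all file formats in one module; the
# VariantCall type itself lives in readpolish.call)

_VAR_HEADER = [
    "chrom", "pos", "type", "ref", "alt", "depth", "alt_count", "freq",
    "mean_qual", "zygosity",
]


def write_variants(calls, path: str | Path, params_stamp: dict | None = None) -> None:
    with open(path, "w") as fh:
        if params_stamp:
            for k, v in params_stamp.items():
                fh.write(f"##{k}={v}\n")
        fh.write("#" + "\t".join(_VAR_HEADER) + "\n")
        for v in calls:
            mq = "" if v.mean_alt_qual is None else f"{v.mean_alt_qual:.2f}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.type}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.depth}\t{v.alt_count}\t{v.alt_freq:.4f}\t{mq}\t{v.zygosity}\n"
            )


def read_variants(path: str | Path):
    from .call import VariantCall

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, p, t, ref, alt, d, ac, fr, mq, zyg = line.rstrip("\n").split("\t")
            out.append(
                VariantCall(
                    chrom=c,
                    pos=int(p),
                    type=t,
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=int(d),
                    alt_count=int(ac),
                    alt_freq=float(fr),
                    mean_alt_qual=float(mq) if mq else None,
                    zygosity=zyg,
                )
            )
    return out
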