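"""Alignment refinement: local realignment around indels, error correction of
mismatch bases, and filtering of mismatch-heavy or discordant reads.

Two modes are provided.  In *basic* mode reads are locally realigned around
indels observed in the input, then filtered on mismatch count and pairing
criteria.  In *error-correction* mode, reads carrying more mismatches than
10% of their length are removed up front, the remainder are realigned, then
likely sequencing errors (judged from base quality and allele frequency at
each non-reference pileup column, per sample for pooled data) are rewritten
to the reference base before filtering.
"""

from __future__ import annotations

import math
import statistics
from bisect import bisect_left, insort
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .formats_io import (
    AlignedRead,
    PileupColumn,
    ReferenceGenome,
    pileup_from_reads,
)
from .mismatch_model import (
    SUB,
    AlignmentDiff,
    count_mismatches,
    diff_read,
    terminal_mismatch,
)

__all__ = [
    "RefineParams",
    "IndelCatalog",
    "InsertStats",
    "build_indel_catalog",
    "local_realign",
    "error_correct",
    "filter_reads",
    "refine_pipeline",
    "estimate_insert_stats",
    "RefineResult",
]

BASIC = "basic"
ERROR_CORRECTION = "error_correction"

# per-sample allele-frequency floors used in pooled (msamp) correction: a
# non-reference allele below the floor for its sample is treated as error
MSAMP_THRESHOLDS = {"homo": 0.8, "het": 0.3}


@dataclass
class RefineParams:
    """Tunable thresholds of the refinement engine.

    ``num`` caps mismatches per read (indels and soft clips count one each);
    ``fnum`` caps the total over a read pair and defaults to floor(1.7*num),
    giving the paired default 3 for num=2.  ``minq`` (optional) restricts
    mismatch counting to substitutions below that quality.  ``correct_minq``
    is the error-correction quality floor (mean non-reference quality below
    it triggers correction); ``mfreq`` the correction frequency floor.
    ``msamp`` maps read-group -> 'homo'|'het' and switches on per-sample
    frequency correction for pooled data.  ``fpair`` removes the surviving
    mate of a filtered read; unset, it defaults to on in error-correction
    mode and off in basic mode.
    """

    mode: str = BASIC
    num: int = 2
    fnum: int | None = None
    mrate: float | None = None
    minq: float | None = None
    correct_minq: float = 10.0
    mfreq: float = 0.0
    msamp: dict[str, str] | None = None
    fpair: bool | None = None
    realign: bool = True
    discordant_filter: bool = True
    insert_sd_mult: float = 5.0
    precorrection_rate: float = 0.10
    terminal_k: int = 2

    def __post_init__(self) -> None:
        if self.mode not in (BASIC, ERROR_CORRECTION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.num < 0:
            raise ValueError("num must be >= 0")
        if not 0.0 <= self.mfreq <= 1.0:
            raise ValueError("mfreq must be in [0, 1]")
        if self.fnum is not None and self.fnum < self.num:
            raise ValueError("fnum must be >= num")
        if self.msamp is not None:
            bad = set(self.msamp.values()) - set(MSAMP_THRESHOLDS)
            if bad:
                raise ValueError(f"msamp designations must be homo/het, got {bad}")

    @property
    def resolved_fnum(self) -> int:
        return self.fnum if self.fnum is not None else math.floor(1.7 * self.num)

    @property
    def resolved_fpair(self) -> bool:
        if self.fpair is not None:
            return self.fpair
        return self.mode == ERROR_CORRECTION


# ---------------------------------------------------------------------------
# indel catalog

@dataclass
class IndelCatalog:
    """Indel alleles observed in the input, keyed by (chrom, anchor position).

    The anchor is the reference base immediately preceding the event, for
    insertions and deletions alike.  Values map (kind, length, inserted-seq)
    to the number of supporting reads.
    """

    entries: dict[tuple[str, int], dict[tuple[str, int, str], int]] = field(
        default_factory=dict
    )
    _anchors: dict[str, list[int]] = field(default_factory=dict)

    def add(self, chrom: str, anchor: int, kind: str, length: int, seq: str) -> None:
        alleles = self.entries.setdefault((chrom, anchor), {})
        akey = (kind, length, seq)
        alleles[akey] = alleles.get(akey, 0) + 1
        pos_list = self._anchors.setdefault(chrom, [])
        i = bisect_left(pos_list, anchor)
        if i == len(pos_list) or pos_list[i] != anchor:
            insort(pos_list, anchor)

    def overlapping(self, chrom: str, start: int, end: int):
        """Yield (anchor, kind, length, seq) entries with anchor in [start, end]."""
        pos_list = self._anchors.get(chrom, [])
        i = bisect_left(pos_list, start)
        while i < len(pos_list) and pos_list[i] <= end:
            anchor = pos_list[i]
            for (kind, length, seq) in self.entries[(chrom, anchor)]:
                yield anchor, kind, length, seq
            i += 1

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_indel_catalog(
    reads: list[AlignedRead],
    ref: ReferenceGenome,
    diffs: list[AlignmentDiff] | None = None,
) -> IndelCatalog:
    """Collect every distinct indel allele observed in any read's CIGAR."""
    catalog = IndelCatalog()
    if diffs is None:
        diffs = [diff_read(r, ref) for r in reads]
    for d in diffs:
        for e in d.events:
            if e.kind == "INS":
                catalog.add(d.read.chrom, e.ref_pos, "INS", e.length, e.read_bases)
            elif e.kind == "DEL":
                # anchor = base preceding the first deleted base
                catalog.add(d.read.chrom, e.ref_pos - 1, "DEL", e.length, "")
    return catalog


# ---------------------------------------------------------------------------
# local realignment

def _candidate_reads(
    read: AlignedRead,
    anchor: int,
    kind: str,
    length: int,
    chrom_len: int,
) -> list[AlignedRead]:
    """Single-gap candidate alignments of the full read at a catalog indel.

    The read sequence (soft clips unfolded into aligned bases) is re-gapped
    at the anchor, once keeping the 5' end anchored and once keeping the 3'
    end anchored — equivalently, shifting the 3' or the 5' portion of the
    read by the indel length.
    """
    L = read.read_length
    start5 = read.pos - read.leading_clip
    end3 = read.reference_end + read.trailing_clip
    ref_consumed = L + length if kind == "DEL" else L - length
    if kind == "INS" and ref_consumed < 2:
        return []
    starts = {start5, end3 - ref_consumed + 1}
    out = []
    for cand_start in starts:
        a = anchor - cand_start + 1  # read bases aligned before the gap
        if kind == "DEL":
            if not (1 <= a <= L - 1):
                continue
            cigar = [(a, "M"), (length, "D"), (L - a, "M")]
        else:
            b = L - a - length  # aligned bases after the inserted run
            if a < 1 or b < 1:
                continue
            cigar = [(a, "M"), (length, "I"), (b, "M")]
        if cand_start < 1 or cand_start + ref_consumed - 1 > chrom_len:
            continue
        out.append(read.copy(pos=cand_start, cigar=cigar))
    return out


def local_realign(
    read: AlignedRead,
    diff: AlignmentDiff,
    catalog: IndelCatalog,
    ref: ReferenceGenome,
    minq: float | None = None,
) -> tuple[AlignedRead, bool]:
    """Re-gap a read at catalog indels when that lowers (or keeps) its
    mismatch count.

    Only reads with at most one indel or one soft-clipped end are
    candidates; gapless, unclipped reads must carry at least one
    substitution.  Among candidates with the minimal mismatch count, ties go
    to fewest substitution events, then leftmost gap position.  Returns the
    (possibly new) read and whether realignment was accepted.
    """
    if diff.n_indel + diff.n_clip > 1:
        return read, False
    if diff.n_indel == 0 and diff.n_clip == 0 and diff.n_sub == 0:
        return read, False

    orig_count = count_mismatches(diff, minq)
    chrom_len = len(ref.sequences[read.chrom])
    window_lo = read.pos - read.leading_clip
    window_hi = read.reference_end + read.trailing_clip

    best: tuple[int, int, int, AlignedRead] | None = None
    for anchor, kind, length, _seq in catalog.overlapping(
        read.chrom, window_lo - 7, window_hi + 7
    ):
        if anchor < window_lo - length or anchor > window_hi + length:
            continue
        for cand in _candidate_reads(read, anchor, kind, length, chrom_len):
            cdiff = diff_read(cand, ref)
            count = count_mismatches(cdiff, minq)
            key = (count, cdiff.n_sub, anchor)
            if best is None or key < best[:3]:
                best = (count, cdiff.n_sub, anchor, cand)
    if best is not None and best[0] <= orig_count:
        cand = best[3]
        if (cand.pos, cand.cigar) != (read.pos, read.cigar):
            return cand, True
    return read, False


# ---------------------------------------------------------------------------
# error correction

def _column_corrections(
    column: PileupColumn, params: RefineParams
) -> list[tuple[int, int]]:
    """Decide which bases of one column to rewrite to the reference.

    Returns (read_index, read_offset) pairs.  A non-reference allele is
    corrected when its mean base quality falls below ``correct_minq``, when
    its frequency (allele observations / column base observations) falls
    below ``mfreq``, or when it is a minority allele among multiple
    non-reference alleles.  With ``msamp`` set, frequency logic runs per
    read-group with floors 0.8 (homozygous sample) / 0.3 (heterozygous).
    """
    ref_base = column.ref_base
    if ref_base not in "ACGT":
        return []
    base_obs = [o for o in column.obs if o.base in "ACGT"]
    groups: dict[str, list] = defaultdict(list)
    for o in base_obs:
        if o.base != ref_base:
            groups[o.base].append(o)
    if not groups:
        return []
    total = len(base_obs)
    counts = {b: len(g) for b, g in groups.items()}
    max_count = max(counts.values())
    out: list[tuple[int, int]] = []

    for b, g in groups.items():
        quals = [o.qual for o in g if o.qual is not None]
        mean_q = sum(quals) / len(quals) if quals else 0.0
        whole_allele = False
        if mean_q < params.correct_minq:
            whole_allele = True
        elif len(groups) > 1 and counts[b] < max_count:
            whole_allele = True
        elif params.msamp is None and counts[b] / total < params.mfreq:
            whole_allele = True
        if whole_allele:
            out.extend((o.read_index, o.read_offset) for o in g)
            continue
        if params.msamp is not None:
            per_sample_total = Counter(o.read_group for o in base_obs)
            for o in g:
                if o.read_group is None:
                    raise ValueError(
                        f"read {o.read_name} lacks a read group; msamp mode "
                        "requires RG on every read"
                    )
                desig = params.msamp.get(o.read_group)
                if desig is None:
                    raise ValueError(
                        f"read group {o.read_group!r} missing from msamp table"
                    )
                n_s = per_sample_total[o.read_group]
                c_s = sum(1 for x in g if x.read_group == o.read_group)
                if n_s and c_s / n_s < MSAMP_THRESHOLDS[desig]:
                    out.append((o.read_index, o.read_offset))
    return out


def error_correct(
    reads: list[AlignedRead],
    ref: ReferenceGenome,
    params: RefineParams,
    columns: list[PileupColumn] | None = None,
) -> tuple[list[AlignedRead], int]:
    """Rewrite likely-error bases to the reference across all reads.

    Builds a pileup from the (realigned) reads unless ``columns`` built from
    the same list is supplied.  Only substituted bases are ever edited —
    always *to* the reference base, never away from it — and quality scores
    are left untouched.  Returns the edited read list and the number of
    corrected bases.
    """
    if columns is None:
        columns = pileup_from_reads(reads, ref)
    edits: dict[int, dict[int, str]] = defaultdict(dict)
    for col in columns:
        for idx, off in _column_corrections(col, params):
            edits[idx][off] = col.ref_base
    if not edits:
        return list(reads), 0
    out = list(reads)
    n_corrected = 0
    for idx, offsets in edits.items():
        seq = list(out[idx].seq)
        for off, base in offsets.items():
            seq[off] = base
            n_corrected += 1
        out[idx] = out[idx].copy(seq="".join(seq))
    return out, n_corrected


# ---------------------------------------------------------------------------
# filtering

@dataclass
class InsertStats:
    mean: float
    sd: float
    n_pairs: int


def estimate_insert_stats(reads: list[AlignedRead]) -> InsertStats:
    """Mean and SD of the template length over proper pairs.

    Uses pairs with both mates mapped to the same chromosome, counting each
    pair once via its positive template length.
    """
    sizes = [
        float(r.insert_size)
        for r in reads
        if r.is_paired
        and r.mate_mapped
        and r.insert_size > 0
        and (r.mate_chrom is None or r.mate_chrom == r.chrom)
    ]
    if len(sizes) < 2:
        return InsertStats(mean=0.0, sd=0.0, n_pairs=len(sizes))
    return InsertStats(
        mean=statistics.fmean(sizes), sd=statistics.stdev(sizes), n_pairs=len(sizes)
    )


def filter_reads(
    reads: list[AlignedRead],
    ref: ReferenceGenome,
    params: RefineParams,
    insert_stats: InsertStats | None = None,
    diffs: list[AlignmentDiff] | None = None,
) -> tuple[list[AlignedRead], list[tuple[str, str]]]:
    """Apply the removal rules; returns retained reads and a removal log.

    A read is removed when it is soft-clipped at both termini, contains more
    than two indels, exceeds the per-read mismatch cap ``num`` (or the
    fraction ``mrate``), belongs to a pair exceeding the pair cap ``fnum``,
    carries a terminal substitution (only when realignment is disabled), or
    is discordant (mate unmapped, or template length beyond mean + 5 SD).
    With ``fpair`` on, the mate of any removed read is removed as well.  The
    log records one (read name + mate tag, reason) entry per removed read.
    """
    if diffs is None:
        diffs = [diff_read(r, ref) for r in reads]
    if insert_stats is None:
        insert_stats = estimate_insert_stats(reads)
    counts = [count_mismatches(d, params.minq) for d in diffs]

    pair_totals: dict[str, int] = defaultdict(int)
    pair_members: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        if r.is_paired:
            pair_totals[r.name] += counts[i]
            pair_members[r.name].append(i)

    max_insert = (
        insert_stats.mean + params.insert_sd_mult * insert_stats.sd
        if insert_stats.n_pairs >= 2
        else None
    )
    fnum = params.resolved_fnum

    removed: dict[int, str] = {}
    for i, (r, d, c) in enumerate(zip(reads, diffs, counts)):
        if r.leading_clip and r.trailing_clip:
            removed[i] = "double_clip"
        elif d.n_indel > 2:
            removed[i] = "many_indels"
        elif c > params.num:
            removed[i] = "num"
        elif params.mrate is not None and c / r.read_length > params.mrate:
            removed[i] = "mrate"
        elif r.is_paired and len(pair_members[r.name]) == 2 and pair_totals[r.name] > fnum:
            removed[i] = "fnum"
        elif not params.realign and terminal_mismatch(d, params.terminal_k):
            removed[i] = "terminal"
        elif params.discordant_filter and r.is_paired:
            if not r.mate_mapped:
                removed[i] = "discordant"
            elif max_insert is not None and abs(r.insert_size) > max_insert:
                removed[i] = "discordant"

    if params.resolved_fpair:
        for i in list(removed):
            for j in pair_members.get(reads[i].name, []):
                if j != i and j not in removed:
                    removed[j] = "fpair"

    kept = [r for i, r in enumerate(reads) if i not in removed]
    log = [
        (f"{reads[i].name}/{1 if reads[i].is_first_mate else 2}", reason)
        for i, reason in sorted(removed.items())
    ]
    return kept, log


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RefineResult:
    reads: list[AlignedRead]
    summary: dict


def refine_pipeline(
    reads: list[AlignedRead], ref: ReferenceGenome, params: RefineParams
) -> RefineResult:
    """Run the full refinement: (prefilter) -> realign -> (correct) -> filter.

    Basic mode realigns then filters.  Error-correction mode first drops
    reads whose mismatch count exceeds ``precorrection_rate`` of their
    length, realigns, corrects errors, then filters.  Insert-size statistics
    for the discordant filter are estimated from the full input.
    """
    summary: dict = {"reads_in": len(reads), "mode": params.mode}
    insert_stats = estimate_insert_stats(reads)
    summary["insert_mean"] = round(insert_stats.mean, 2)
    summary["insert_sd"] = round(insert_stats.sd, 2)

    work = list(reads)
    if params.mode == ERROR_CORRECTION:
        survivors = []
        n_pre = 0
        for r in work:
            d = diff_read(r, ref)
            if count_mismatches(d) > params.precorrection_rate * r.read_length:
                n_pre += 1
            else:
                survivors.append(r)
        summary["prefiltered"] = n_pre
        work = survivors

    n_realigned = 0
    if params.realign:
        diffs = [diff_read(r, ref) for r in work]
        catalog = build_indel_catalog(work, ref, diffs)
        summary["catalog_indels"] = len(catalog)
        realigned = []
        for r, d in zip(work, diffs):
            new, accepted = local_realign(r, d, catalog, ref, params.minq)
            realigned.append(new)
            n_realigned += accepted
        work = realigned
    summary["realigned"] = n_realigned

    if params.mode == ERROR_CORRECTION:
        work, n_corrected = error_correct(work, ref, params)
        summary["bases_corrected"] = n_corrected

    kept, log = filter_reads(work, ref, params, insert_stats=insert_stats)
    summary["reads_out"] = len(kept)
    summary["removed_by_reason"] = dict(Counter(reason for _, reason in log))
    return RefineResult(reads=kept, summary=summary)
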