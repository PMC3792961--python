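"""Differences of an aligned read against the reference, and mismatch counting.

Mismatches are found by direct comparison of the read sequence with the
corresponding reference region (never via the MD tag, so any aligner's output
can be processed).  Under the filtering rules, an indel or a soft-clipped end
each count as one mismatch; substitution counting can be restricted to
low-quality bases (only bases with quality below ``minq`` count), so that
high-quality mismatches — likely true variants — do not penalise a read.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .formats_io import AlignedRead, ReferenceGenome

__all__ = ["DiffEvent", "AlignmentDiff", "diff_read", "count_mismatches",
           "terminal_mismatch"]

SUB = "SUB"
INS = "INS"
DEL = "DEL"
SOFTCLIP = "SOFTCLIP"


@dataclass(frozen=True)
class DiffEvent:
    """One difference between read and reference.

    ``ref_pos`` is 1-based: the substituted base for SUB, the base preceding
    the insertion for INS, the first deleted base for DEL, the reference
    position adjacent to the clip for SOFTCLIP.  ``qual`` is the Phred score
    of the read base (mean over bases for multi-base events).
    """

    kind: str
    ref_pos: int
    read_offset: int
    length: int
    read_bases: str
    ref_bases: str
    qual: float | None


@dataclass
class AlignmentDiff:
    read: AlignedRead
    events: list[DiffEvent]

    @cached_property
    def n_sub(self) -> int:
        return sum(1 for e in self.events if e.kind == SUB)

    @cached_property
    def n_indel(self) -> int:
        return sum(1 for e in self.events if e.kind in (INS, DEL))

    @cached_property
    def n_clip(self) -> int:
        return sum(1 for e in self.events if e.kind == SOFTCLIP)


def diff_read(read: AlignedRead, ref: ReferenceGenome) -> AlignmentDiff:
    """Compare every aligned base to the reference and collect events.

    Positions where the reference is N yield no SUB event (ambiguous
    reference bases are never evidence either way); a read base of N that
    differs from a called reference base does count as a SUB.  CIGAR = and X
    runs are re-verified against the reference rather than trusted.  Hard
    clips and N (skip) ops contribute no events; N advances the reference.
    """
    chrom_len = len(ref.sequences[read.chrom])
    if read.reference_end > chrom_len or read.pos < 1:
        raise ValueError(
            f"read {read.name} spans {read.pos}-{read.reference_end}, "
            f"beyond {read.chrom} length {chrom_len}"
        )
    events: list[DiffEvent] = []
    refseq = ref.sequences[read.chrom]
    rpos = read.pos
    roff = 0
    for n, op in read.cigar:
        if op in "M=X":
            for k in range(n):
                rb = refseq[rpos + k - 1]
                qb = read.seq[roff + k]
                if rb != "N" and qb != rb:
                    events.append(
                        DiffEvent(
                            kind=SUB,
                            ref_pos=rpos + k,
                            read_offset=roff + k,
                            length=1,
                            read_bases=qb,
                            ref_bases=rb,
                            qual=float(read.quals[roff + k]),
                        )
                    )
            rpos += n
            roff += n
        elif op == "I":
            qs = read.quals[roff : roff + n]
            events.append(
                DiffEvent(
                    kind=INS,
                    ref_pos=rpos - 1,
                    read_offset=roff,
                    length=n,
                    read_bases=read.seq[roff : roff + n],
                    ref_bases="",
                    qual=sum(qs) / len(qs) if qs else None,
                )
            )
            roff += n
        elif op == "D":
            events.append(
                DiffEvent(
                    kind=DEL,
                    ref_pos=rpos,
                    read_offset=roff,
                    length=n,
                    read_bases="",
                    ref_bases=refseq[rpos - 1 : rpos + n - 1],
                    qual=None,
                )
            )
            rpos += n
        elif op == "S":
            qs = read.quals[roff : roff + n]
            events.append(
                DiffEvent(
                    kind=SOFTCLIP,
                    ref_pos=rpos if roff > 0 else read.pos,
                    read_offset=roff,
                    length=n,
                    read_bases=read.seq[roff : roff + n],
                    ref_bases="",
                    qual=sum(qs) / len(qs) if qs else None,
                )
            )
            roff += n
        elif op == "N":
            rpos += n
        # H, P: no event, nothing consumed from the read
    return AlignmentDiff(read=read, events=events)


def count_mismatches(diff: AlignmentDiff, minq: float | None = None) -> int:
    """Rule-based mismatch count of a read.

    Each indel and each soft-clipped end is one mismatch.  Substitutions all
    count when ``minq`` is unset; with ``minq`` set, only substitutions whose
    base quality is below ``minq`` count (high-quality mismatches are treated
    as potential true variants, not errors).
    """
    subs = sum(
        1
        for e in diff.events
        if e.kind == SUB and (minq is None or (e.qual is not None and e.qual < minq))
    )
    return subs + diff.n_indel + diff.n_clip


def terminal_mismatch(diff: AlignmentDiff, k: int = 2) -> bool:
    """True iff any substitution lies within the first or last ``k`` read bases."""
    if k < 1:
        raise ValueError("k must be >= 1")
    L = diff.read.read_length
    return any(
        e.kind == SUB and (e.read_offset < k or e.read_offset >= L - k)
        for e in diff.events
    )
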