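"""Threshold-based SNP and small-indel calling from pileup columns.

Calls are made per column from empirically set thresholds on read depth,
base quality and allele frequency.  For heterozygous support, a called
allele with frequency below 0.9 must be backed by at least ``tnum`` reads,
while an allele at or above 0.9 needs only ``num``.  For indels, the
frequency denominator excludes reads whose alignment 3' terminus (including
soft-clipped ends) lies at the site — such reads end at the anchor and
cannot attest an indel that follows it, which preserves sensitivity in
low-coverage regions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .formats_io import (
    AlignedRead,
    PileupColumn,
    ReferenceGenome,
    pileup_from_reads,
)

__all__ = ["CallParams", "VariantCall", "call_snp", "call_indel",
           "suppress_near_indel", "call_variants"]


@dataclass
class CallParams:
    """Calling thresholds.

    num: minimum reads with a non-reference base at the site (default 2).
    freq: minimum frequency of the called allele (default 0.8).
    qual_ave: minimum mean base quality of non-reference bases, SNPs only.
    qual_base: minimum quality of an individual non-reference base.
    maxr: maximum reads covering non-reference alleles (unset by default;
        a practical choice is 3x the mean read depth).  When
        ``maxr_on_depth`` is set, maxr instead caps the total column depth.
    tnum: minimum reads supporting a heterozygous (<0.9 frequency) allele.
    """

    num: int = 2
    freq: float = 0.8
    qual_ave: float = 20.0
    qual_base: int = 3
    maxr: int | None = None
    tnum: int = 3
    het_boundary: float = 0.9
    maxr_on_depth: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.freq <= 1.0:
            raise ValueError("freq must be in (0, 1]")
        if self.num < 1 or self.tnum < 1:
            raise ValueError("num and tnum must be >= 1")


@dataclass(frozen=True)
class VariantCall:
    """A called SNP or indel.

    For deletions ``ref_allele`` holds the deleted bases and ``alt_allele``
    is '-'; for insertions the reverse.  ``pos`` is the substituted base for
    SNPs and the anchor base (the one preceding the event) for indels.
    """

    chrom: str
    pos: int
    type: str  # SNP / INS / DEL
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    alt_freq: float
    mean_alt_qual: float | None
    zygosity: str  # hom / het

    @property
    def is_indel(self) -> bool:
        return self.type in ("INS", "DEL")


def call_snp(column: PileupColumn, params: CallParams) -> VariantCall | None:
    """Evaluate the majority non-reference base allele at a column.

    Bases below ``qual_base`` are excluded from alt support before the
    majority allele is chosen; ties between equally supported non-reference
    alleles yield no call.  Ambiguous (N) reference positions are never
    called.
    """
    ref_base = column.ref_base
    if ref_base not in "ACGT":
        return None
    groups: dict[str, list] = defaultdict(list)
    for o in column.obs:
        if o.base in "ACGT" and o.base != ref_base:
            if o.qual is not None and o.qual < params.qual_base:
                continue
            groups[o.base].append(o)
    if not groups:
        return None
    best = max(groups.values(), key=len)
    if sum(1 for g in groups.values() if len(g) == len(best)) > 1:
        return None  # ambiguous majority
    alt_base = best[0].base
    alt_count = len(best)
    depth = column.depth
    if depth <= 0:
        return None
    alt_freq = alt_count / depth
    if params.maxr is not None:
        covered = depth if params.maxr_on_depth else alt_count
        if covered > params.maxr:
            return None
    if alt_freq < params.freq:
        return None
    quals = [o.qual for o in best if o.qual is not None]
    mean_q = sum(quals) / len(quals) if quals else 0.0
    if mean_q < params.qual_ave:
        return None
    if alt_freq >= params.het_boundary:
        if alt_count < params.num:
            return None
        zyg = "hom"
    else:
        if alt_count < params.tnum:
            return None
        zyg = "het"
    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        type="SNP",
        ref_allele=ref_base,
        alt_allele=alt_base,
        depth=depth,
        alt_count=alt_count,
        alt_freq=min(alt_freq, 1.0),
        mean_alt_qual=mean_q,
        zygosity=zyg,
    )


def call_indel(column: PileupColumn, params: CallParams) -> VariantCall | None:
    """Evaluate the majority indel allele at a column.

    Support counts reads carrying the identical indel allele.  The frequency
    denominator is the column depth minus the reads whose 3' termini
    (soft-clipped ends included) lie at the site.  ``qual_ave`` is not
    applied to indels.
    """
    if not column.indels:
        return None
    if column.ref_base not in "ACGT":
        return None
    groups: dict[tuple[str, int, str], int] = defaultdict(int)
    for io in column.indels:
        groups[(io.kind, io.length, io.seq)] += 1
    best_key = max(groups, key=lambda k: groups[k])
    best_count = groups[best_key]
    if sum(1 for v in groups.values() if v == best_count) > 1:
        return None
    if best_count < params.num:
        return None
    denom = column.depth - column.n_end3
    if denom <= 0:
        return None
    freq = best_count / denom
    if freq < params.freq:
        return None
    if params.maxr is not None:
        covered = column.depth if params.maxr_on_depth else best_count
        if covered > params.maxr:
            return None
    kind, length, seq = best_key
    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        type=kind,
        ref_allele=seq if kind == "DEL" else "-",
        alt_allele=seq if kind == "INS" else "-",
        depth=column.depth,
        alt_count=best_count,
        alt_freq=min(freq, 1.0),
        mean_alt_qual=None,
        zygosity="hom" if freq >= params.het_boundary else "het",
    )


def suppress_near_indel(calls: list[VariantCall], window: int = 3) -> list[VariantCall]:
    """Drop SNP calls within ``window`` bp of a homozygous indel call.

    Misaligned indels tend to spawn spurious substitutions nearby, so SNPs
    flanking a confidently homozygous indel are not trusted.  Heterozygous
    indels do not suppress, and indel calls are never dropped.
    """
    hom_indels: dict[str, list[int]] = defaultdict(list)
    for c in calls:
        if c.is_indel and c.zygosity == "hom":
            hom_indels[c.chrom].append(c.pos)
    out = []
    for c in calls:
        if c.type == "SNP" and any(
            abs(c.pos - p) <= window for p in hom_indels.get(c.chrom, [])
        ):
            continue
        out.append(c)
    return out


def call_variants(
    source: Iterable[PileupColumn] | list[AlignedRead],
    params: CallParams | None = None,
    ref: ReferenceGenome | None = None,
) -> list[VariantCall]:
    """Call SNPs and indels over a pileup stream or directly from reads.

    When ``source`` is a list of aligned reads, pileup columns are built
    internally (given ``ref``), making the SAM path equivalent to the pileup
    path on the same data.
    """
    if params is None:
        params = CallParams()
    src = source
    if isinstance(src, list) and src and isinstance(src[0], AlignedRead):
        if ref is None:
            raise ValueError("calling from reads requires the reference genome")
        src = pileup_from_reads(src, ref)
    calls: list[VariantCall] = []
    for col in src:
        snp = call_snp(col, params)
        if snp is not None:
            calls.append(snp)
        indel = call_indel(col, params)
        if indel is not None:
            calls.append(indel)
    calls.sort(key=lambda c: (c.chrom, c.pos, c.type))
    return suppress_near_indel(calls)
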