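"""Synthetic references and pre-aligned reads with controlled error content.

Reads are emitted already placed at their true positions, so pileups are
exact and no external aligner is needed.  The generator emulates the error
structure seen in real short-read data — a baseline substitution rate, an
error rate ramping up toward the read 3' end, and optional clusters of
low-quality errors in a chosen region — without modelling sequence-specific
chemistry.  Misalignment is modelled separately by injecting reads drawn
from a donor sequence with coordinates forged into a target region (the
"targeted alignment" scenario).

When a mutated genome plus its truth table is supplied, reads are drawn
from the ORIGINAL genome but expressed in mutated-reference coordinates,
with gapped CIGARs across the simulated indels — the frame in which
refinement and calling operate.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .formats_io import AlignedRead, ReferenceGenome, TruthTable

__all__ = [
    "ReadErrorProfile",
    "ErrorRecord",
    "random_genome",
    "generate_reads",
    "inject_foreign_reads",
]

_BASES = "ACGT"


def random_genome(
    lengths: dict[str, int] | int, seed: int = 0, gc: float = 0.5
) -> ReferenceGenome:
    """Uniform-composition random genome (one chromosome 'c1' when an int
    is given)."""
    if isinstance(lengths, int):
        lengths = {"c1": lengths}
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for c, n in lengths.items():
        idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
        seqs[c] = lut[idx].tobytes().decode("ascii")
    return ReferenceGenome(seqs)


@dataclass
class ReadErrorProfile:
    """Controls injected sequencing errors.

    ``base_error_rate`` is the per-base substitution probability at the 5'
    end; the rate grows linearly to ``base_error_rate * three_prime_ramp``
    at the 3' end (ramp >= 1, i.e. non-decreasing along the read).
    ``cluster`` = (chrom, start, end, errors_per_read) forces that many
    low-quality errors into every read overlapping the region.  Erroneous
    bases get ``qual_error``, correct bases ``qual_correct``.
    """

    base_error_rate: float = 0.0
    three_prime_ramp: float = 1.0
    cluster: tuple[str, int, int, int] | None = None
    qual_correct: int = 38
    qual_error: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0, 1]")
        if self.three_prime_ramp < 1.0:
            raise ValueError("three_prime_ramp must be >= 1 (non-decreasing)")


@dataclass(frozen=True)
class ErrorRecord:
    """Sidecar record of one injected error (original-genome coordinates)."""

    read_name: str
    mate: int
    chrom: str
    ref_pos: int
    read_offset: int
    orig_base: str
    new_base: str


# ---------------------------------------------------------------------------
# liftover of original-genome intervals onto the mutated reference

class _Liftover:
    """Per-chromosome map from original coordinates to mutated coordinates.

    Built from the truth table, whose records are stated in the calling
    frame: a truth DEL means the mutated reference gained bases (simulated
    insertion), a truth INS means it lost bases (simulated deletion).
    """

    def __init__(self, truth: TruthTable, chrom: str):
        # events: (orig_anchor, gain_k or -loss_k) sorted by anchor
        self.events: list[tuple[int, int]] = []
        for r in truth.records:
            if r.chrom != chrom:
                continue
            if r.type == "DEL":
                self.events.append((r.orig_pos, len(r.ref_allele)))
            elif r.type == "INS":
                self.events.append((r.orig_pos, -len(r.alt_allele)))
        self.events.sort()
        self.anchors = [a for a, _ in self.events]
        self.cum = np.cumsum([d for _, d in self.events]) if self.events else []

    def offset_after(self, i: int) -> int:
        return int(self.cum[i]) if i >= 0 else 0

    def map_pos(self, o: int) -> int | None:
        """Mutated coordinate of original position ``o`` (None if deleted)."""
        i = bisect_right(self.anchors, o - 1) - 1
        # events with anchor <= o-1 are fully upstream except a deletion
        # spanning o itself
        if i >= 0:
            a, d = self.events[i]
            if d < 0 and a < o <= a - d:  # inside a simulated deletion
                return None
        return o + self.offset_after(i)

    def lift_read(self, s: int, L: int) -> tuple[int, list[tuple[int, str]]] | None:
        """Alignment (mutated pos, CIGAR) of an original interval [s, s+L-1].

        Original bases falling inside simulated deletions become I ops
        (soft clips at the read ends); simulated insertions become D ops.
        Returns None if no base of the read maps.
        """
        e = s + L - 1
        ops: list[tuple[int, str]] = []

        def push(n: int, op: str) -> None:
            if n <= 0:
                return
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + n, op)
            else:
                ops.append((n, op))

        cur = s
        lo = bisect_right(self.anchors, s - 8)  # indels are <= 6 bp
        for idx in range(max(lo - 2, 0), len(self.events)):
            a, d = self.events[idx]
            if a > e:
                break
            if d > 0:  # simulated insertion after a: reads lack those bases
                if a < s or a >= e or a < cur - 1:
                    continue
                push(a - cur + 1, "M")
                push(d, "D")
                cur = a + 1
            else:  # simulated deletion of a+1..a+k: read bases have no home
                k = -d
                dl, dh = a + 1, a + k
                if dh < cur or dl > e:
                    continue
                if a >= cur:
                    push(a - cur + 1, "M")
                    push(min(dh, e) - dl + 1, "I")
                else:
                    push(min(dh, e) - cur + 1, "I")
                cur = min(dh, e) + 1
        push(e - cur + 1, "M")

        # unaligned read ends become soft clips
        if ops and ops[0][1] == "I":
            ops[0] = (ops[0][0], "S")
        if ops and ops[-1][1] == "I":
            ops[-1] = (ops[-1][0], "S")
        if not any(op == "M" for _, op in ops):
            return None
        first_aligned = s + (ops[0][0] if ops[0][1] == "S" else 0)
        pos = self.map_pos(first_aligned)
        if pos is None:
            return None
        return pos, ops


# ---------------------------------------------------------------------------
# read generation

def _ramp_rates(profile: ReadErrorProfile, L: int, reverse: bool) -> np.ndarray:
    """Per-stored-base error probability; position along the sequencing
    direction (3' end last for forward reads, first for reverse reads)."""
    frac = np.linspace(0.0, 1.0, L)
    if reverse:
        frac = frac[::-1]
    return profile.base_error_rate * (1.0 + (profile.three_prime_ramp - 1.0) * frac)


def generate_reads(
    genome: ReferenceGenome,
    depth: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    profile: ReadErrorProfile | None = None,
    seed: int = 0,
    align_to: tuple[ReferenceGenome, TruthTable] | None = None,
    read_group: str | None = None,
    name_prefix: str = "rp",
) -> tuple[list[AlignedRead], list[ErrorRecord]]:
    """Paired-end reads tiled to the target mean depth.

    Each record's placement is its true origin.  With ``align_to`` =
    (mutated genome, truth table), sequences still come from ``genome`` but
    coordinates and CIGARs are expressed against the mutated reference.
    Returns the reads plus a sidecar list of injected errors.
    """
    if profile is None:
        profile = ReadErrorProfile()
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    errors: list[ErrorRecord] = []
    base_arr = np.array(list(_BASES))

    for chrom, seq in genome.sequences.items():
        L = len(seq)
        min_insert = read_len
        if read_len > L or insert_mean > L:
            raise ValueError(
                f"{chrom}: read_len/insert_mean infeasible for length {L}"
            )
        n_pairs = int(round(depth * L / (2 * read_len)))
        lifter = _Liftover(align_to[1], chrom) if align_to is not None else None
        for i in range(n_pairs):
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(min_insert, min(insert, L))
            s1 = int(rng.integers(1, L - insert + 2))
            s2 = s1 + insert - read_len
            name = f"{name_prefix}_{chrom}_{i}"
            pair = []
            for mate, (start, strand) in enumerate(
                [(s1, "+"), (s2, "-")], start=1
            ):
                stored = list(seq[start - 1 : start + read_len - 1])
                quals = [profile.qual_correct] * read_len
                rates = _ramp_rates(profile, read_len, reverse=(strand == "-"))
                err_offsets = set(np.nonzero(rng.random(read_len) < rates)[0])
                if profile.cluster is not None:
                    cchrom, cs, ce, k = profile.cluster
                    if chrom == cchrom and start <= ce and start + read_len - 1 >= cs:
                        err_offsets |= set(
                            int(x)
                            for x in rng.choice(read_len, size=k, replace=False)
                        )
                for off in sorted(err_offsets):
                    orig = stored[off]
                    choices = [b for b in _BASES if b != orig]
                    new = choices[int(rng.integers(0, 3))]
                    stored[off] = new
                    quals[off] = profile.qual_error
                    errors.append(
                        ErrorRecord(
                            read_name=name,
                            mate=mate,
                            chrom=chrom,
                            ref_pos=start + off,
                            read_offset=off,
                            orig_base=orig,
                            new_base=new,
                        )
                    )
                if lifter is None:
                    pos, cigar = start, [(read_len, "M")]
                else:
                    lifted = lifter.lift_read(start, read_len)
                    if lifted is None:
                        pair = []
                        break
                    pos, cigar = lifted
                pair.append(
                    AlignedRead(
                        name=name,
                        chrom=chrom,
                        pos=pos,
                        strand=strand,
                        cigar=cigar,
                        seq="".join(stored),
                        quals=quals,
                        mapq=60,
                        read_group=read_group,
                        is_paired=True,
                        is_first_mate=(mate == 1),
                        mate_mapped=True,
                        mate_chrom=chrom,
                        mate_pos=0,
                        mate_strand="-" if mate == 1 else "+",
                        insert_size=insert if mate == 1 else -insert,
                    )
                )
            if len(pair) == 2:
                pair[0].mate_pos = pair[1].pos
                pair[1].mate_pos = pair[0].pos
                reads.extend(pair)
    for r in reads:
        r.validate()
    del base_arr
    return reads, errors


def inject_foreign_reads(
    native_reads: list[AlignedRead],
    donor_genome: ReferenceGenome,
    target_genome: ReferenceGenome,
    target_chrom: str,
    target_start: int,
    target_end: int,
    fraction: float,
    mismatch_floor: int = 3,
    seed: int = 0,
) -> tuple[list[AlignedRead], set[str]]:
    """Add misaligned reads: donor-derived sequence with coordinates forged
    into the target region, each guaranteed >= ``mismatch_floor``
    substitutions against the target reference.

    ``fraction`` is the share of foreign reads in the combined output (0.5
    doubles the read count).  Returns the combined list and the names of
    the foreign reads.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    from .mismatch_model import diff_read

    rng = np.random.default_rng(seed)
    read_len = native_reads[0].read_length if native_reads else 75
    n_foreign = int(round(fraction / (1.0 - fraction) * len(native_reads)))
    donor_chroms = list(donor_genome.sequences)
    target_seq = target_genome.sequences[target_chrom]
    out = list(native_reads)
    names: set[str] = set()
    for i in range(n_foreign):
        dc = donor_chroms[int(rng.integers(0, len(donor_chroms)))]
        dseq = donor_genome.sequences[dc]
        ds = int(rng.integers(1, len(dseq) - read_len + 2))
        stored = list(dseq[ds - 1 : ds + read_len - 1])
        pos = int(rng.integers(target_start, max(target_start, target_end - read_len + 1) + 1))
        # top up substitutions until the floor is guaranteed
        ref_window = target_seq[pos - 1 : pos + read_len - 1]
        n_sub = sum(1 for a, b in zip(stored, ref_window) if a != b)
        while n_sub < mismatch_floor:
            off = int(rng.integers(0, read_len))
            if stored[off] != ref_window[off]:
                continue
            stored[off] = [b for b in _BASES if b != ref_window[off]][
                int(rng.integers(0, 3))
            ]
            n_sub += 1
        name = f"foreign_{i}"
        names.add(name)
        read = AlignedRead(
            name=name,
            chrom=target_chrom,
            pos=pos,
            strand="+",
            cigar=[(read_len, "M")],
            seq="".join(stored),
            quals=[30] * read_len,
            mapq=30,
            is_paired=False,
        )
        assert diff_read(read, target_genome).n_sub >= mismatch_floor
        out.append(read)
    return out, names
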