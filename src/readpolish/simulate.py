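"""Reference-genome mutation simulation and truth-set evaluation.

SNPs and 1-6 bp indels are introduced at user-set rates (defaults: SNPs at
0.2% and indels at 0.02% of genome positions), apportioned across
chromosomes by length.  Substituted bases follow the empirical excess of
transitions: transition changes are drawn 4-fold more often than
transversion changes.  Indel lengths follow the empirical 1-6 bp spectrum
(66/17/7/7/2/1%), apportioned deterministically by largest remainder so the
realised histogram matches the weights exactly.

The truth table is expressed in mutated-reference coordinates — the frame
in which reads are aligned and variants called — so a simulator-inserted
segment is recorded as the deletion a caller would report, and vice versa.
The evaluator scores calls against truth: TPR = matched truth records /
truth records x 100; FPR = unmatched calls / total calls x 100, SNPs and
indels separately.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np

from .call import VariantCall
from .formats_io import ReferenceGenome, TruthRecord, TruthTable

__all__ = [
    "SimulateParams",
    "DEFAULT_INDEL_LENGTH_WEIGHTS",
    "apportion",
    "draw_snp",
    "mutate_genome",
    "invert_mutations",
    "evaluate",
]

DEFAULT_INDEL_LENGTH_WEIGHTS = {1: 0.66, 2: 0.17, 3: 0.07, 4: 0.07, 5: 0.02, 6: 0.01}

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = np.array(list("ACGT"))


@dataclass
class SimulateParams:
    """Simulator settings.

    Counts override rates when given.  ``titv_ratio`` r draws a transition
    with probability r/(r+1) so the realised transition:transversion count
    ratio equals r (the conventional 2:1 accounting corresponds to r=2).
    ``min_gap`` is the minimum number of unmutated bases kept between
    mutation footprints.
    """

    snp_rate: float = 0.002
    indel_rate: float = 0.0002
    snp_count: int | None = None
    indel_count: int | None = None
    titv_ratio: float = 4.0
    indel_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTH_WEIGHTS)
    )
    deterministic_lengths: bool = True
    min_gap: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be > 0")
        s = sum(self.indel_length_weights.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"indel_length_weights must sum to 1, got {s}")


def apportion(total: int, lengths: dict) -> dict:
    """Split ``total`` across keys proportionally to ``lengths`` by largest
    remainder; ties broken by insertion order of the mapping.  Sum of the
    result equals ``total`` exactly."""
    if total < 0:
        raise ValueError("total must be >= 0")
    if not lengths:
        raise ValueError("lengths must be non-empty")
    weight_sum = float(sum(lengths.values()))
    quotas = {k: total * v / weight_sum for k, v in lengths.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    shortfall = total - sum(counts.values())
    order = sorted(
        lengths.keys(),
        key=lambda k: (-(quotas[k] - counts[k]), list(lengths).index(k)),
    )
    for k in order[:shortfall]:
        counts[k] += 1
    return counts


def draw_snp(ref_base: str, rng: np.random.Generator, titv_ratio: float = 4.0) -> str:
    """Draw an alternative base: the transition partner with probability
    r/(r+1), each transversion partner with probability 1/(2(r+1))."""
    if ref_base not in "ACGT":
        raise ValueError(f"cannot substitute ambiguous base {ref_base!r}")
    p_ti = titv_ratio / (titv_ratio + 1.0)
    u = rng.random()
    if u < p_ti:
        return TRANSITION[ref_base]
    tv = TRANSVERSIONS[ref_base]
    return tv[0] if (u - p_ti) < (1.0 - p_ti) / 2.0 else tv[1]


# one placement request: (kind 'SNP'|'INS'|'DEL' in simulator frame, length)
_Placement = tuple[str, int]


def _place_mutations(
    seq: str,
    placements: list[_Placement],
    rng: np.random.Generator,
    min_gap: int,
    max_tries: int = 200,
) -> list[tuple[int, str, int]]:
    """Choose non-conflicting positions for all placements on one chromosome.

    Returns (position, kind, length) sorted by position.  A SNP occupies its
    base; an insertion its anchor base and the next; a deletion its anchor
    plus the deleted span.  Footprints are kept ``min_gap`` bases apart and
    never touch N runs or chromosome edges.
    """
    L = len(seq)
    taken: list[tuple[int, int]] = []  # footprints sorted by start

    def conflicts(fs: int, fe: int) -> bool:
        i = bisect_left(taken, (fs, fe))
        for j in (i - 1, i):
            if 0 <= j < len(taken):
                s, e = taken[j]
                if fs - min_gap <= e and fe + min_gap >= s:
                    return True
        return False

    out = []
    for kind, length in placements:
        placed = False
        for _ in range(max_tries):
            p = int(rng.integers(2, L))  # keep 1 bp off either edge
            if kind == "SNP":
                fs, fe = p, p
            elif kind == "INS":
                fs, fe = p, p + 1
            else:  # DEL: anchor p, deleting p+1..p+length
                fs, fe = p, p + length
            if fe > L - 1:
                continue
            if "N" in seq[fs - 2 : fe + 1]:  # footprint plus 1 bp margin
                continue
            if conflicts(fs, fe):
                continue
            insort(taken, (fs, fe))
            out.append((p, kind, length))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place all mutations: genome too small or too dense"
            )
    out.sort()
    return out


def mutate_genome(
    ref: ReferenceGenome, params: SimulateParams
) -> tuple[ReferenceGenome, TruthTable]:
    """Introduce SNPs and indels; return the mutated genome and truth table.

    Mutation counts are apportioned to chromosomes by length (largest
    remainder), indel lengths likewise apportioned over the length weights
    (exact histogram) unless ``deterministic_lengths`` is off, in which case
    lengths are sampled.  Insertions draw uniform A/C/G/T sequence;
    deletions remove reference bases.  Same seed, same output.
    """
    rng = np.random.default_rng(params.seed)
    lengths = ref.lengths
    total_len = sum(lengths.values())
    n_snp = (
        params.snp_count
        if params.snp_count is not None
        else round(params.snp_rate * total_len)
    )
    n_indel = (
        params.indel_count
        if params.indel_count is not None
        else round(params.indel_rate * total_len)
    )
    snp_per_chrom = apportion(n_snp, lengths)
    indel_per_chrom = apportion(n_indel, lengths)

    if params.deterministic_lengths:
        len_counts = apportion(n_indel, params.indel_length_weights)
        length_pool = [l for l, c in len_counts.items() for _ in range(c)]
    else:
        ws = params.indel_length_weights
        keys = list(ws)
        length_pool = list(
            rng.choice(keys, size=n_indel, p=[ws[k] for k in keys])
        )
    length_pool = [int(x) for x in length_pool]
    rng.shuffle(length_pool)

    mutated_seqs: dict[str, str] = {}
    records: list[TruthRecord] = []
    pool_at = 0
    for chrom in ref.sequences:
        seq = ref.sequences[chrom]
        placements: list[_Placement] = [("SNP", 1)] * snp_per_chrom[chrom]
        k = indel_per_chrom[chrom]
        for ln in length_pool[pool_at : pool_at + k]:
            kind = "INS" if rng.random() < 0.5 else "DEL"
            placements.append((kind, ln))
        pool_at += k
        rng.shuffle(placements)

        placed = _place_mutations(seq, placements, rng, params.min_gap)

        segments: list[str] = []
        cursor = 1  # 1-based next original position to copy
        offset = 0  # mutated minus original coordinate
        for p, kind, ln in placed:
            if kind == "SNP":
                segments.append(seq[cursor - 1 : p - 1])
                orig_base = seq[p - 1]
                new_base = draw_snp(orig_base, rng, params.titv_ratio)
                segments.append(new_base)
                records.append(
                    TruthRecord(
                        chrom=chrom,
                        pos=p + offset,
                        type="SNP",
                        ref_allele=new_base,
                        alt_allele=orig_base,
                        orig_pos=p,
                    )
                )
                cursor = p + 1
            elif kind == "INS":  # inserted into the mutated reference
                segments.append(seq[cursor - 1 : p])
                ins = "".join(_BASES[rng.integers(0, 4, ln)])
                segments.append(ins)
                # reads (original genome) lack these bases -> called as DEL
                records.append(
                    TruthRecord(
                        chrom=chrom,
                        pos=p + offset,
                        type="DEL",
                        ref_allele=ins,
                        alt_allele="-",
                        orig_pos=p,
                    )
                )
                offset += ln
                cursor = p + 1
            else:  # DEL: original bases p+1..p+ln absent from the mutated ref
                segments.append(seq[cursor - 1 : p])
                deleted = seq[p : p + ln]
                records.append(
                    TruthRecord(
                        chrom=chrom,
                        pos=p + offset,
                        type="INS",
                        ref_allele="-",
                        alt_allele=deleted,
                        orig_pos=p,
                    )
                )
                offset -= ln
                cursor = p + ln + 1
        segments.append(seq[cursor - 1 :])
        mutated_seqs[chrom] = "".join(segments)

    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = TruthTable(records)
    truth.validate()
    return ReferenceGenome(mutated_seqs), truth


def invert_mutations(mutated: ReferenceGenome, truth: TruthTable) -> ReferenceGenome:
    """Apply the truth records to the mutated genome, recovering the original.

    Truth records are written in the calling frame, i.e. they already
    describe the edit that turns the mutated reference back into the
    original genome (SNP: restore alt; DEL record: drop the bases the
    simulator inserted; INS record: restore the bases it deleted).
    """
    out: dict[str, str] = {}
    by_chrom: dict[str, list[TruthRecord]] = {}
    for r in truth.records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, seq in mutated.sequences.items():
        segments: list[str] = []
        cursor = 1
        for r in sorted(by_chrom.get(chrom, []), key=lambda x: x.pos):
            if r.type == "SNP":
                segments.append(seq[cursor - 1 : r.pos - 1])
                segments.append(r.alt_allele)
                cursor = r.pos + 1
            elif r.type == "DEL":  # mutated ref carries extra bases after anchor
                segments.append(seq[cursor - 1 : r.pos])
                cursor = r.pos + len(r.ref_allele) + 1
            else:  # INS: reads carry extra bases after anchor
                segments.append(seq[cursor - 1 : r.pos])
                segments.append(r.alt_allele)
                cursor = r.pos + 1
        segments.append(seq[cursor - 1 :])
        out[chrom] = "".join(segments)
    return ReferenceGenome(out)


def evaluate(
    calls: list[VariantCall], truth: TruthTable, kind: str = "SNP"
) -> tuple[float, float]:
    """Score calls of one class ('SNP' or 'INDEL') against the truth table.

    A call matches a truth record iff chromosome, position, type and alleles
    agree (for indels: type, length and sequence).  Returns (TPR %, FPR %).
    An empty truth set makes TPR undefined and raises; zero calls give
    FPR 0 with a warning.
    """
    kind = kind.upper()
    truth_recs = truth.by_type(kind)
    if not truth_recs:
        raise ValueError(f"no {kind} records in truth table; TPR undefined")
    if kind == "INDEL":
        sel = lambda c: c.is_indel  # noqa: E731
    else:
        sel = lambda c: c.type == kind  # noqa: E731
    sub_calls = [c for c in calls if sel(c)]
    truth_keys = {
        (r.chrom, r.pos, r.type, r.ref_allele, r.alt_allele) for r in truth_recs
    }
    call_keys = {
        (c.chrom, c.pos, c.type, c.ref_allele, c.alt_allele) for c in sub_calls
    }
    matched = len(truth_keys & call_keys)
    tpr = 100.0 * matched / len(truth_keys)
    if not call_keys:
        warnings.warn(f"no {kind} calls; FPR reported as 0")
        return tpr, 0.0
    fpr = 100.0 * (len(call_keys) - matched) / len(call_keys)
    return tpr, fpr
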