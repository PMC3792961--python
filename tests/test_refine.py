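"""Local realignment, error correction and read filtering."""

import numpy as np
import pytest

from readpolish.fixtures import (
    ReadErrorProfile,
    generate_reads,
    inject_foreign_reads,
    random_genome,
)
from readpolish.formats_io import ReferenceGenome, pileup_from_reads
from readpolish.mismatch_model import count_mismatches, diff_read
from readpolish.refine import (
    ERROR_CORRECTION,
    RefineParams,
    build_indel_catalog,
    error_correct,
    estimate_insert_stats,
    filter_reads,
    local_realign,
    refine_pipeline,
)

from conftest import make_read


class TestParams:
    def test_fnum_follows_the_1_7_fold_rule(self):
        assert RefineParams(num=2).resolved_fnum == 3
        assert RefineParams(num=4).resolved_fnum == 6
        assert RefineParams(num=2, fnum=4).resolved_fnum == 4

    def test_fpair_defaults_by_mode(self):
        assert not RefineParams(mode="basic").resolved_fpair
        assert RefineParams(mode=ERROR_CORRECTION).resolved_fpair

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RefineParams(num=2, fnum=1)
        with pytest.raises(ValueError):
            RefineParams(mfreq=1.5)
        with pytest.raises(ValueError):
            RefineParams(msamp={"s1": "diploid"})


class TestIndelCatalog:
    def test_shared_deletion_one_entry(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        reads = [
            make_read(name=f"r{i}", pos=91, cigar=[(10, "M"), (1, "D"), (10, "M")],
                      seq=seq[90:100] + seq[101:111])
            for i in range(2)
        ]
        cat = build_indel_catalog(reads, genome_20kb)
        assert len(cat) == 1
        (support,) = cat.entries[("c1", 100)].values()
        assert support == 2

    def test_no_indels_empty_catalog(self, clean_reads, genome_20kb):
        assert len(build_indel_catalog(clean_reads[:20], genome_20kb)) == 0

    def test_distinct_insertion_sequences_are_distinct_entries(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        reads = [
            make_read(name="a", pos=51, cigar=[(5, "M"), (2, "I"), (5, "M")],
                      seq=seq[50:55] + "AG" + seq[55:60]),
            make_read(name="b", pos=51, cigar=[(5, "M"), (2, "I"), (5, "M")],
                      seq=seq[50:55] + "AC" + seq[55:60]),
        ]
        cat = build_indel_catalog(reads, genome_20kb)
        assert len(cat) == 2
        assert set(cat.entries[("c1", 55)]) == {("INS", 2, "AG"), ("INS", 2, "AC")}


def _deletion_scenario():
    """A 2 bp deletion at c1:41-42 (anchor 40); one read carries it in its
    CIGAR, another spans it gapless and misaligns its 3' tail."""
    genome = random_genome(200, seed=77)
    seq = genome.sequences["c1"]
    carrier = make_read(
        name="carrier", pos=21, cigar=[(20, "M"), (2, "D"), (18, "M")],
        seq=seq[20:40] + seq[42:60],
    )
    # gapless read: 15 bases before the deletion, then 5 bases that belong
    # 2 bp further right
    gapless = make_read(name="gapless", pos=26, cigar=[(20, "M")],
                        seq=seq[25:40] + seq[42:47])
    return genome, carrier, gapless


def brute_force_min_count(read, genome, del_len=2):
    """Enumerate every placement of one deletion gap in the read (all split
    points, both anchorings) and return the minimal mismatch count."""
    best = count_mismatches(diff_read(read, genome))
    L = read.read_length
    for a in range(1, L):
        for start in (read.pos, read.pos - del_len):
            if start < 1:
                continue
            cand = read.copy(pos=start,
                             cigar=[(a, "M"), (del_len, "D"), (L - a, "M")])
            if cand.reference_end > len(genome.sequences["c1"]):
                continue
            best = min(best, count_mismatches(diff_read(cand, genome)))
    return best


class TestLocalRealign:
    def test_regap_at_catalog_deletion_reaches_brute_force_minimum(self):
        genome, carrier, gapless = _deletion_scenario()
        cat = build_indel_catalog([carrier, gapless], genome)
        d = diff_read(gapless, genome)
        before = count_mismatches(d)
        assert before >= 2  # misaligned 3' tail produces substitutions
        new, accepted = local_realign(gapless, d, cat, genome)
        after = count_mismatches(diff_read(new, genome))
        assert accepted
        assert after == 1  # the deletion itself is the only mismatch left
        assert after == brute_force_min_count(gapless, genome)
        assert new.seq == gapless.seq and new.quals == gapless.quals

    def test_no_events_returned_unchanged(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        read = make_read(pos=101, cigar=[(30, "M")], seq=seq[100:130])
        d = diff_read(read, genome_20kb)
        cat = build_indel_catalog([read], genome_20kb)
        new, accepted = local_realign(read, d, cat, genome_20kb)
        assert not accepted and new == read

    def test_worse_candidate_keeps_original(self):
        genome, carrier, _ = _deletion_scenario()
        seq = genome.sequences["c1"]
        # correctly aligned read with one substitution far from the indel:
        # any re-gap at the catalog deletion can only add mismatches
        s = list(seq[120:150])
        s[15] = "A" if s[15] != "A" else "C"
        read = make_read(name="ok", pos=121, cigar=[(30, "M")], seq="".join(s))
        cat = build_indel_catalog([carrier], genome)
        d = diff_read(read, genome)
        new, accepted = local_realign(read, d, cat, genome)
        assert new.cigar == read.cigar and new.pos == read.pos

    def test_multi_indel_reads_pass_through(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        read = make_read(
            pos=11, cigar=[(10, "M"), (1, "D"), (10, "M"), (1, "D"), (10, "M")],
            seq=seq[10:20] + seq[21:31] + seq[32:42],
        )
        d = diff_read(read, genome_20kb)
        cat = build_indel_catalog([read], genome_20kb)
        new, accepted = local_realign(read, d, cat, genome_20kb)
        assert not accepted

    def test_accepted_realignment_never_increases_count(self):
        """Property: across random mismatch-laden reads near a real indel,
        realignment output never has more mismatches than the input."""
        genome, carrier, _ = _deletion_scenario()
        seq = genome.sequences["c1"]
        rng = np.random.default_rng(5)
        cat = build_indel_catalog([carrier], genome)
        for _ in range(100):
            start = int(rng.integers(20, 45))
            L = 20
            s = list(seq[start - 1 : start + L - 1])
            for off in rng.choice(L, size=int(rng.integers(1, 5)), replace=False):
                s[off] = "ACGT"[int(rng.integers(0, 4))]
            read = make_read(pos=start, cigar=[(L, "M")], seq="".join(s))
            d = diff_read(read, genome)
            if d.n_sub == 0:
                continue
            before = count_mismatches(d)
            new, _ = local_realign(read, d, cat, genome)
            assert count_mismatches(diff_read(new, genome)) <= before


def _column_fixture(obs_spec, ref_base="A"):
    """Build one pileup column by synthesising reads of length 1.

    obs_spec: list of (base, qual) or (base, qual, read_group).
    """
    reads = []
    for i, spec in enumerate(obs_spec):
        base, qual, rg = (spec + (None,))[:3] if len(spec) == 2 else spec
        reads.append(
            make_read(name=f"o{i}", pos=5, cigar=[(1, "M")], seq=base,
                      quals=[qual], read_group=rg)
        )
    ref = ReferenceGenome({"c1": "CCCC" + ref_base + "CCCC"})
    return reads, ref


class TestErrorCorrect:
    def test_low_quality_singleton_corrected(self):
        reads, ref = _column_fixture([("A", 38)] * 4 + [("C", 5)])
        out, n = error_correct(reads, ref, RefineParams(mode=ERROR_CORRECTION))
        assert n == 1
        assert out[4].seq == "A"
        assert out[4].quals == [5]  # qualities untouched

    def test_high_quality_balanced_allele_untouched(self):
        reads, ref = _column_fixture([("A", 38), ("A", 38), ("C", 30), ("C", 30)])
        out, n = error_correct(reads, ref, RefineParams(mode=ERROR_CORRECTION))
        assert n == 0 and [r.seq for r in out] == ["A", "A", "C", "C"]

    def test_minority_non_reference_allele_corrected(self):
        reads, ref = _column_fixture(
            [("C", 30), ("C", 30), ("C", 30), ("G", 30)]
        )
        out, n = error_correct(reads, ref, RefineParams(mode=ERROR_CORRECTION))
        assert n == 1
        assert out[3].seq == "A"  # G -> ref
        assert [r.seq for r in out[:3]] == ["C", "C", "C"]  # majority retained

    def test_frequency_rule(self):
        reads, ref = _column_fixture([("A", 38)] * 8 + [("C", 30), ("C", 30)])
        params = RefineParams(mode=ERROR_CORRECTION, mfreq=0.3)
        out, n = error_correct(reads, ref, params)
        assert n == 2  # freq 0.2 < 0.3 despite q30

    def test_msamp_per_sample_thresholds(self):
        # sample s1 (homozygous): 3/5 non-ref = 0.6 < 0.8 -> corrected
        # sample s2 (heterozygous): 2/5 non-ref = 0.4 >= 0.3 -> kept
        spec = (
            [("C", 30, "s1")] * 3 + [("A", 38, "s1")] * 2
            + [("C", 30, "s2")] * 2 + [("A", 38, "s2")] * 3
        )
        reads, ref = _column_fixture(spec)
        params = RefineParams(
            mode=ERROR_CORRECTION, msamp={"s1": "homo", "s2": "het"}
        )
        out, n = error_correct(reads, ref, params)
        assert n == 3
        assert [r.seq for r in out[:3]] == ["A", "A", "A"]
        assert [r.seq for r in out[5:7]] == ["C", "C"]

    def test_msamp_requires_read_groups(self):
        reads, ref = _column_fixture([("A", 38), ("C", 30)])
        params = RefineParams(mode=ERROR_CORRECTION, msamp={"s1": "homo"})
        with pytest.raises(ValueError, match="read group"):
            error_correct(reads, ref, params)

    def test_corrections_only_rewrite_to_reference(self, genome_20kb):
        """Property: every edit turns a base into the reference base;
        reference-matching bases are never altered."""
        profile = ReadErrorProfile(base_error_rate=0.01, qual_error=5)
        reads, _ = generate_reads(
            genome_20kb, depth=10, read_len=50, insert_mean=160, insert_sd=10,
            profile=profile, seed=33,
        )
        reads = reads[:400]
        out, n = error_correct(reads, genome_20kb, RefineParams(mode=ERROR_CORRECTION))
        assert n > 0
        seq = genome_20kb.sequences["c1"]
        edited = 0
        for before, after in zip(reads, out):
            assert before.name == after.name
            for off, (b, a) in enumerate(zip(before.seq, after.seq)):
                if b != a:
                    edited += 1
                    ref_base = seq[before.pos - 1 + off]  # gapless fixture reads
                    assert a == ref_base and b != ref_base
        assert edited == n


class TestFilterReads:
    def _reads_with_subs(self, genome, spec):
        """spec: list of (name, n_subs); returns gapless 30 bp reads."""
        seq = genome.sequences["c1"]
        reads = []
        for i, (name, k) in enumerate(spec):
            start = 100 + 40 * i
            s = list(seq[start - 1 : start + 29])
            for off in range(k):
                s[3 + off] = "A" if s[3 + off] != "A" else "C"
            reads.append(make_read(name=name, pos=start, cigar=[(30, "M")],
                                   seq="".join(s)))
        return reads

    def test_num_threshold(self, genome_20kb):
        reads = self._reads_with_subs(genome_20kb, [("bad", 3), ("ok", 2)])
        kept, log = filter_reads(reads, genome_20kb, RefineParams(num=2))
        assert [r.name for r in kept] == ["ok"]
        assert log == [("bad/1", "num")]

    def test_fnum_removes_the_pair(self, genome_20kb):
        reads = self._reads_with_subs(genome_20kb, [("p", 2), ("p", 2)])
        for r, first in zip(reads, (True, False)):
            r.is_paired = True
            r.is_first_mate = first
            r.mate_mapped = True
        kept, log = filter_reads(
            reads, genome_20kb, RefineParams(num=2, discordant_filter=False)
        )
        assert kept == []
        assert {reason for _, reason in log} == {"fnum"}

    def test_double_clip_removed(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        read = make_read(pos=201, cigar=[(2, "S"), (20, "M"), (3, "S")],
                         seq="AA" + seq[200:220] + "AAA")
        kept, log = filter_reads([read], genome_20kb, RefineParams())
        assert kept == [] and log[0][1] == "double_clip"

    def test_more_than_two_indels_removed(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        read = make_read(
            pos=11,
            cigar=[(5, "M"), (1, "D"), (5, "M"), (1, "D"), (5, "M"), (1, "D"), (5, "M")],
            seq=seq[10:15] + seq[16:21] + seq[22:27] + seq[28:33],
        )
        kept, log = filter_reads([read], genome_20kb, RefineParams(num=5))
        assert kept == [] and log[0][1] == "many_indels"

    def test_terminal_mismatch_only_when_realign_off(self, genome_20kb):
        seq = genome_20kb.sequences["c1"]
        s = list(seq[300:330])
        s[0] = "A" if s[0] != "A" else "C"
        read = make_read(pos=301, cigar=[(30, "M")], seq="".join(s))
        kept, _ = filter_reads([read], genome_20kb, RefineParams(realign=True))
        assert kept == [read]
        kept, log = filter_reads([read], genome_20kb, RefineParams(realign=False))
        assert kept == [] and log[0][1] == "terminal"

    def test_discordant_mate_unmapped(self, genome_20kb, clean_reads):
        orphan = clean_reads[0].copy(mate_mapped=False)
        kept, log = filter_reads([orphan], genome_20kb, RefineParams())
        assert kept == [] and log[0][1] == "discordant"

    def test_discordant_long_insert(self, genome_20kb, clean_reads):
        reads = list(clean_reads[:200])
        stats = estimate_insert_stats(reads)
        stretched = reads[0].copy(insert_size=int(stats.mean + 6 * stats.sd))
        kept, log = filter_reads(
            reads + [stretched], genome_20kb, RefineParams()
        )
        removed = dict(log)
        assert f"{stretched.name}/1" in removed
        assert removed[f"{stretched.name}/1"] == "discordant"

    def test_mrate(self, genome_20kb):
        reads = self._reads_with_subs(genome_20kb, [("r", 2)])
        kept, log = filter_reads(
            reads, genome_20kb, RefineParams(num=5, mrate=0.05)
        )
        assert kept == [] and log[0][1] == "mrate"  # 2/30 > 0.05

    def test_fpair_propagates_to_the_mate(self, genome_20kb):
        reads = self._reads_with_subs(genome_20kb, [("p", 3), ("p", 0)])
        for r, first in zip(reads, (True, False)):
            r.is_paired = True
            r.is_first_mate = first
            r.mate_mapped = True
        kept, log = filter_reads(
            reads, genome_20kb,
            RefineParams(num=2, fpair=True, discordant_filter=False),
        )
        assert kept == []
        assert dict(log) == {"p/1": "num", "p/2": "fpair"}

    def test_monotone_in_num(self, genome_20kb):
        """Raising num (fnum following its default) never removes more."""
        profile = ReadErrorProfile(base_error_rate=0.02, qual_error=5)
        reads, _ = generate_reads(
            genome_20kb, depth=6, read_len=60, insert_mean=200, insert_sd=15,
            profile=profile, seed=13,
        )
        previous: set[tuple[str, bool]] | None = None
        for num in (0, 1, 2, 3, 5, 8):
            kept, _ = filter_reads(reads, genome_20kb, RefineParams(num=num))
            names = {(r.name, r.is_first_mate) for r in kept}
            if previous is not None:
                assert previous <= names
            previous = names


@pytest.fixture(scope="module")
def snp_fixture():
    """5 kb genome; reads carry one true SNP (all reads, high quality)
    plus scattered q2 singleton errors."""
    genome = random_genome(5_000, seed=101)
    snp_pos = 2_500
    seq = genome.sequences["c1"]
    alt = "A" if seq[snp_pos - 1] != "A" else "G"
    sample = ReferenceGenome({"c1": seq[: snp_pos - 1] + alt + seq[snp_pos:]})
    profile = ReadErrorProfile(base_error_rate=0.004, qual_error=2)
    reads, _ = generate_reads(
        sample, depth=18, read_len=60, insert_mean=200, insert_sd=15,
        profile=profile, seed=55,
    )
    return genome, reads, snp_pos, alt


class TestRefinePipeline:
    @staticmethod
    def _nonref_columns(reads, genome):
        cols = pileup_from_reads(reads, genome)
        return {
            c.pos
            for c in cols
            if any(o.base in "ACGT" and o.base != c.ref_base for o in c.obs)
        }

    def test_identity_input_unchanged(self, genome_20kb, clean_reads):
        result = refine_pipeline(clean_reads[:100], genome_20kb, RefineParams())
        assert result.reads == clean_reads[:100]
        assert result.summary["removed_by_reason"] == {}

    def test_error_correction_cleans_errors_keeps_snp(self, snp_fixture):
        genome, reads, snp_pos, alt = snp_fixture
        before = self._nonref_columns(reads, genome)
        result = refine_pipeline(
            reads, genome, RefineParams(mode=ERROR_CORRECTION)
        )
        after = self._nonref_columns(result.reads, genome)
        assert snp_pos in before and snp_pos in after  # true variant survives
        assert len(after) < len(before)  # spurious columns strictly decrease
        assert result.summary["bases_corrected"] > 0
        # the SNP column itself is untouched: every read still carries alt
        cols = {c.pos: c for c in pileup_from_reads(result.reads, genome)}
        col = cols[snp_pos]
        assert all(o.base == alt for o in col.obs if o.base in "ACGT")

    def test_basic_mode_removes_instead_of_correcting(self, snp_fixture):
        genome, reads, _, _ = snp_fixture
        basic = refine_pipeline(reads, genome, RefineParams(mode="basic"))
        heavy = [
            r for r in reads
            if count_mismatches(diff_read(r, genome)) > 2
        ]
        kept_names = {(r.name, r.is_first_mate) for r in basic.reads}
        assert heavy  # fixture does contain over-threshold reads
        for r in heavy:
            assert (r.name, r.is_first_mate) not in kept_names
        assert basic.summary["removed_by_reason"].get("num", 0) > 0

    def test_output_reads_subset_of_input_no_duplicates(self, snp_fixture):
        genome, reads, _, _ = snp_fixture
        result = refine_pipeline(reads, genome, RefineParams(mode=ERROR_CORRECTION))
        in_keys = {(r.name, r.is_first_mate) for r in reads}
        out_keys = [(r.name, r.is_first_mate) for r in result.reads]
        assert set(out_keys) <= in_keys
        assert len(out_keys) == len(set(out_keys))

    def test_injected_foreign_reads_preferentially_removed(self, genome_20kb):
        native, _ = generate_reads(
            genome_20kb, depth=10, read_len=60, insert_mean=200, insert_sd=15,
            seed=3,
        )
        native = [r for r in native if r.overlaps("c1", 4_000, 6_000)]
        donor = random_genome(20_000, seed=999)
        combined, foreign_names = inject_foreign_reads(
            native, donor, genome_20kb, "c1", 4_000, 6_000,
            fraction=0.4, mismatch_floor=5, seed=8,
        )
        result = refine_pipeline(combined, genome_20kb, RefineParams())
        kept = {(r.name, r.is_first_mate) for r in result.reads}
        foreign_kept = sum(1 for r in combined
                           if r.name in foreign_names
                           and (r.name, r.is_first_mate) in kept)
        native_kept = sum(1 for r in native if (r.name, r.is_first_mate) in kept)
        n_foreign = len(combined) - len(native)
        frac_foreign_removed = 1 - foreign_kept / n_foreign
        frac_native_removed = 1 - native_kept / len(native)
        assert frac_foreign_removed > frac_native_removed
        assert frac_foreign_removed == 1.0  # floor of 5 subs >> num=2
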