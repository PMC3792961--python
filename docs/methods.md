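# Methods

This note records the model and procedure each module implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Mismatch model

Differences between a read and the reference are found by direct
comparison of the read sequence with the corresponding reference region,
never via the MD tag, so alignments from any aligner can be processed.
CIGAR `=`/`X` runs are re-verified against the reference for the same
reason. The mismatch count of a read is

    count = #substitutions + #indel events + #soft-clipped ends,

i.e. each indel and each clipped end is one mismatch — a read carrying a
single deletion has only one further mismatch of headroom under a cap of
two. With the optional quality threshold `minq`, only substitutions whose
base quality is *below* `minq` are counted: a high-quality mismatch is
treated as a potential true variant rather than an error, so the count is
monotone non-decreasing in `minq` and the unthresholded count is its
supremum. A read base over reference N is neither a match nor a mismatch
(ambiguous reference positions are never evidence); a read N over a called
reference base counts as a substitution (an uncalled base is evidence
against the alignment). Adjacent substitutions stay separate events — no
MNP merging. Hard clips and `N` (skip) ops contribute nothing; `N`
advances the reference.

## Local realignment

The engine first catalogues every distinct indel allele observed in any
read's CIGAR (keyed by chromosome and the base preceding the event). A
read is a realignment candidate when it has at most one indel or one
soft-clipped end; gapless, unclipped reads must carry at least one
substitution (realigning clean reads only destabilises them). For each
catalogued indel overlapping the read span (± the indel length), two
single-gap candidates are generated from the full read sequence (soft
clips unfolded): one keeping the 5′ end anchored, one keeping the 3′ end
anchored — equivalently, shifting the 3′ or 5′ portion of the read by the
indel length. Whether the 5′ or 3′ portion should move is not decidable a
priori, so both are tried and the minimum kept. The best candidate is
accepted iff its mismatch count is less than or equal to the original's;
ties between candidates break by fewest substitution events, then leftmost
gap position (an arbitrary but deterministic order). Sequence and
qualities are never altered by realignment.

## Error correction

Correction operates on pileup columns built in memory from the realigned
reads. At a column with reference base R, each non-reference base allele X
is corrected (every X rewritten to R, qualities untouched) when any of:

* mean base quality of X's observations < `correct_minq` (default 10);
* frequency of X (observations of X / base observations at the column)
  < `mfreq` (default 0, i.e. disabled);
* several non-reference alleles coexist and X is not the most frequent
  (minority alleles at a mismatch site are noise; an exact tie corrects
  neither, since neither is "lower").

In pooled mode (`msamp`, a read-group → homozygous/heterozygous map
supplied by the user — the designation cannot be inferred from the data),
the frequency logic runs per read group with floors 0.8 (homozygous) and
0.3 (heterozygous): a true heterozygous allele at ≈0.5 within its sample
survives, while cross-sample leakage below the floor is corrected. The
quality rule remains global. Correction only ever rewrites substituted
bases *to* the reference; reference-matching bases, indels and soft clips
are never edited (indels and clips are only counted and filtered).

In error-correction mode the pipeline first removes reads whose mismatch
count exceeds 10% of their length (`precorrection_rate`), counting indels
and clips as one each for consistency with the filtering count; these
reads are too corrupt to correct safely and would poison column
frequencies.

## Filtering

A read is removed when: soft-clipped at both termini; more than two
indels; mismatch count (with `minq`, if set) > `num` (default 2); count /
read length > `mrate` (unset by default — the 10% rule above is a separate
fixed stage, not an `mrate` alias); pair total > `fnum` (default
floor(1.7·num), giving the paired default 3 — the only integerisation
consistent with the printed pair of defaults 2 and 3); a substitution
within the terminal 2 bp (only when realignment is disabled, since
realignment is the preferred remedy); or the pair is discordant — mate
unmapped, or |template length| > mean + 5 SD, with the statistics
estimated from all properly oriented mapped pairs of the input in a first
pass. With `fpair` (default on in error-correction mode), the surviving
mate of a removed read is removed too. The removal log records exactly one
reason per read, assigned in the order above.

## Calling

Per column, bases below `qual_base` (default 3) are excluded first, then
the majority non-reference allele is evaluated (a tie yields no call —
an ambiguous majority is evidence of noise, not of two variants). A SNP
call requires frequency ≥ `freq` (default 0.8, denominator = column
depth, deletion placeholders included), mean alt quality ≥ `qual_ave`
(default 20, SNPs only), alt support ≤ `maxr` when set (a cap against
collapsed-repeat pileups; a practical setting is 3× mean depth, and a
switch allows capping total depth instead), and support ≥ `num` when the
frequency is ≥ 0.9 (homozygous) or ≥ `tnum` = 3 below 0.9 (heterozygous).
Indel calls group observations by exact allele (type, length, sequence),
require support ≥ `num` and frequency ≥ `freq`, with denominator = depth −
(reads whose alignment 3′ terminus, trailing soft clips included, lies at
the site): a read ending at the anchor cannot attest an indel that follows
it, and excluding such reads preserves sensitivity at low coverage. The
"3′ terminus" is implemented as the rightmost aligned position of the read
— identical to the pileup `$` marker, which keeps the SAM-derived and
text-pileup paths exactly equivalent (a property the tests assert against
a samtools-generated pileup). Finally, SNPs within 3 bp of a homozygous
indel call are suppressed; heterozygous indels do not suppress. Columns
whose stated depth is zero, or with an ambiguous (N) reference base, are
never called.

Two pileup dialects are supported and must be named explicitly (the
classic 10-column consensus format with depth in column 8, and the
6-column mpileup format with depth in column 4) — the dialects are
column-ambiguous on short lines, so auto-detection is unsafe. Both the
stated depth column and a recount of parsed observations are exposed.

## Simulation

Mutation counts default to rates of 0.2% (SNPs) and 0.02% (indels) of
genome positions and are apportioned across chromosomes proportionally to
length by largest remainder (ties by chromosome order), so totals are
exact and seed-independent. Substituted bases draw the transition partner
with probability r/(r+1) where r = `titv_ratio` (default 4), making the
realised transition:transversion *count* ratio equal r; users preferring
the conventional two-transversion accounting (ratio 2) can set r = 2.
Indel lengths follow the 1–6 bp weights 0.66/0.17/0.07/0.07/0.02/0.01,
apportioned deterministically by largest remainder so the realised
histogram is exact and testable (a sampling mode is available behind
`deterministic_lengths=False`); insertion/deletion is an even coin flip
and insertion content is uniform over A/C/G/T.

Placement is rejection sampling: a mutation footprint (SNP base; indel
anchor plus inserted/deleted span) must lie at least `min_gap` bases from
every other footprint, off the chromosome edges, and not at or adjacent to
reference N runs. The default `min_gap` = 3 keeps simulated variants out
of each other's calling interactions — in particular, a simulated SNP can
never fall inside the caller's 3 bp indel-adjacency suppression window, so
simulator output measures the caller's thresholds rather than the
geometry of random collisions. A clustered-placement stress mode is
deliberately left to the fixtures module (error clusters) rather than the
simulator.

The truth table is written in **mutated-reference coordinates**, the frame
in which reads are aligned and variants called, and its alleles describe
the variant as a perfect caller would report it: a simulator-inserted
segment appears in reads as a deletion (and vice versa), and a SNP record
carries the mutated base as reference allele and the original base as
alternative. This convention makes evaluation a direct key match and makes
the truth table literally the edit script that inverts the mutated genome
back to the original (asserted byte-exactly in tests). A companion column
keeps original-genome coordinates for provenance.

TPR and FPR are computed per variant class: a call matches a truth record
iff chromosome, position, type and alleles agree; TPR = 100·matched/truth,
FPR = 100·unmatched calls/total calls. An empty truth set leaves TPR
undefined (an error); zero calls give FPR 0 with a warning.

## Synthetic reads (fixtures)

Paired-end reads are tiled to a target mean depth with normal insert
sizes and emitted pre-aligned at their true origins, so pileups are exact
and no aligner is involved. Injected substitution errors follow a
per-base rate rising linearly toward the read 3′ end (the dominant
pattern in real short-read data), get a low quality score, and are logged
to a sidecar that the tests reconcile exactly against the mismatch model.
A cluster specification forces a fixed number of low-quality errors into
every read overlapping a region (emulating clustered errors in
low-coverage regions), and `inject_foreign_reads` forges donor-derived
reads into a target window with a guaranteed minimum substitution count
(the targeted-alignment scenario). When reads from the original genome
are expressed against a mutated reference, a per-chromosome liftover maps
coordinates and builds gapped CIGARs: simulator insertions become `D`
ops, simulator deletions become `I` ops (soft clips when they hit a read
end), and reads that lose every aligned base are dropped.

What this generator does *not* emulate: sequence-specific error motifs,
GC-coverage bias, quality-score miscalibration, chimeric fragments, or
genuinely misplaced alignments beyond the explicit injection scenario.
Passing tests therefore demonstrate that the engine's rules behave as
specified under controlled error structure, not that any particular
accuracy level will be attained on real data.

## Problem sizes and numerics

The test suite runs on genomes of 5–200 kb at 6–30× depth, and the
distributional checks use a 10 Mb genome with 60,000 SNPs (transition
fraction within 3 standard errors of 0.8) and 10,000 indels (histogram
exact by construction) — sizes chosen so the full suite completes in a
few minutes on one CPU while keeping every statistical check
well-powered. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical simulator
and fixture output. Insert-size statistics need at least two proper pairs,
otherwise the insert-length discordance rule is skipped (mate-unmapped
discordance still applies). Indel frequencies are capped at 1.0 in the
reported call (the denominator adjustment can push raw ratios above 1 on
pathological stated depths).

## Known limitations

* Realignment considers one gap per read (reads with two or more indels
  are excluded, following the engine's own restriction) and only indels
  already observed in the input; a true indel supported by no gapped read
  cannot be recovered.
* The caller is single-sample and threshold-based: no genotype
  likelihoods, no joint calling, no structural variants (it is
  length-agnostic but untested beyond small indels).
* Error correction trusts the realigned pileup; systematic errors shared
  by most reads at a column (frequency near 1) are indistinguishable from
  variants and will not be corrected.
* The pooled-sample mode requires user-supplied homozygous/heterozygous
  designations per read group.
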