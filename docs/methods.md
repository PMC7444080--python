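# Methods

## Model

One original DNA molecule is tagged, before amplification, with a unique
structured UMI; every read carrying that UMI is an independent noisy
observation of the same molecule. The analysis therefore has two levels:

1. **Within a group** (one molecule): a true variant is expected in nearly
   every read, while sequencing errors are independent across reads. A
   call requires a consensus fraction of the group's reads.
2. **Across groups** (the population): each passing group contributes one
   molecule-level observation; the variant allele fraction is
   `supporting groups / eligible groups`, with a Wilson 95% interval.

Assumptions: UMIs are unique per molecule (the simulator enforces this by
sampling the structured-UMI space without replacement; in real data the
structured pattern plus the minimum-reads threshold suppress false
groups); sequencing errors are independent across reads; the dominant
consensus-resistant artifact is a polymerase error in the first barcoded
copy, which propagates to all reads of the molecule. Its expected count,
`n_groups × molecule_length × per_base_error`, is the method's noise
floor and is reported by `stats.expected_error_groups`.

## Pipeline stages

extract → group → align → per-group call → group filter → merge.

**UMI extraction.** The universal primer is located within a window of
1.5× (primer+UMI) length from the read start (both orientations) by
edit-distance search (edlib, infix mode) with at most
`max_primer_mismatches` (default 3) edits — Hamming matching would reject
most indel-bearing long reads. The next pattern-length bases are the UMI
candidate, accepted only if every fixed pattern base matches exactly
("high-confidence UMI"): the fixed bases (e.g. TG in `NNNNTGNNNN`) act as
a built-in quality check. Grouping is by exact UMI string; no
mismatch-neighbour merging is attempted, because satellite groups created
by UMI sequencing errors fall below the `min_reads` threshold anyway,
while merging risks fusing distinct molecules.

**Alignment.** A full dynamic program (no seeding): semi-global with free
end gaps on the reference; unaligned query ends are soft-clipped but
charged the same two-piece gap cost as an internal gap, so a read cannot
escape a large true deletion by clipping at it. The two-piece gap cost,
`min(gap_open + L·gap_extend, long_gap_open + L·long_gap_extend)` =
`min(4 + 2L, 24 + L/16)` with match +2 / mismatch −4, keeps 1-bp errors
expensive (cost 6) while a multi-kilobase deletion costs only ~24 + L/16 —
less than the matches its flanks earn — and therefore survives as a single
D run. The long-gap slope of 1/16 is the package's calibration: any slope
near 1 makes a 5-kb deletion cost more than its flanks can pay, which
would force split alignments. 1/16 is exactly representable in binary, so
accumulated and closed-form gap costs agree bit for bit and the jitted
kernel can be checked against an exhaustive oracle by strict equality.
Scores below `min_score_frac × match × read_length` (default fraction
0.25) are reported unmapped.

**Inversion discovery.** Poorly-aligned internal read segments (long I
runs, or X/I/D blocks bridged by ≤12-base accidental match runs with ≤75%
match content) are realigned to the reverse complement of the reference; a
minus-strand placement that scores ≥0.35 of the segment's maximum and
nests inside the read's plus-strand span is inversion evidence. A pure
deletion yields no candidate segment and a novel insertion fails the
minus-strand floor, so neither masquerades as an inversion.

**Per-group calling.**

- *SNVs*: at candidate positions (a non-reference base in ≥2 reads at
  ≥30% of covering reads), support is counted per read: a read showing the
  alt base counts for it; a read whose alignment represents the position
  as a deletion is resolved by local realignment (edit distance of its
  ±10-base window against the reference vs the alt-substituted window).
  Realignment may resolve such an abstention but never overrules a read
  that shows a concrete base — allowing it to would let correlated noise
  flip observed evidence, which measurably creates false positives. A call
  requires `consensus_fraction` (default 0.75) of covering reads and
  coverage ≥ `min_reads` (default 5): a 5-read group needs 4 concordant
  reads, which keeps the expected spurious SNV count per ~300 Nanopore-like
  groups well below one. The plain column-count caller (`call_snvs`)
  retains the simple rule and serves ensemble mode.
- *Small indels* (1–30 bp): per-read I/D runs, left-aligned (standard VCF
  normalisation), called at the same consensus fraction over covering
  reads. On Nanopore-like reads, recurrent 1-bp deletions in homopolymer
  context are an expected artifact class of this caller; they are reported
  honestly rather than suppressed, and are excluded from somatic *SNV*
  loads by definition.
- *SVs* (>30 bp; the boundary `min_sv_len=31` encodes "greater than 30"):
  per-read D runs, I runs and inversion evidence are clustered by kind
  with both breakpoints within `breakpoint_tol` (10 bp, absorbing
  alignment jitter around large gaps); a cluster is emitted at
  `sv_support_fraction` (default 0.6) of the group's reads, at the
  per-read median breakpoints. D/I runs explained by a read's inversion
  evidence are masked so an inversion is not double-reported as
  deletion+insertion; point calls inside the evidence span are suppressed
  when ≥1/3 of the group shows evidence, because base identity there is
  representation-dependent.

**Group filter.** A group is dropped when (a) mean read identity to the
group consensus — matches over the *full* read length, so clipped and
inserted bases count against — falls below `min_group_identity` (0.7);
(b) the same subset of ≥2 reads holds a minor substitution allele at more
positions than random error coincidence explains (threshold: the Poisson
99.9% quantile of `covered_length × error_rate²/3`, never below 3) — the
signature of two molecules colliding on one UMI; or (c) an SV-sized event
cluster has within-group support in (1/3, `sv_support_fraction`) — mixed
incompatible structures under one UMI. The coincidence-adaptive threshold
matters: a flat 3-position rule flags a quarter of clean 5-read groups on
multi-kilobase Nanopore amplicons, where any two reads share ~2 error
positions by chance.

**Merge.** SNVs and small indels merge on exact identity (after left
alignment); SVs merge by kind and breakpoints within `breakpoint_tol`
(single linkage). Classification: `target` if matching a user-supplied
target variant, `known` if in a user-supplied known-variant list,
otherwise `somatic`. The VCF (v4.2) carries one line per (variant,
supporting group) with `<UMI>_<readcount>` in the ID column; the final
filter on read depth, quality and VAF bounds is configurable and
permissive by default. All stages are deterministic; per-group work is
parallelisable with results independent of worker count (groups are
processed and reduced in sorted UMI order).

## Simulator

`umivar.simulate` emulates a spike-in experiment: molecules drawn from an
allele mix (SNV, deletion, insertion, inversion edits at preset
frequencies), independent somatic SNVs at a per-megabase rate placed
outside allele edits, a unique structured UMI per molecule, one
substitution-only polymerase pass on the barcoded copy (default per-base
rate 6e-6/168 ≈ 3.6e-8, a high-fidelity polymerase), then per-read
platform errors:

| platform | sub | ins | del | reads |
| --- | --- | --- | --- | --- |
| nanopore | 0.05 | 0.03 | 0.04 | full length, ~half reverse-complemented |
| illumina | 0.001 | 1e-4 | 1e-4 | paired 150-bp ends |
| pacbio | 0.002 | 0.003 | 0.003 | full length |

The Nanopore profile is a calibration choice for a high-error long-read
platform, not a measured instrument model. Reads per molecule follow a
negative binomial (default mean 8, dispersion 4, mirroring observed
median group sizes of 6–10 in comparable runs); scenario code may raise
the mean so that the *extracted* reads per eligible group match a target
median, since UMI extraction thins coverage by the acceptance fraction
(~46% under the Nanopore profile — within the 35–65% range seen in
practice). Not emulated: chimera formation, homopolymer-specific error
enrichment, quality-score variation (constant Q per platform), PCR errors
beyond the first copy. Passing tests on this generator therefore
demonstrate correct inference under idealised, independent errors; real
data add context-dependent error modes that the group filter and
consensus thresholds mitigate but the tests do not probe.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; 1-based only in VCF.
- Indels are left-aligned before comparison or merging; truth-to-call
  identity checks canonicalise both sides the same way because gap
  placement inside repeats is representation-ambiguous.
- Inversion breakpoints are ambiguous wherever segment edges coincide
  with their own reverse complement; calls are matched within
  `breakpoint_tol`.
- Alignment ties (forward vs reverse strand, equal DP paths) resolve
  deterministically: forward strand preferred, first-encountered optimum
  in the fixed traceback order.
- Empty inputs: an empty FASTQ yields a zero-count manifest and a
  header-only VCF; an empty group is an error; zero eligible groups is a
  warning, not a failure.
- The detection-power bound uses the exact ceiling with boundary
  verification (guarding floating-point edge cases on both sides).

## Problem sizes in the test suite

The stochastic validations run at scales chosen to exercise the claims on
one CPU: 20 seeded replicates of a 1:100 spike-in sized to ~270–280
eligible groups on a 168-bp amplicon (the scale at which the closed-form
power bound predicts ~94% detection); parameter recovery at 1e-2 and 1e-3
with ~270 and ~2400 eligible PacBio-like groups; a 6000-molecule
error-free run for the ensemble-mode negative control; and exhaustive
alignment-oracle comparison on 200 instances of ≤12 bases. The zero-error
end-to-end test uses an 80-molecule population carrying every supported
variant class on a 1.2-kb amplicon.

## Known limitations

- SNVs inside an inverted segment are not re-called against the inverted
  orientation; they are suppressed with the segment.
- Inversion consensus under Nanopore-level noise is conservative:
  per-read evidence detection is ~80%, so small or noise-flanked
  inversions can fall below the 0.6 support fraction and be missed
  (error-free recovery is exact).
- Small-indel calling on high-indel platforms produces occasional 1-bp
  homopolymer artifacts at 5-read depth; raising `min_reads` or
  `consensus_fraction` trades them against sensitivity.
- Exact-match grouping does not correct UMI sequencing errors; reads with
  corrupted UMIs are lost to satellite singletons (by design).
- The aligner is O(|query|·|reference|) and intended for amplicon-scale
  references (≤ ~10 kb), not genomes.
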