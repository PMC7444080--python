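"""Per-UMI-group consensus variant calling and population-level merging.

Each UMI group stands for one original molecule, so a true variant is
expected in (nearly) every read of its group, while sequencing errors are
scattered across reads. Calling therefore demands a consensus fraction of
the group's reads: an SNV needs ``consensus_fraction`` (default 0.75) of
the covering reads to agree on the alternative base; structural variants
(> 30 bp) need ``sv_support_fraction`` (default 0.6) of the group's reads
to exhibit a matching event within a breakpoint tolerance. Variant allele
fraction at the population level is supporting groups / eligible groups —
a molecule count, not a read count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy.stats import poisson

from .align import Alignment, InversionEvidence
from .errors import UmivarError
from .io import VcfEntry, make_vcf_id

__all__ = [
    "FilterParams",
    "Pileup",
    "GroupCalls",
    "PopulationVariant",
    "PopulationCallSet",
    "pileup_group",
    "call_snvs",
    "call_small_indels",
    "call_svs",
    "call_group",
    "group_filter",
    "merge_and_filter",
    "left_align_deletion",
    "left_align_insertion",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass
class FilterParams:
    """Thresholds governing group eligibility, calling and the final VCF.

    ``min_sv_len`` = 31 encodes the "> 30 bp" structural-variant boundary;
    events of 1-30 bases are small indels. ``breakpoint_tol`` absorbs
    alignment jitter around large gaps when matching SVs within and across
    groups.
    """

    min_reads: int = 5
    consensus_fraction: float = 0.75
    min_sv_len: int = 31
    sv_support_fraction: float = 0.6
    min_group_identity: float = 0.7
    breakpoint_tol: int = 10
    # population-level VCF filter
    min_depth: int = 5
    min_qual: float = 0.0
    vaf_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("consensus_fraction", "sv_support_fraction", "min_group_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise UmivarError(f"{name} must be in (0, 1]")
        if self.min_sv_len < 1:
            raise UmivarError("min_sv_len must be >= 1")


@dataclass
class Pileup:
    """Per-position base/deletion counts for one UMI group.

    ``counts`` is a 5 x L array (A, C, G, T, deletion); ``insertions`` maps
    the reference position *preceding* an insertion to a Counter of
    inserted sequences. ``depth`` counts reads presenting a base (deletions
    excluded).
    """

    counts: np.ndarray
    insertions: dict[int, Counter]
    n_reads: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts[:4].sum(axis=0)

    @property
    def coverage(self) -> np.ndarray:
        """Reads whose alignment spans each position (bases + deletions)."""
        return self.counts.sum(axis=0)


def pileup_group(alignments: list[Alignment], reference: str) -> Pileup:
    """Tally base/deletion counts from CIGAR walks of one group's reads.

    Soft-clipped bases are ignored; insertions are keyed to the position
    preceding them.
    """
    if not alignments:
        raise UmivarError("cannot pile up an empty group")
    L = len(reference)
    counts = np.zeros((5, L), dtype=np.int32)
    insertions: dict[int, Counter] = defaultdict(Counter)
    for aln in alignments:
        qpos = 0
        rpos = aln.ref_start
        for op, n in aln.cigar_tuples():
            if op in "=X":
                seg = aln.query[qpos : qpos + n]
                codes = np.fromiter(
                    (_CODE.get(b, -1) for b in seg), dtype=np.int64, count=n
                )
                valid = codes >= 0
                np.add.at(
                    counts, (codes[valid], np.arange(rpos, rpos + n)[valid]), 1
                )
                qpos += n
                rpos += n
            elif op == "D":
                counts[4, rpos : rpos + n] += 1
                rpos += n
            elif op == "I":
                insertions[rpos - 1][aln.query[qpos : qpos + n]] += 1
                qpos += n
            elif op == "S":
                qpos += n
    return Pileup(counts, dict(insertions), len(alignments))


def call_snvs(
    pileup: Pileup, reference: str, params: FilterParams
) -> list[tuple[int, str, str, float]]:
    """Consensus SNVs: at each position with depth >= min_reads, call the
    alternative base whose fraction of the base-presenting reads reaches
    ``consensus_fraction``. At most one SNV per position."""
    depth = pileup.depth
    eligible = np.nonzero(depth >= params.min_reads)[0]
    if len(eligible) == 0:
        return []
    top = pileup.counts[:4, eligible].argmax(axis=0)
    calls = []
    for pos, b in zip(eligible, top):
        ref_base = reference[pos]
        alt = _BASES[b]
        if alt == ref_base:
            continue
        frac = pileup.counts[b, pos] / depth[pos]
        if frac >= params.consensus_fraction:
            calls.append((int(pos), ref_base, alt, float(frac)))
    return calls


def _query_window(aln: Alignment, lo: int, hi: int) -> str:
    """Read bases aligned within reference window [lo, hi)."""
    qpos = 0
    rpos = aln.ref_start
    out = []
    for op, n in aln.cigar_tuples():
        if op in "=X":
            for k in range(n):
                if lo <= rpos + k < hi:
                    out.append(aln.query[qpos + k])
            qpos += n
            rpos += n
        elif op == "D":
            rpos += n
        elif op == "I":
            if lo < rpos <= hi:
                out.append(aln.query[qpos : qpos + n])
            qpos += n
        elif op == "S":
            qpos += n
        if rpos >= hi:
            break
    return "".join(out)


def refine_snvs(
    alignments: list[Alignment],
    pileup: Pileup,
    reference: str,
    params: FilterParams,
    window: int = 10,
) -> list[tuple[int, str, str, float]]:
    """Consensus SNVs confirmed by per-read local realignment.

    Column counts alone under-call true SNVs on indel-noisy reads: the
    aligner sometimes re-represents a mismatching alt base as a deletion,
    draining the column. At candidate positions (a non-reference base in
    >= 2 reads at >= 30% of the covering reads) each deletion-representing
    read is therefore re-scored: its bases around the position are
    compared, by edit distance, against the reference window and the
    alt-substituted window, and the read is counted for the alt when the
    alt window is strictly closer. Reads showing a concrete base keep
    their column identity — realignment may resolve an abstention, never
    overrule an observed base. The alt is called when (shown + resolved)
    support reaches ``consensus_fraction`` of the covering reads.
    """
    import edlib

    counts = pileup.counts
    coverage = pileup.coverage  # includes deletion-representing reads
    L = len(reference)
    alt_counts = counts[:4].copy()
    for i, base in enumerate(reference):
        code = _CODE.get(base)
        if code is not None:
            alt_counts[code, i] = 0
    top_alt = alt_counts.argmax(axis=0)
    top_n = alt_counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            coverage > 0, (top_n + counts[4]) / np.maximum(coverage, 1), 0.0
        )
    candidates = np.nonzero(
        (coverage >= params.min_reads) & (top_n >= 2) & (frac >= 0.3)
    )[0]
    if len(candidates) == 0:
        return []
    mat = _base_matrix(alignments, L)
    calls = []
    for pos in candidates:
        alt_code = int(top_alt[pos])
        alt = _BASES[alt_code]
        lo, hi = max(0, int(pos) - window), min(L, int(pos) + window + 1)
        ref_win = reference[lo:hi]
        alt_win = ref_win[: pos - lo] + alt + ref_win[pos - lo + 1 :]
        support = 0
        covering = 0
        for r, aln in enumerate(alignments):
            shown = mat[r, pos]
            if shown < 0:
                continue
            covering += 1
            if shown == alt_code:
                support += 1
            elif shown == 4:  # deletion-represented: resolve by realignment
                sub = _query_window(aln, lo, hi)
                if not sub:
                    continue
                d_ref = edlib.align(sub, ref_win, mode="NW")["editDistance"]
                d_alt = edlib.align(sub, alt_win, mode="NW")["editDistance"]
                if d_alt < d_ref:
                    support += 1
        if covering >= params.min_reads and support / covering >= params.consensus_fraction:
            calls.append((int(pos), reference[pos], alt, support / covering))
    return calls


def left_align_deletion(reference: str, pos: int, length: int) -> int:
    """Shift a deletion of reference[pos:pos+length] to its leftmost
    score-equivalent position (standard VCF normalization)."""
    while pos > 0 and reference[pos - 1] == reference[pos + length - 1]:
        pos -= 1
    return pos


def left_align_insertion(reference: str, pos: int, seq: str) -> tuple[int, str]:
    """Left-align an insertion placed after reference position ``pos``."""
    while pos >= 0 and seq and reference[pos] == seq[-1]:
        seq = reference[pos] + seq[:-1]
        pos -= 1
    return pos, seq


def _read_indel_events(
    aln: Alignment, reference: str
) -> list[tuple[str, int, int, str]]:
    """Per-read indel events as (kind, pos, length, seq), left-aligned.
    Deletion pos is the first deleted base; insertion pos the base the
    insertion follows."""
    events = []
    qpos = 0
    rpos = aln.ref_start
    for op, n in aln.cigar_tuples():
        if op in "=X":
            qpos += n
            rpos += n
        elif op == "D":
            pos = left_align_deletion(reference, rpos, n)
            events.append(("deletion", pos, n, ""))
            rpos += n
        elif op == "I":
            seq = aln.query[qpos : qpos + n]
            pos, seq = left_align_insertion(reference, rpos - 1, seq)
            events.append(("insertion", pos, n, seq))
            qpos += n
        elif op == "S":
            qpos += n
    return events


def _masked_by_inversion(
    kind: str, pos: int, length: int,
    inversion: InversionEvidence | None, read_events: dict,
) -> bool:
    """True when a D/I run is part of the I+D representation of an
    inversion already explained by minus-strand evidence."""
    if inversion is None:
        return False
    if kind == "deletion":
        s, e = pos, pos + length
        iv_s, iv_e = inversion.ref_interval
        overlap = min(e, iv_e) - max(s, iv_s)
        return overlap > 0.5 * length
    # insertion: compare against the evidence's query interval length
    iv_len = inversion.query_interval[1] - inversion.query_interval[0]
    return abs(length - iv_len) <= 0.5 * iv_len


def call_small_indels(
    alignments: list[Alignment],
    pileup: Pileup,
    reference: str,
    params: FilterParams,
    inversions: dict[str, InversionEvidence] | None = None,
) -> list[tuple[int, str, int, str, float]]:
    """Consensus small indels (1 .. min_sv_len-1 bases), left-aligned.

    Returns (pos, kind, length, sequence, support_fraction); support is the
    fraction of reads covering the position that carry the identical event.
    """
    inversions = inversions or {}
    tally: Counter = Counter()
    for aln in alignments:
        for kind, pos, length, seq in _read_indel_events(aln, reference):
            if length >= params.min_sv_len:
                continue
            if _masked_by_inversion(kind, pos, length, inversions.get(aln.read_id), {}):
                continue
            tally[(kind, pos, length, seq)] += 1
    coverage = pileup.coverage
    calls = []
    for (kind, pos, length, seq), count in sorted(tally.items(), key=lambda kv: kv[0][1]):
        cov = int(coverage[min(pos, len(reference) - 1)])
        if cov < params.min_reads:
            continue
        frac = count / cov
        if frac >= params.consensus_fraction:
            calls.append((pos, kind, length, seq, float(frac)))
    return calls


def _cluster_events(
    events: list[tuple], tol: int
) -> list[list[tuple]]:
    """Single-linkage clustering of (kind, a, b, ...) events: two events
    link when kinds match and both coordinates are within ``tol``."""
    parent = list(range(len(events)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            if events[i][0] != events[j][0]:
                continue
            if abs(events[i][1] - events[j][1]) <= tol and abs(
                events[i][2] - events[j][2]
            ) <= tol:
                parent[find(i)] = find(j)
    clusters: dict[int, list[tuple]] = defaultdict(list)
    for i, e in enumerate(events):
        clusters[find(i)].append(e)
    return list(clusters.values())


def call_svs(
    alignments: list[Alignment],
    inversions: dict[str, InversionEvidence],
    reference: str,
    params: FilterParams,
) -> list[tuple[str, int, int, str, float]]:
    """Consensus structural variants (>= min_sv_len) for one group.

    Per-read events — D runs (deletions), I runs (insertions) and inversion
    evidence — are clustered by kind and breakpoints within
    ``breakpoint_tol``; a cluster is emitted when it is supported by at
    least ``sv_support_fraction`` of the group's reads, at the per-read
    median breakpoints. Returns (kind, start, end_or_len, seq, support).
    For insertions the second coordinate is the inserted length.
    """
    n_reads = len(alignments)
    events: list[tuple] = []  # (kind, a, b, seq, read_id)
    for aln in alignments:
        inv = inversions.get(aln.read_id)
        for kind, pos, length, seq in _read_indel_events(aln, reference):
            if length < params.min_sv_len:
                continue
            if _masked_by_inversion(kind, pos, length, inv, {}):
                continue
            if kind == "deletion":
                events.append(("deletion", pos, pos + length, "", aln.read_id))
            else:
                events.append(("insertion", pos, length, seq, aln.read_id))
        if inv is not None:
            s, e = inv.ref_interval
            events.append(("inversion", s, e, "", aln.read_id))
    calls = []
    for cluster in _cluster_events(events, params.breakpoint_tol):
        readers = {e[4] for e in cluster}
        frac = len(readers) / n_reads
        if frac < params.sv_support_fraction:
            continue
        kind = cluster[0][0]
        a = int(median(e[1] for e in cluster))
        b = int(median(e[2] for e in cluster))
        seq = ""
        if kind == "insertion":
            with_seq = sorted(cluster, key=lambda e: (len(e[3]), e[3]))
            seq = with_seq[len(with_seq) // 2][3]
        calls.append((kind, a, b, seq, float(frac)))
    calls.sort(key=lambda c: (c[1], c[0]))
    return calls


@dataclass
class GroupCalls:
    """All consensus calls of one UMI group."""

    umi: str
    read_count: int
    snvs: list[tuple[int, str, str, float]] = field(default_factory=list)
    small_indels: list[tuple[int, str, int, str, float]] = field(default_factory=list)
    svs: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    pass_filter: bool = True
    mean_identity: float = 1.0
    filter_reason: str = ""


def _mean_identity(alignments: list[Alignment], consensus: np.ndarray) -> float:
    """Mean per-read fraction of bases matching the group consensus.

    The denominator is the full read length: soft-clipped and inserted
    bases count against identity, so a read whose corruption the aligner
    absorbed into clips and gaps still scores low."""
    idents = []
    for aln in alignments:
        qpos = 0
        rpos = aln.ref_start
        matches = 0
        for op, n in aln.cigar_tuples():
            if op in "=X":
                for k in range(n):
                    code = _CODE.get(aln.query[qpos + k], -1)
                    if code >= 0 and code == consensus[rpos + k]:
                        matches += 1
                qpos += n
                rpos += n
            elif op == "D":
                rpos += n
            elif op in "IS":
                qpos += n
        if qpos:
            idents.append(matches / qpos)
    return float(np.mean(idents)) if idents else 0.0


def call_group(
    umi: str,
    alignments: list[Alignment],
    inversions: dict[str, InversionEvidence],
    reference: str,
    params: FilterParams,
) -> GroupCalls:
    """Run the full per-group calling stack (pileup -> SNVs, small indels,
    SVs) and annotate the group with its filter status."""
    pileup = pileup_group(alignments, reference)
    calls = GroupCalls(umi=umi, read_count=len(alignments))
    calls.snvs = refine_snvs(alignments, pileup, reference, params)
    calls.small_indels = call_small_indels(
        alignments, pileup, reference, params, inversions
    )
    calls.svs = call_svs(alignments, inversions, reference, params)
    # base identity inside a putative inverted segment is unreliable (reads
    # represent it as mismatches or I+D interchangeably): when a sizeable
    # fraction of the group shows inversion evidence, suppress point calls
    # within the evidence span
    if len(inversions) >= max(2, len(alignments) / 3):
        spans = [ev.ref_interval for ev in inversions.values()]
        lo = min(s for s, _ in spans) - params.breakpoint_tol
        hi = max(e for _, e in spans) + params.breakpoint_tol
        calls.snvs = [s for s in calls.snvs if not (lo <= s[0] < hi)]
        calls.small_indels = [
            d for d in calls.small_indels if not (lo <= d[0] < hi)
        ]
    _annotate_filter(calls, alignments, inversions, pileup, reference, params)
    return calls


def _base_matrix(alignments: list[Alignment], L: int) -> np.ndarray:
    """Reads x reference-positions base-code matrix (-1 uncovered, 0-3
    bases A/C/G/T, 4 deletion)."""
    mat = np.full((len(alignments), L), -1, dtype=np.int8)
    for r, aln in enumerate(alignments):
        qpos = 0
        rpos = aln.ref_start
        for op, n in aln.cigar_tuples():
            if op in "=X":
                for k in range(n):
                    mat[r, rpos + k] = _CODE.get(aln.query[qpos + k], -1)
                qpos += n
                rpos += n
            elif op == "D":
                mat[r, rpos : rpos + n] = 4
                rpos += n
            elif op in "IS":
                qpos += n
    return mat


def _annotate_filter(
    calls: GroupCalls,
    alignments: list[Alignment],
    inversions: dict[str, InversionEvidence],
    pileup: Pileup,
    reference: str,
    params: FilterParams,
) -> None:
    consensus = pileup.counts[:4].argmax(axis=0)
    calls.mean_identity = _mean_identity(alignments, consensus)
    if calls.mean_identity < params.min_group_identity:
        calls.pass_filter = False
        calls.filter_reason = (
            f"mean read-to-consensus identity {calls.mean_identity:.3f} "
            f"< {params.min_group_identity}"
        )
        return
    # UMI-collision evidence: two disjoint read subsets, each internally
    # consistent, disagreeing at several positions. A position is
    # suspicious when a minor substitution allele is held by >= 2 reads at
    # >= 30% of the base-presenting depth; a collision requires the *same*
    # read subset to hold the minor allele at more positions than random
    # error coincidence explains (independent errors land in different
    # reads; the threshold is the Poisson 99.9% quantile of the expected
    # same-pair coincidences, never below 3). Positions inside inversion
    # evidence are excluded — reads may represent an inverted segment as
    # either mismatches or an I+D pair, which is not a collision. So are
    # single-base deletion errors, too frequent on noisy long reads.
    mat = _base_matrix(alignments, len(reference))
    base_counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
    depth = base_counts.sum(axis=0)
    order = np.argsort(base_counts, axis=0)
    second_base = order[-2]
    second = np.take_along_axis(base_counts, order[-2:-1], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(depth > 0, second / np.maximum(depth, 1), 0.0)
    candidate = (depth >= params.min_reads) & (second >= 2) & (minor_frac >= 0.3)
    for ev in inversions.values():
        s, e = ev.ref_interval
        pad = params.breakpoint_tol
        candidate[max(0, s - pad) : e + pad] = False
    suspicious = np.nonzero(candidate)[0]
    subset_hits: Counter = Counter()
    for pos in suspicious:
        readers = frozenset(np.nonzero(mat[:, pos] == second_base[pos])[0].tolist())
        if len(readers) >= 2:
            subset_hits[readers] += 1
    if subset_hits:
        err = max(0.0, 1.0 - calls.mean_identity)
        covered = int((depth >= params.min_reads).sum())
        expect_pair = covered * err * err / 3.0
        threshold = max(3.0, poisson.ppf(0.999, expect_pair) + 1)
        if max(subset_hits.values()) >= threshold:
            calls.pass_filter = False
            calls.filter_reason = (
                "coherent minor read subset at "
                f"{max(subset_hits.values())} positions (UMI collision)"
            )
            return
    # structural ambiguity: an SV-sized event cluster supported by a
    # middling fraction of reads — two incompatible molecules under one UMI
    n_reads = len(alignments)
    events: list[tuple] = []
    for aln in alignments:
        inv = inversions.get(aln.read_id)
        for kind, pos, length, seq in _read_indel_events(aln, reference):
            if length < params.min_sv_len:
                continue
            if _masked_by_inversion(kind, pos, length, inv, {}):
                continue
            if kind == "deletion":
                events.append(("deletion", pos, pos + length, "", aln.read_id))
            else:
                events.append(("insertion", pos, length, seq, aln.read_id))
    for cluster in _cluster_events(events, params.breakpoint_tol):
        frac = len({e[4] for e in cluster}) / n_reads
        if 1 / 3 < frac < params.sv_support_fraction:
            calls.pass_filter = False
            calls.filter_reason = (
                f"ambiguous SV support {frac:.2f} (mixed molecules under one UMI)"
            )
            return


def group_filter(groups: list[GroupCalls], params: FilterParams) -> list[GroupCalls]:
    """Keep only groups flagged pass_filter by :func:`call_group`."""
    return [g for g in groups if g.pass_filter]


def call_ensemble(
    alignments: list[Alignment], reference: str, params: FilterParams
) -> list[tuple[int, str, str, float]]:
    """Ensemble-mode SNV calling: pool every read into one pileup and apply
    the same consensus rule, ignoring UMIs. This is the negative control
    for rare variants — a sub-percent allele can never reach the consensus
    fraction of a pooled pileup, which is exactly why per-molecule grouping
    is needed."""
    if not alignments:
        return []
    pileup = pileup_group(alignments, reference)
    return call_snvs(pileup, reference, params)


@dataclass
class PopulationVariant:
    kind: str
    pos: int  # 0-based; deletion/inversion start, snv position, insertion anchor
    end: int  # exclusive end for deletion/inversion; pos+1 for snv; length for ins
    ref: str
    alt: str
    supporting_umis: list[str]
    total_groups: int
    class_: str = "somatic"

    @property
    def support(self) -> int:
        return len(self.supporting_umis)

    @property
    def vaf(self) -> float:
        return self.support / self.total_groups

    def key(self) -> tuple:
        if self.kind == "snv":
            return ("snv", self.pos, self.alt)
        if self.kind == "insertion":
            return ("insertion", self.pos, self.alt)
        return (self.kind, self.pos, self.end)


@dataclass
class PopulationCallSet:
    variants: list[PopulationVariant]
    total_groups: int

    def by_class(self, class_: str) -> list[PopulationVariant]:
        return [v for v in self.variants if v.class_ == class_]

    def __len__(self) -> int:
        return len(self.variants)


def _match_target(variant: PopulationVariant, target: dict, tol: int) -> bool:
    if target.get("kind", "snv") != variant.kind:
        return False
    if variant.kind == "snv":
        return variant.pos == target["pos"] and variant.alt == target.get(
            "alt", variant.alt
        )
    return (
        abs(variant.pos - target["pos"]) <= tol
        and abs(variant.end - target.get("end", variant.end)) <= tol
    )


def merge_and_filter(
    groups: list[GroupCalls],
    reference: str,
    params: FilterParams,
    reference_name: str = "amplicon",
    known_variants: list[dict] | None = None,
    target_variant: dict | None = None,
) -> tuple[PopulationCallSet, list[VcfEntry]]:
    """Merge per-group calls into a population call set and VCF entries.

    SNVs and small indels merge on exact identity; SVs merge when kind and
    breakpoints agree within ``breakpoint_tol`` (single linkage). VAF is
    supporting groups / total eligible groups. Classification: ``target``
    when matching ``target_variant``, ``known`` when present in
    ``known_variants``, otherwise ``somatic``.
    """
    kept = group_filter(groups, params)
    total = len(kept)
    variants: list[PopulationVariant] = []
    if total:
        snv_map: dict[tuple, list[str]] = defaultdict(list)
        indel_map: dict[tuple, list[str]] = defaultdict(list)
        sv_events: list[tuple] = []
        for g in kept:
            for pos, ref_b, alt, _frac in g.snvs:
                snv_map[(pos, ref_b, alt)].append(g.umi)
            for pos, kind, length, seq, _frac in g.small_indels:
                indel_map[(kind, pos, length, seq)].append(g.umi)
            for kind, a, b, seq, _frac in g.svs:
                sv_events.append((kind, a, b, seq, g.umi))
        for (pos, ref_b, alt), umis in snv_map.items():
            variants.append(
                PopulationVariant("snv", pos, pos + 1, ref_b, alt, sorted(umis), total)
            )
        for (kind, pos, length, seq), umis in indel_map.items():
            if kind == "deletion":
                ref_allele = reference[max(pos - 1, 0) : pos + length]
                alt_allele = ref_allele[0] if pos > 0 else reference[pos + length]
                variants.append(
                    PopulationVariant(
                        "deletion", pos, pos + length, ref_allele, alt_allele,
                        sorted(umis), total,
                    )
                )
            else:
                anchor = reference[pos] if pos >= 0 else reference[0]
                variants.append(
                    PopulationVariant(
                        "insertion", pos, length, anchor, anchor + seq,
                        sorted(umis), total,
                    )
                )
        for cluster in _cluster_events(sv_events, params.breakpoint_tol):
            kind = cluster[0][0]
            a = int(median(e[1] for e in cluster))
            b = int(median(e[2] for e in cluster))
            umis = sorted({e[4] for e in cluster})
            if kind == "deletion":
                ref_allele = reference[max(a - 1, 0)] if a > 0 else "N"
                variants.append(
                    PopulationVariant(
                        "deletion", a, b, f"{ref_allele}", "<DEL>", umis, total
                    )
                )
            elif kind == "insertion":
                seqs = sorted((e[3] for e in cluster), key=len)
                seq = seqs[len(seqs) // 2]
                anchor = reference[a] if 0 <= a < len(reference) else "N"
                variants.append(
                    PopulationVariant(
                        "insertion", a, b, anchor,
                        anchor + seq if seq else "<INS>", umis, total,
                    )
                )
            else:
                variants.append(
                    PopulationVariant(
                        "inversion", a, b, reference[a] if a < len(reference) else "N",
                        "<INV>", umis, total,
                    )
                )
    for v in variants:
        v.class_ = "somatic"
        if target_variant and _match_target(v, target_variant, params.breakpoint_tol):
            v.class_ = "target"
        elif known_variants and any(
            _match_target(v, kv, params.breakpoint_tol) for kv in known_variants
        ):
            v.class_ = "known"
    lo, hi = params.vaf_bounds
    variants = [v for v in variants if lo <= v.vaf <= hi]
    variants.sort(key=lambda v: (v.pos, v.kind, v.alt))
    read_counts = {g.umi: g.read_count for g in kept}
    entries: list[VcfEntry] = []
    for v in variants:
        for umi in v.supporting_umis:
            if read_counts.get(umi, 0) < params.min_depth:
                continue
            info: dict[str, object] = {
                "TYPE": v.kind,
                "SUPPORT": v.support,
                "TOTAL": v.total_groups,
                "VAF": round(v.vaf, 8),
                "CLASS": v.class_,
            }
            if v.kind in ("deletion", "inversion"):
                info["END"] = v.end  # 1-based inclusive == 0-based exclusive
                info["SVLEN"] = v.end - v.pos
            elif v.kind == "insertion":
                info["SVLEN"] = v.end
            qual = 60.0
            if qual < params.min_qual:
                continue
            entries.append(
                VcfEntry(
                    chrom=reference_name,
                    pos=v.pos + 1,
                    id=make_vcf_id(umi, read_counts[umi]),
                    ref=v.ref,
                    alt=v.alt,
                    qual=qual,
                    info=info,
                )
            )
    entries.sort(key=lambda e: (e.chrom, e.pos, e.alt, e.id))
    return PopulationCallSet(variants, total), entries
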