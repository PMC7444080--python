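"""End-to-end orchestration: extract -> group -> align -> call -> merge.

The stages mirror a UMI-consensus amplicon analysis: reads are scanned for
the universal primer and structured UMI, binned into UMI groups by exact
string, each eligible group's reads are aligned to the amplicon reference
and reduced to consensus calls, low-confidence groups are dropped, and the
per-group calls are merged into a population call set with VCF, group
table, stats and manifest outputs. Per-group work is independent; the
worker count is a throughput knob that never changes results (groups are
processed and reduced in sorted UMI order).
"""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import Alignment, AlignmentParams, align_read, detect_inversion
from .errors import UmivarError
from .io import FastqRead, read_fasta, read_fastq, write_vcf
from .umi import (
    UMIDesign,
    UMIGroupTable,
    extract_umi,
    group_by_umi,
    write_group_table,
)
from .variants import (
    FilterParams,
    GroupCalls,
    PopulationCallSet,
    call_group,
    merge_and_filter,
)

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    reads: str
    reference: str
    design: UMIDesign
    output_dir: str
    params: FilterParams = field(default_factory=FilterParams)
    align_params: AlignmentParams = field(default_factory=AlignmentParams)
    paired: bool = False
    known_variants: list[dict] | None = None
    target_variant: dict | None = None
    surveyed_len_bp: int | None = None
    reference_name: str | None = None
    threads: int = 1
    seed: int = 0


@dataclass
class AnalysisResult:
    callset: PopulationCallSet
    groups: list[GroupCalls]
    table: UMIGroupTable
    entries: list
    manifest: dict


def _group_sequences(
    reads: list[FastqRead], design: UMIDesign, min_reads: int, paired: bool
) -> tuple[UMIGroupTable, dict[str, list[tuple[str, str]]], int]:
    """Extract UMIs and collect per-group (read_id, insert_seq) pairs.

    For paired data the UMI comes from r1; the mate contributes its full
    sequence to the same group.
    """
    extractions = []
    mate_seqs: dict[str, str] = {}
    if paired:
        r1 = [r for r in reads if r.mate != "r2"]
        for r in reads:
            if r.mate == "r2":
                mate_seqs[r.id] = r.seq
    else:
        r1 = reads
    for read in r1:
        extractions.append(extract_umi(read, design))
    table = group_by_umi(extractions, min_reads)
    inserts = {ex.read_id: ex.insert_seq for ex in extractions if ex.accepted}
    seqs: dict[str, list[tuple[str, str]]] = {}
    for umi in table.eligible:
        members: list[tuple[str, str]] = []
        for rid in table.groups[umi]:
            if inserts[rid]:
                members.append((rid, inserts[rid]))
            if rid in mate_seqs:
                members.append((rid + "/2", mate_seqs[rid]))
        seqs[umi] = members
    return table, seqs, len(extractions) - sum(
        1 for e in extractions if not e.accepted
    )


def _process_group(args) -> tuple[str, GroupCalls, int]:
    """Align one group's reads and call its consensus variants.

    Returns (umi, calls, n_unmapped). Module-level so worker processes can
    pickle it; deterministic, so the degree of parallelism cannot change
    the result.
    """
    umi, members, reference, params, align_params = args
    alignments: list[Alignment] = []
    inversions = {}
    unmapped = 0
    for rid, seq in members:
        aln = align_read(seq, reference, align_params, read_id=rid)
        if aln is None:
            unmapped += 1
            continue
        alignments.append(aln)
        ev = detect_inversion(
            aln, reference, align_params, min_sv_len=params.min_sv_len
        )
        if ev is not None:
            inversions[rid] = ev
    if len(alignments) < params.min_reads:
        calls = GroupCalls(umi=umi, read_count=len(alignments), pass_filter=False,
                           filter_reason="too few mappable reads")
        return umi, calls, unmapped
    calls = call_group(umi, alignments, inversions, reference, params)
    return umi, calls, unmapped


def run_analysis(
    reads: list[FastqRead],
    reference: str,
    design: UMIDesign,
    params: FilterParams | None = None,
    align_params: AlignmentParams | None = None,
    paired: bool = False,
    known_variants: list[dict] | None = None,
    target_variant: dict | None = None,
    reference_name: str = "amplicon",
    threads: int = 1,
) -> AnalysisResult:
    """Run the full analysis on in-memory reads; the library core of the
    ``umivar run`` command."""
    params = params or FilterParams()
    align_params = align_params or AlignmentParams()
    table, seqs, n_with_umi = _group_sequences(
        reads, design, params.min_reads, paired
    )
    jobs = [
        (umi, seqs[umi], reference, params, align_params)
        for umi in sorted(seqs)
    ]
    unmapped = 0
    groups: list[GroupCalls] = []
    if threads > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_process_group, jobs, chunksize=8))
    else:
        results = [_process_group(job) for job in jobs]
    for _umi, calls, n_unmapped in results:
        unmapped += n_unmapped
        groups.append(calls)
    callset, entries = merge_and_filter(
        groups,
        reference,
        params,
        reference_name=reference_name,
        known_variants=known_variants,
        target_variant=target_variant,
    )
    n_r1 = sum(1 for r in reads if r.mate != "r2")
    manifest = {
        "version": __version__,
        "total_reads": n_r1,
        "reads_with_umi": n_with_umi,
        "total_umis": table.n_total,
        "eligible_groups": table.n_eligible,
        "reads_in_eligible_groups": sum(
            len(table.groups[u]) for u in table.eligible
        ),
        "median_reads_per_eligible_group": table.median_eligible_reads(),
        "unmapped_reads": unmapped,
        "groups_passing_filter": callset.total_groups,
        "variants": {
            "total": len(callset.variants),
            "target": len(callset.by_class("target")),
            "known": len(callset.by_class("known")),
            "somatic": len(callset.by_class("somatic")),
        },
    }
    return AnalysisResult(callset, groups, table, entries, manifest)


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read inputs, run the analysis, write VCF,
    group table, stats and manifest into ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = read_fasta(config.reference)
    if not refs:
        raise UmivarError(f"{config.reference}: no sequences")
    name = config.reference_name or next(iter(refs))
    if name not in refs:
        raise UmivarError(f"{config.reference}: no sequence named {name!r}")
    reference = refs[name]
    reads = read_fastq(config.reads, paired=config.paired)
    result = run_analysis(
        reads,
        reference,
        config.design,
        params=config.params,
        align_params=config.align_params,
        paired=config.paired,
        known_variants=config.known_variants,
        target_variant=config.target_variant,
        reference_name=name,
        threads=config.threads,
    )
    write_vcf(result.entries, name, out / "calls.vcf", len(reference))
    write_group_table(result.table, out / "groups.tsv")
    stats = _run_stats(result, config)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    manifest = dict(result.manifest)
    manifest["config"] = {
        "reads": str(config.reads),
        "reference": str(config.reference),
        "min_reads": config.params.min_reads,
        "min_sv_len": config.params.min_sv_len,
        "consensus_fraction": config.params.consensus_fraction,
        "threads": config.threads,
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if result.table.n_eligible == 0:
        import sys

        print("warning: zero eligible UMI groups; outputs are empty",
              file=sys.stderr)
    return manifest


def _run_stats(result: AnalysisResult, config: RunConfig) -> dict:
    from .stats import cluster_recurrent_svs, somatic_load, substitution_spectrum

    somatic = result.callset.by_class("somatic")
    snv_pairs = [(v.ref, v.alt) for v in somatic if v.kind == "snv"]
    spectrum = substitution_spectrum(snv_pairs) if snv_pairs else None
    sv_entries = []
    for v in result.callset.variants:
        if v.kind in ("deletion", "insertion", "inversion"):
            for umi in v.supporting_umis:
                sv_entries.append((v.kind, v.pos, v.end, umi))
    clusters = cluster_recurrent_svs(sv_entries, config.params.breakpoint_tol)
    stats: dict = {
        "sv_groups": len({e[3] for e in sv_entries}),
        "sv_clusters": [
            {
                "kind": c.kind,
                "start": c.start,
                "end": c.end,
                "count": c.count,
                "fraction": round(c.fraction, 6),
            }
            for c in clusters
        ],
        "n_somatic_snvs": sum(1 for v in somatic if v.kind == "snv"),
    }
    if spectrum is not None:
        stats["substitution_spectrum"] = spectrum.counts
    surveyed = config.surveyed_len_bp
    if surveyed and result.callset.total_groups:
        stats["somatic_snv_load_per_mb"] = round(
            somatic_load(
                stats["n_somatic_snvs"], result.callset.total_groups, surveyed
            ),
            1,
        )
    return stats
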