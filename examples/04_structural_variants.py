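"""Quantify DNA-repair-like structural variants and their recurrence.

A 2-kb amplicon population mimics on-target Cas9 repair outcomes: a large
deletion, a large insertion, an inversion and small indels around a cut
site. Per-group CIGAR walks call SVs (> 30 bp) at the per-read median
breakpoints; recurrence clustering then reveals which events hit the same
breakpoints in independent molecules — hotspot evidence.
"""

import numpy as np

from umivar import (
    AlleleSpec,
    Edit,
    ErrorModel,
    PopulationSpec,
    ReadDepth,
    UMIDesign,
    cluster_recurrent_svs,
    run_analysis,
    simulate_run,
)

rng = np.random.default_rng(11)
reference = "".join(rng.choice(list("ACGT"), 2000))
design = UMIDesign("ACACGACGCTCTTCCGATCT", "NNNNTGNNNN", reference[:20])
insert = "".join(np.random.default_rng(5).choice(list("ACGT"), 120))

spec = PopulationSpec(
    reference=reference,
    alleles=[
        AlleleSpec("wild_type", 0.50),
        AlleleSpec("large_deletion", 0.20, [Edit("deletion", 700, 800)]),
        AlleleSpec("large_insertion", 0.10, [Edit("insertion", 1000, insert)]),
        AlleleSpec("inversion", 0.10, [Edit("inversion", 900, 300)]),
        AlleleSpec("small_del", 0.10, [Edit("deletion", 998, 2)]),
    ],
    n_molecules=500,
    umi_design=design,
    error_model=ErrorModel.for_platform("nanopore"),
    reads_per_molecule=ReadDepth(mean=12.0, dispersion=4.0),
    platform="nanopore",
    seed=4,
)
reads, truth, _ = simulate_run(spec)
result = run_analysis(reads, reference, design)

print(f"eligible groups: {result.manifest['eligible_groups']}, "
      f"passing filter: {result.manifest['groups_passing_filter']}")
sv_entries = []
for v in result.callset.variants:
    size = v.end - v.pos if v.kind != "insertion" else v.end
    print(f"{v.kind:>10s} at {v.pos:>5d} size ~{size:>4d}: "
          f"{v.support} group(s), VAF {v.vaf:.3f}")
    if v.kind in ("deletion", "insertion", "inversion") and size > 30:
        for umi in v.supporting_umis:
            sv_entries.append((v.kind, v.pos, v.end, umi))

clusters = cluster_recurrent_svs(sv_entries, breakpoint_tol=10)
print("\nrecurrence clusters (same breakpoints in independent molecules):")
for c in clusters:
    print(f"  {c.kind} {c.start}-{c.end}: {c.count} group(s), "
          f"{100 * c.fraction:.1f}% of SV-bearing groups")
print("\nRecurrent identical breakpoints across molecules indicate repair")
print("hotspots rather than random end-joining.")
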