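"""Detect a 1:100 spike-in SNV from noisy long reads, end to end.

Reads are scanned for the universal primer and structured UMI, binned into
UMI groups (>= 5 reads), aligned, and reduced to per-group consensus calls;
identical calls are merged across groups into a population call set whose
VAF is supporting groups / eligible groups — a count of original
molecules, immune to amplification bias.
"""

import numpy as np

from umivar import (
    AlleleSpec,
    Edit,
    ErrorModel,
    PopulationSpec,
    ReadDepth,
    UMIDesign,
    run_analysis,
    simulate_run,
)

rng = np.random.default_rng(7)
reference = "".join(rng.choice(list("ACGT"), 168))
design = UMIDesign("ACACGACGCTCTTCCGATCT", "NNNNTGNNNN", reference[:20])

spec = PopulationSpec(
    reference=reference,
    alleles=[
        AlleleSpec("wild_type", 0.99),
        AlleleSpec("knockin", 0.01, [Edit("snv", 100, "T")]),
    ],
    n_molecules=1550,
    umi_design=design,
    error_model=ErrorModel.for_platform("nanopore"),
    reads_per_molecule=ReadDepth(mean=12.0, dispersion=4.0),
    platform="nanopore",
    seed=3,
)
reads, truth, _ = simulate_run(spec)
result = run_analysis(
    reads, reference, design,
    target_variant={"kind": "snv", "pos": 100, "alt": "T"},
)

m = result.manifest
print(f"reads: {m['total_reads']}, with UMI: {m['reads_with_umi']} "
      f"({100 * m['reads_with_umi'] / m['total_reads']:.1f}%)")
print(f"eligible UMI groups (>=5 reads): {m['eligible_groups']}, "
      f"passing filter: {m['groups_passing_filter']}")
for v in result.callset.variants:
    print(f"called {v.kind} at {v.pos} {v.ref}>{v.alt}: "
          f"{v.support}/{v.total_groups} groups, VAF {v.vaf:.2e}, "
          f"class {v.class_}")
from umivar import vaf_of_variant

targets = result.callset.by_class("target")
if targets:
    _vaf, (lo, hi) = vaf_of_variant(targets[0].support, targets[0].total_groups)
    print(f"\nWilson 95% interval {lo:.1e} - {hi:.1e} covers the designed 1e-2: "
          f"{lo <= 0.01 <= hi}")
print("Each supporting group is one original molecule, so the estimate is")
print("a molecule count, robust to ~12% raw read error and PCR bias.")
print("(1-bp deletion calls are a known homopolymer artifact class of")
print("Nanopore-like reads; SNV calls stay clean.)")
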