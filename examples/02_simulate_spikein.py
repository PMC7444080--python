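"""Simulate a UMI-labeled spike-in experiment with full ground truth.

A 168-bp amplicon population carries an engineered SNV in 1% of molecules.
Each molecule receives a unique structured UMI (NNNNTGNNNN), one
polymerase-error pass, and Nanopore-like per-read errors (5% substitution,
3% insertion, 4% deletion).
"""

import numpy as np

from umivar import (
    AlleleSpec,
    Edit,
    ErrorModel,
    PopulationSpec,
    UMIDesign,
    simulate_run,
)

rng = np.random.default_rng(7)
reference = "".join(rng.choice(list("ACGT"), 168))
design = UMIDesign(
    universal_primer="ACACGACGCTCTTCCGATCT",
    umi_pattern="NNNNTGNNNN",
    gene_specific=reference[:20],
)

spec = PopulationSpec(
    reference=reference,
    alleles=[
        AlleleSpec("wild_type", 0.99),
        AlleleSpec("knockin", 0.01, [Edit("snv", 100, "T")]),
    ],
    n_molecules=500,
    umi_design=design,
    error_model=ErrorModel.for_platform("nanopore"),
    platform="nanopore",
    seed=11,
)

reads, truth, manifest = simulate_run(spec)
spike = [m for m in truth if m.allele == "knockin"]
print(f"simulated {manifest['n_reads']} reads from {len(truth)} molecules")
print(f"spike-in molecules: {len(spike)} "
      f"(expected ~{spec.n_molecules * 0.01:.0f} at 1%)")
print(f"every molecule has a unique UMI: "
      f"{len({m.umi for m in truth}) == len(truth)}")
print("first spike-in molecule:", spike[0].molecule_id,
      "UMI", spike[0].umi, "reads", len(spike[0].read_ids))
print("\nThe truth table records molecule -> UMI -> edits -> read ids,")
print("so every downstream stage can be scored against known ground truth.")
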