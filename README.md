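# umivar

UMI-consensus rare-variant calling for amplicon sequencing, with a
ground-truth read simulator.

## The problem

Raw sequencing error (up to ~12% per base on long-read platforms, ~1% on
short reads) buries any allele rarer than a few percent. When each original
DNA molecule is tagged with a unique molecular identifier (UMI) before
amplification, every sequencing read inherits its molecule's UMI; the set
of reads sharing one UMI — a *UMI group* — is many observations of one
molecule, and consensus within the group cancels independent sequencing
error. Variants as rare as 1e-4, and large structural variants (deletions,
insertions, inversions) that only long reads can span, become callable and
*countable*: the variant allele fraction (VAF) is

```
VAF = supporting UMI groups / eligible UMI groups
```

a count of original molecules, immune to amplification bias. Two
closed-form design quantities frame every experiment:

- detection power: an allele at frequency `f` appears in at least one of
  `n` sampled molecules with probability `1 − (1−f)^n`, so the minimal
  group count for confidence `P` is `⌈ln(1−P)/ln(1−f)⌉`;
- error floor: a polymerase error in the first (barcoding) copy propagates
  to every read of its molecule and survives consensus; its expected count
  is `n_groups × molecule_length × per_base_error`.

The package is written for experimentalists quantifying rare subclonal
variants — spike-in benchmarks, somatic mutation loads, CRISPR on-target
repair outcomes (recurrent large deletions/insertions, inversion alleles,
indel spectra) — and for method developers who need a simulator with a
molecule-level truth table to score every pipeline stage.

## What's inside

| module | role |
| --- | --- |
| `umivar.simulate` | population/UMI/error simulator with a full truth table |
| `umivar.umi` | structured-UMI design validation, extraction, grouping, subsampling |
| `umivar.align` | two-piece affine-gap semi-global aligner (numba DP) + inversion discovery |
| `umivar.variants` | per-group consensus SNV/indel/SV calling, group filtering, population merge |
| `umivar.stats` | somatic load, detection power, error budget, SV recurrence, spectra, haplotypes, VAF |
| `umivar.pipeline` | one-call orchestration (`run_analysis` / `run_pipeline`) |
| `umivar.io` / `umivar.cli` | FASTA/FASTQ/VCF v4.2 I/O and the `umivar` command line |

## Worked example

`examples/03_call_rare_variant.py` simulates a 1:100 spike-in SNV on a
168-bp amplicon with Nanopore-like error (5% substitution, 3% insertion,
4% deletion) and runs the full analysis:

```
reads: 18500, with UMI: 8568 (46.3%)
eligible UMI groups (>=5 reads): 267, passing filter: 267
called deletion at 21 TC>T: 1/267 groups, VAF 3.75e-03, class somatic
called snv at 100 G>T: 1/267 groups, VAF 3.75e-03, class target

Wilson 95% interval 6.6e-04 - 2.1e-02 covers the designed 1e-2: True
```

Reading the numbers: 46.3% of raw reads carry a high-confidence structured
UMI (primer found, fixed pattern bases intact); they bin into 267 groups of
at least five reads — 267 original molecules. The engineered G>T at
position 100 is recovered in one group and classified `target`; its Wilson
interval covers the designed 1% frequency. The lone 1-bp deletion call is
the homopolymer artifact class expected from Nanopore-like indel noise;
no spurious SNV is called. The other examples cover the design calculators
(`01`), the simulator and its truth table (`02`), and structural-variant
recurrence clustering (`04`).

The same analysis runs from the shell:

```bash
umivar simulate --spec population.json -o sim/
umivar call --reads sim/reads.fastq --ref amplicon.fa --design design.json -o out/
umivar stats --power-f 0.01 --power-confidence 0.9
```

outputs: `calls.vcf` (VCF v4.2, the supporting group's UMI and read count
in the ID column as `<UMI>_<readcount>`), `groups.tsv`, `stats.json`,
`manifest.json`.

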