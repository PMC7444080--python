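"""UMI design validation, extraction, grouping and read subsampling.

A UMI-tagged amplicon read starts (in one orientation or the other) with a
universal amplification handle followed by a structured UMI such as
``NNNNTGNNNN``: random bases interrupted by fixed anchor bases that break
homopolymers and act as a built-in quality check. Extraction finds the
universal primer near the read start with a bounded edit distance, takes the
following pattern-length bases as the UMI candidate, and accepts it only if
every fixed pattern base matches exactly. Reads sharing one exact UMI string
form a UMI group — the unit of consensus calling, standing for one original
molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import edlib
import numpy as np

from .errors import UmivarError
from .io import FastqRead

__all__ = [
    "UMIDesign",
    "UMIExtraction",
    "UMIGroupTable",
    "validate_design",
    "extract_umi",
    "group_by_umi",
    "subsample_reads",
    "reverse_complement",
    "umi_space_size",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class UMIDesign:
    """Primer/UMI architecture of the labeling oligo.

    The labeling primer is universal handle + UMI + gene-specific 3' part;
    after extension and amplification a forward read therefore begins with
    ``universal_primer + UMI`` followed by the amplicon sequence.
    """

    universal_primer: str
    umi_pattern: str
    gene_specific: str
    max_primer_mismatches: int = 3
    reverse_primer: str = ""

    @property
    def pattern_length(self) -> int:
        return len(self.umi_pattern)

    @property
    def n_random(self) -> int:
        return self.umi_pattern.count("N")

    def fixed_positions(self) -> list[tuple[int, str]]:
        return [(i, b) for i, b in enumerate(self.umi_pattern) if b != "N"]


def umi_space_size(pattern: str) -> int:
    """Number of distinct UMIs the structured pattern can produce."""
    return 4 ** pattern.count("N")


def validate_design(design: UMIDesign) -> list[str]:
    """Check a design against the rules of thumb for structured UMIs.

    Returns a list of human-readable violations (empty means valid):
    pattern length outside 10-12 nt, missing fixed anchor base, N-runs of
    five or more (homopolymer slippage risk), non-ACGTN characters, empty
    primers, and primers sharing a long exact overlap.
    """
    violations: list[str] = []
    pattern = design.umi_pattern
    if not (10 <= len(pattern) <= 12):
        violations.append(
            f"pattern length {len(pattern)} outside the 10-12 nt range"
        )
    if set(pattern) - set("ACGTN"):
        violations.append("pattern contains characters outside ACGTN")
    if "N" in pattern and not any(b != "N" for b in pattern):
        violations.append("pattern has no fixed anchor base (structure check impossible)")
    run = 0
    for b in pattern:
        run = run + 1 if b == "N" else 0
        if run >= 5:
            violations.append("pattern contains an N-run of 5 or more")
            break
    if not design.universal_primer:
        violations.append("universal primer is empty")
    if not design.gene_specific:
        violations.append("gene-specific primer is empty")
    for other_name, other in (
        ("gene_specific", design.gene_specific),
        ("reverse_primer", design.reverse_primer),
    ):
        if other and _longest_shared_kmer(design.universal_primer, other) >= 10:
            violations.append(
                f"universal primer shares a >=10-base exact overlap with {other_name}"
            )
    return violations


def _longest_shared_kmer(a: str, b: str) -> int:
    best = 0
    for k in range(min(len(a), len(b)), 9, -1):
        kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
        if any(b[i : i + k] in kmers for i in range(len(b) - k + 1)):
            return k
    return best


@dataclass
class UMIExtraction:
    """Outcome of UMI extraction for one read."""

    read_id: str
    umi: str | None
    orientation: str  # "forward" | "reverse"
    reject_reason: str  # "none" | "no_primer" | "bad_structure" | "bad_length"
    insert_seq: str

    @property
    def accepted(self) -> bool:
        return self.reject_reason == "none"


def _find_primer(seq: str, primer: str, max_ed: int, window: int) -> int | None:
    """Locate the primer within the first ``window`` bases; return the end
    offset (exclusive) of the best hit, or None."""
    prefix = seq[: window + len(primer)]
    hit = edlib.align(primer, prefix, mode="HW", task="locations", k=max_ed)
    if hit["editDistance"] == -1 or not hit["locations"]:
        return None
    # edlib returns 0-based inclusive end positions
    return hit["locations"][0][1] + 1


def extract_umi(read: FastqRead, design: UMIDesign) -> UMIExtraction:
    """Extract the structured UMI from a read (either orientation).

    The universal primer is searched within a window of 1.5x the
    (primer+UMI) length from the 5' end of the read and of its reverse
    complement. On a hit, the next pattern-length bases are the UMI
    candidate, accepted only when every fixed pattern base matches exactly.
    """
    plen = design.pattern_length
    window = int(1.5 * (len(design.universal_primer) + plen))
    if len(read.seq) < len(design.universal_primer) + plen + 1:
        return UMIExtraction(read.id, None, "forward", "no_primer", read.seq)

    for orientation, seq in (
        ("forward", read.seq),
        ("reverse", reverse_complement(read.seq)),
    ):
        end = _find_primer(
            seq, design.universal_primer, design.max_primer_mismatches, window
        )
        if end is None:
            continue
        candidate = seq[end : end + plen]
        insert = seq[end + plen :]
        if len(candidate) < plen:
            return UMIExtraction(read.id, None, orientation, "bad_length", insert)
        if all(candidate[i] == b for i, b in design.fixed_positions()):
            return UMIExtraction(read.id, candidate, orientation, "none", insert)
        return UMIExtraction(read.id, None, orientation, "bad_structure", insert)
    return UMIExtraction(read.id, None, "forward", "no_primer", read.seq)


@dataclass
class UMIGroupTable:
    """Reads binned by exact UMI string.

    ``eligible`` holds the UMIs whose read count reaches ``min_reads``; only
    those groups enter consensus calling. Groups are disjoint by
    construction (a read contributes its single extracted UMI or none).
    """

    groups: dict[str, list[str]]  # umi -> read ids, insertion order
    min_reads: int
    eligible: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.eligible = sorted(
            u for u, reads in self.groups.items() if len(reads) >= self.min_reads
        )

    @property
    def counts(self) -> dict[str, int]:
        return {u: len(r) for u, r in self.groups.items()}

    @property
    def n_total(self) -> int:
        return len(self.groups)

    @property
    def n_eligible(self) -> int:
        return len(self.eligible)

    def median_eligible_reads(self) -> float:
        if not self.eligible:
            return 0.0
        return float(median(len(self.groups[u]) for u in self.eligible))

    def summary(self) -> dict[str, float]:
        return {
            "total_umis": self.n_total,
            "eligible_umis": self.n_eligible,
            "reads_in_groups": sum(len(r) for r in self.groups.values()),
            "reads_in_eligible_groups": sum(
                len(self.groups[u]) for u in self.eligible
            ),
            "median_reads_per_eligible_group": self.median_eligible_reads(),
        }


def group_by_umi(
    extractions: Iterable[UMIExtraction], min_reads: int = 5
) -> UMIGroupTable:
    """Bin accepted extractions into UMI groups by exact string match.

    No mismatch clustering is attempted: sequencing errors inside a UMI
    spawn low-count satellite groups that the ``min_reads`` threshold
    removes, whereas merging near-neighbour UMIs risks fusing distinct
    molecules.
    """
    if min_reads < 1:
        raise UmivarError("min_reads must be >= 1")
    groups: dict[str, list[str]] = {}
    for ex in extractions:
        if ex.accepted:
            groups.setdefault(ex.umi, []).append(ex.read_id)  # type: ignore[arg-type]
    return UMIGroupTable(groups, min_reads)


def write_group_table(table: UMIGroupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("umi\tread_count\teligible\n")
        for umi in sorted(table.groups):
            n = len(table.groups[umi])
            fh.write(f"{umi}\t{n}\t{'yes' if n >= table.min_reads else 'no'}\n")


def subsample_reads(reads: Sequence, n: int, seed: int) -> list:
    """Uniform sample of ``n`` reads without replacement, preserving order."""
    if n < 0 or n > len(reads):
        raise UmivarError(f"cannot subsample {n} of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in np.sort(idx)]
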