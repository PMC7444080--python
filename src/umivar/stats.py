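"""Reporting statistics and experiment-design calculators.

These are the population-level summaries of a UMI-consensus run: the
somatic SNV load per megabase, the minimum number of UMI groups needed to
observe a rare allele, the expected number of groups corrupted by a
first-copy polymerase error, recurrence clustering of structural variants
(repair-hotspot evidence), the substitution spectrum, haplotype
partitioning of groups sharing an SV, and variant allele fractions with
Wilson confidence intervals.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from statistics import median

from statsmodels.stats.proportion import proportion_confint

from .errors import UmivarError

__all__ = [
    "somatic_load",
    "min_groups_for_detection",
    "expected_error_groups",
    "cluster_recurrent_svs",
    "RecurrenceCluster",
    "substitution_spectrum",
    "SpectrumTable",
    "haplotype_partition",
    "vaf_of_variant",
    "PowerResult",
]


def somatic_load(n_snvs: int, n_groups: int, surveyed_len_bp: int) -> float:
    """Somatic SNV load per megabase.

    ``10^6 * n_snvs / (n_groups * surveyed_len_bp)`` — the denominator is
    molecules surveyed times the surveyed region length, with primer-covered
    bases excluded from the length (they are synthetic, not genomic).
    """
    if n_groups < 1 or surveyed_len_bp < 1:
        raise UmivarError("somatic_load requires n_groups >= 1 and surveyed_len_bp >= 1")
    if n_snvs < 0:
        raise UmivarError("n_snvs must be >= 0")
    return 1e6 * n_snvs / (n_groups * surveyed_len_bp)


@dataclass(frozen=True)
class PowerResult:
    """Smallest group count n with 1-(1-f)^n >= confidence."""

    f: float
    confidence: float
    n_min: int


def min_groups_for_detection(f: float, confidence: float) -> PowerResult:
    """Minimum number of UMI groups so that an allele at frequency ``f``
    appears in at least one group with the given probability.

    Detection of at least one carrier among n sampled molecules follows
    P = 1 - (1-f)^n; the bound is the exact ceiling of
    ln(1-confidence)/ln(1-f), verified at the boundary.
    """
    if not (0.0 < f <= 1.0):
        raise UmivarError("allele frequency must be in (0, 1]")
    if not (0.0 < confidence < 1.0):
        raise UmivarError("confidence must be in (0, 1)")
    if f == 1.0:
        return PowerResult(f, confidence, 1)
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - f))
    # guard against floating-point edge cases on either side
    while 1.0 - (1.0 - f) ** n < confidence:
        n += 1
    while n > 1 and 1.0 - (1.0 - f) ** (n - 1) >= confidence:
        n -= 1
    return PowerResult(f, confidence, n)


def expected_error_groups(
    n_groups: int, molecule_len_bp: int, per_base_err: float
) -> float:
    """Expected number of UMI groups carrying a first-copy polymerase
    error: n_groups * molecule_len_bp * per_base_err. This error mode is
    inescapable — it propagates to every read of the molecule — so it sets
    the noise floor of consensus calling."""
    if n_groups < 0 or molecule_len_bp < 0 or per_base_err < 0:
        raise UmivarError("expected_error_groups requires non-negative inputs")
    return n_groups * molecule_len_bp * per_base_err


@dataclass
class RecurrenceCluster:
    """UMI groups from distinct molecules sharing one SV signature —
    recurrence across molecules marks a repair hotspot."""

    kind: str
    start: int
    end: int  # exclusive end (deletion/inversion) or inserted length
    member_umis: list[str]
    fraction: float  # of all SV-bearing groups

    @property
    def count(self) -> int:
        return len(self.member_umis)

    @property
    def size(self) -> int:
        return self.end - self.start if self.kind != "insertion" else self.end


def cluster_recurrent_svs(
    svs: list[tuple[str, int, int, str]],
    breakpoint_tol: int = 10,
    n_sv_groups: int | None = None,
) -> list[RecurrenceCluster]:
    """Single-linkage clustering of per-group SVs.

    ``svs`` holds one entry per SV-bearing group: (kind, start,
    end_or_length, umi). Two SVs link when kinds match and both coordinates
    are within ``breakpoint_tol``. Fractions are over the number of
    SV-bearing groups (distinct UMIs, unless ``n_sv_groups`` is given).
    Clusters are returned sorted by count descending.
    """
    if n_sv_groups is None:
        n_sv_groups = len({s[3] for s in svs})
    if not svs:
        return []
    parent = list(range(len(svs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(svs)):
        for j in range(i + 1, len(svs)):
            if svs[i][0] != svs[j][0]:
                continue
            if (
                abs(svs[i][1] - svs[j][1]) <= breakpoint_tol
                and abs(svs[i][2] - svs[j][2]) <= breakpoint_tol
            ):
                parent[find(i)] = find(j)
    members: dict[int, list[tuple]] = defaultdict(list)
    for i, s in enumerate(svs):
        members[find(i)].append(s)
    clusters = []
    for group in members.values():
        kind = group[0][0]
        start = int(median(s[1] for s in group))
        end = int(median(s[2] for s in group))
        umis = sorted({s[3] for s in group})
        clusters.append(
            RecurrenceCluster(kind, start, end, umis, len(umis) / n_sv_groups)
        )
    clusters.sort(key=lambda c: (-c.count, c.kind, c.start))
    return clusters


_SUB_CLASSES = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]
# strand-symmetric collapse: pyrimidine-centred six classes
_COLLAPSE = {
    "C>A": "C>A", "G>T": "C>A",
    "C>G": "C>G", "G>C": "C>G",
    "C>T": "C>T", "G>A": "C>T",
    "T>A": "T>A", "A>T": "T>A",
    "T>C": "T>C", "A>G": "T>C",
    "T>G": "T>G", "A>C": "T>G",
}


@dataclass
class SpectrumTable:
    """Counts of the 12 ordered substitution classes plus the collapsed
    strand-symmetric six-class view."""

    counts: dict[str, int]

    @property
    def collapsed(self) -> dict[str, int]:
        out = Counter()
        for cls, n in self.counts.items():
            out[_COLLAPSE[cls]] += n
        for cls in sorted(set(_COLLAPSE.values())):
            out.setdefault(cls, 0)
        return dict(out)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def transition_fraction(self) -> float:
        ti = sum(self.counts[c] for c in ("A>G", "G>A", "C>T", "T>C"))
        return ti / self.total if self.total else 0.0


def substitution_spectrum(snvs: list[tuple[str, str]]) -> SpectrumTable:
    """Tally ref>alt substitution classes from (ref_base, alt_base) pairs."""
    counts = {cls: 0 for cls in _SUB_CLASSES}
    for ref, alt in snvs:
        if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            raise UmivarError(f"invalid substitution {ref!r}->{alt!r}")
        counts[f"{ref}>{alt}"] += 1
    return SpectrumTable(counts)


def haplotype_partition(
    group_snvs: dict[str, set],
    coverage: dict[str, tuple[int, int]] | None = None,
) -> list[list[str]]:
    """Partition UMI groups into haplotypes by their SNV fingerprints.

    Groups whose SNV sets agree on the positions covered by *all* members
    belong to one haplotype; positions missing from any member's coverage
    are ignored so that partial reads do not split haplotypes. Returns
    haplotype classes as sorted lists of member UMIs.
    """
    if not group_snvs:
        raise UmivarError("haplotype_partition requires at least one group")
    umis = sorted(group_snvs)
    if coverage:
        common_start = max(coverage[u][0] for u in umis if u in coverage)
        common_end = min(coverage[u][1] for u in umis if u in coverage)
    else:
        common_start, common_end = 0, float("inf")

    def fingerprint(umi: str) -> frozenset:
        return frozenset(
            s for s in group_snvs[umi]
            if common_start <= _snv_pos(s) < common_end
        )

    classes: dict[frozenset, list[str]] = defaultdict(list)
    for umi in umis:
        classes[fingerprint(umi)].append(umi)
    return sorted(classes.values(), key=lambda c: c[0])


def _snv_pos(snv) -> int:
    if isinstance(snv, tuple):
        return snv[0]
    return int(snv)


def vaf_of_variant(
    supporting_groups: int, total_groups: int
) -> tuple[float, tuple[float, float]]:
    """Variant allele fraction with its Wilson 95% interval.

    VAF is supporting UMI groups over total eligible groups — each group is
    one original molecule, so this estimates the allele's frequency in the
    initial population.
    """
    if total_groups < 1:
        raise UmivarError("total_groups must be >= 1")
    if not (0 <= supporting_groups <= total_groups):
        raise UmivarError("supporting_groups must be in [0, total_groups]")
    lo, hi = proportion_confint(
        supporting_groups, total_groups, alpha=0.05, method="wilson"
    )
    return supporting_groups / total_groups, (float(lo), float(hi))
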