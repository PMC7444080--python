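"""Reading and writing of FASTA, FASTQ and VCF.

FASTQ is parsed with a strict 4-line reader so that malformed records can be
reported with their line number; Phred+33 is the only quality encoding
accepted. FASTA goes through Biopython. VCF output follows v4.2, with the
UMI and the read count of the supporting group encoded in the ID column as
``<UMI>_<readcount>``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .errors import ParseError, UmivarError

__all__ = [
    "FastqRead",
    "VcfEntry",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_vcf",
    "INFO_SCHEMA",
]


@dataclass
class FastqRead:
    """One sequencing read.

    ``qual`` holds integer Phred scores, one per base. ``mate`` is
    ``"single"`` for unpaired data and ``"r1"``/``"r2"`` for read pairs
    sharing an id.
    """

    id: str
    seq: str
    qual: list[int] = field(repr=False)
    mate: str = "single"

    def __post_init__(self) -> None:
        if not self.seq:
            raise UmivarError(f"read {self.id!r}: empty sequence")
        if len(self.qual) != len(self.seq):
            raise UmivarError(
                f"read {self.id!r}: {len(self.qual)} quality values for "
                f"{len(self.seq)} bases"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path, paired: bool = False) -> list[FastqRead]:
    """Read a (possibly gzipped) FASTQ file.

    Records are returned in file order. With ``paired=True`` the file is
    expected to interleave mates (r1, r2, r1, r2, ...) whose ids match after
    stripping a ``/1``/``/2`` suffix; mates are labelled accordingly.
    """
    reads: list[FastqRead] = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ParseError(f"{path}: truncated record at line {lineno}")
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            phred = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 93 for q in phred):
                raise ParseError(
                    f"{path}: line {lineno + 3}: quality characters outside "
                    "Phred+33 range"
                )
            reads.append(FastqRead(header[1:].split()[0].rstrip("\n"), seq, phred))
            lineno += 3
    if paired:
        if len(reads) % 2:
            raise ParseError(f"{path}: odd number of records in paired mode")
        for i, read in enumerate(reads):
            read.mate = "r1" if i % 2 == 0 else "r2"
            base = read.id
            for suffix in ("/1", "/2"):
                if base.endswith(suffix):
                    read.id = base[:-2]
        for r1, r2 in zip(reads[::2], reads[1::2]):
            if r1.id != r2.id:
                raise ParseError(
                    f"{path}: mates {r1.id!r} and {r2.id!r} do not share an id"
                )
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ (gzipped if the path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        for read in reads:
            suffix = {"r1": "/1", "r2": "/2"}.get(read.mate, "")
            qual = "".join(chr(q + 33) for q in read.qual)
            fh.write(f"@{read.id}{suffix}\n{read.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> uppercase-sequence map."""
    result: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in result:
                raise ParseError(f"{path}: duplicate sequence name {record.id!r}")
            result[record.id] = str(record.seq).upper()
    return result


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# INFO keys this package emits. Writing an entry with any other key is an
# error: the header must declare everything it prints.
INFO_SCHEMA: dict[str, tuple[str, str, str]] = {
    "TYPE": ("1", "String", "Variant type (snv, insertion, deletion, inversion)"),
    "SVLEN": ("1", "Integer", "Length of the structural variant"),
    "END": ("1", "Integer", "1-based inclusive end of the variant interval"),
    "SUPPORT": ("1", "Integer", "Number of UMI groups supporting the variant"),
    "TOTAL": ("1", "Integer", "Number of eligible UMI groups considered"),
    "VAF": ("1", "Float", "Variant allele fraction (supporting/eligible groups)"),
    "CLASS": ("1", "String", "Variant class (target, known, somatic)"),
    "GSF": ("1", "Float", "Within-group support fraction"),
}


@dataclass
class VcfEntry:
    """One VCF data line.

    ``id`` carries the supporting group's UMI and read count as
    ``<UMI>_<readcount>``; :func:`make_vcf_id` builds it.
    """

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    qual: float
    info: dict[str, object] = field(default_factory=dict)
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise UmivarError(f"VCF entry at pos {self.pos}: pos must be >= 1")
        if not self.ref or not self.alt:
            raise UmivarError(f"VCF entry at pos {self.pos}: empty allele")
        vaf = self.info.get("VAF")
        if vaf is not None and not (0.0 <= float(vaf) <= 1.0):
            raise UmivarError(f"VCF entry at pos {self.pos}: VAF {vaf} outside [0,1]")


def make_vcf_id(umi: str, read_count: int) -> str:
    return f"{umi}_{read_count}"


def _format_info(info: dict[str, object]) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if key not in INFO_SCHEMA:
            raise UmivarError(f"unknown INFO key {key!r}")
        if isinstance(value, float):
            parts.append(f"{key}={value:.6g}")
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def write_vcf(
    entries: list[VcfEntry],
    reference_name: str,
    path: str | Path,
    reference_length: int | None = None,
) -> None:
    """Write entries as VCF v4.2. Entries must be sorted by (chrom, pos)."""
    keys = [(e.chrom, e.pos) for e in entries]
    if keys != sorted(keys):
        raise UmivarError("VCF entries must be sorted by (chrom, pos)")
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=umivar\n")
        if reference_length is not None:
            fh.write(f"##contig=<ID={reference_name},length={reference_length}>\n")
        else:
            fh.write(f"##contig=<ID={reference_name}>\n")
        for key, (number, vtype, desc) in INFO_SCHEMA.items():
            fh.write(
                f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in entries:
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.id or '.'}\t{e.ref}\t{e.alt}\t"
                f"{e.qual:.6g}\t{e.filter}\t{_format_info(e.info)}\n"
            )
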