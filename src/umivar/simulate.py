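"""Synthetic UMI-labeled amplicon populations with full ground truth.

The generator emulates a spike-in experiment: a molecule population drawn
from a small set of alleles (wild type plus engineered variants at preset
frequencies such as 1:100 ... 1:10,000), independent somatic SNVs added at a
per-megabase rate, one structured UMI per molecule (unique by construction,
sampling the pattern space without replacement), a single polymerase-error
pass standing for the first-copy barcoding error — the one error mode
consensus cannot remove, because it propagates to every read of the
molecule — and finally per-read platform-specific sequencing error
(Nanopore-like: high substitution and indel rates; Illumina-like: low
substitution, paired 150-base ends; PacBio-HiFi-like: low error, full
length). Every molecule, UMI, true edit and emitted read id is recorded in
a :class:`TruthTable` so downstream stages can be tested for exact
parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SpecError, UmivarError
from .io import FastqRead
from .umi import UMIDesign, reverse_complement, umi_space_size

__all__ = [
    "Edit",
    "AlleleSpec",
    "ErrorModel",
    "ReadDepth",
    "PopulationSpec",
    "MoleculeTruth",
    "TruthTable",
    "build_population",
    "tag_with_umis",
    "amplify_and_sequence",
    "simulate_run",
    "apply_edits",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

# Platinum SuperFi-like first-copy fidelity: ~6 errors per 1e6 unique
# 168-bp molecules, i.e. 6e-6 / 168 per base.
SUPERFI_PER_BASE = 6e-6 / 168


@dataclass(frozen=True)
class Edit:
    """One true edit in reference coordinates (0-based).

    payload: alt base for ``snv``; length for ``deletion``/``inversion``;
    inserted sequence for ``insertion`` (placed immediately after ``pos``).
    """

    kind: str
    pos: int
    payload: object

    def interval(self) -> tuple[int, int]:
        if self.kind in ("deletion", "inversion"):
            return (self.pos, self.pos + int(self.payload))
        return (self.pos, self.pos + 1)

    def key(self) -> tuple:
        """Canonical identity used to compare against calls."""
        if self.kind in ("deletion", "inversion"):
            return (self.kind, self.pos, self.pos + int(self.payload))
        return (self.kind, self.pos, self.payload)


@dataclass
class AlleleSpec:
    label: str
    frequency: float
    edits: list[Edit] = field(default_factory=list)


@dataclass
class ErrorModel:
    """Per-base error probabilities of the PCR and sequencing stages."""

    pcr_per_base: float = SUPERFI_PER_BASE
    seq_sub: float = 0.0
    seq_ins: float = 0.0
    seq_del: float = 0.0
    read_len: int | str = "full"
    base_qual: int = 30

    PLATFORM_PROFILES = {
        # Nanopore raw-read error split; the defaults are calibration
        # choices for a high-error long-read platform, not measured values.
        "nanopore": dict(seq_sub=0.05, seq_ins=0.03, seq_del=0.04,
                         read_len="full", base_qual=12),
        "illumina": dict(seq_sub=0.001, seq_ins=0.0001, seq_del=0.0001,
                         read_len=150, base_qual=35),
        "pacbio": dict(seq_sub=0.002, seq_ins=0.003, seq_del=0.003,
                       read_len="full", base_qual=30),
    }

    @classmethod
    def for_platform(cls, platform: str, pcr_per_base: float = SUPERFI_PER_BASE):
        try:
            profile = cls.PLATFORM_PROFILES[platform]
        except KeyError:
            raise SpecError(f"unknown platform {platform!r}") from None
        return cls(pcr_per_base=pcr_per_base, **profile)

    def validate(self) -> None:
        for name in ("pcr_per_base", "seq_sub", "seq_ins", "seq_del"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SpecError(f"error_model.{name} = {v} outside [0,1)")
        if self.seq_sub + self.seq_ins + self.seq_del >= 1.0:
            raise SpecError("seq_sub + seq_ins + seq_del must be < 1")


@dataclass
class ReadDepth:
    """Reads per molecule ~ negative binomial(mean, dispersion)."""

    mean: float = 8.0
    dispersion: float = 4.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean < 1:
            raise SpecError("reads_per_molecule mean must be >= 1")
        r = self.dispersion
        p = r / (r + self.mean)
        return rng.negative_binomial(r, p, size=n)


@dataclass
class PopulationSpec:
    reference: str
    alleles: list[AlleleSpec]
    n_molecules: int
    umi_design: UMIDesign
    somatic_snv_per_mb: float = 0.0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    reads_per_molecule: ReadDepth = field(default_factory=ReadDepth)
    platform: str = "nanopore"
    two_ended: bool = False
    seed: int = 0

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.n_molecules < 1:
            problems.append("n_molecules must be >= 1")
        if self.somatic_snv_per_mb < 0:
            problems.append("somatic_snv_per_mb must be >= 0")
        total = sum(a.frequency for a in self.alleles)
        if abs(total - 1.0) > 1e-6:
            problems.append(f"allele frequencies sum to {total:.6g}, not 1")
        L = len(self.reference)
        for allele in self.alleles:
            deleted: list[tuple[int, int]] = []
            for e in allele.edits:
                s, t = e.interval()
                if s < 0 or t > L:
                    problems.append(
                        f"allele {allele.label}: edit at {e.pos} outside reference"
                    )
                for ds, dt in deleted:
                    if s < dt and ds < t:
                        problems.append(
                            f"allele {allele.label}: edit at {e.pos} overlaps "
                            "a deleted interval"
                        )
                if e.kind in ("deletion", "inversion"):
                    deleted.append((s, t))
        if self.platform not in ErrorModel.PLATFORM_PROFILES:
            problems.append(f"unknown platform {self.platform!r}")
        try:
            self.error_model.validate()
        except SpecError as exc:
            problems.append(str(exc))
        return problems


def apply_edits(reference: str, edits: Sequence[Edit]) -> str:
    """Apply non-overlapping edits (reference coordinates) left to right."""
    parts: list[str] = []
    cursor = 0
    for e in sorted(edits, key=lambda e: (e.pos, e.kind)):
        if e.pos < cursor:
            raise UmivarError(f"overlapping edits at position {e.pos}")
        if e.kind == "snv":
            parts.append(reference[cursor : e.pos])
            parts.append(str(e.payload))
            cursor = e.pos + 1
        elif e.kind == "deletion":
            parts.append(reference[cursor : e.pos])
            cursor = e.pos + int(e.payload)
        elif e.kind == "insertion":
            parts.append(reference[cursor : e.pos + 1])
            parts.append(str(e.payload))
            cursor = e.pos + 1
        elif e.kind == "inversion":
            parts.append(reference[cursor : e.pos])
            end = e.pos + int(e.payload)
            parts.append(reverse_complement(reference[e.pos : end]))
            cursor = end
        else:
            raise UmivarError(f"unknown edit kind {e.kind!r}")
    parts.append(reference[cursor:])
    return "".join(parts)


@dataclass
class MoleculeTruth:
    molecule_id: str
    allele: str
    edits: list[Edit]
    umi: str | None = None
    read_ids: list[str] = field(default_factory=list)


@dataclass
class TruthTable:
    """Molecule-level ledger: molecule -> allele, UMI, true edits, reads."""

    molecules: list[MoleculeTruth]

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def variant_support(self, min_reads: int = 1) -> dict[tuple, int]:
        """Canonical variant key -> number of molecules carrying it that
        produced at least ``min_reads`` reads (the expected supporting-group
        count under error-free analysis)."""
        support: dict[tuple, int] = {}
        for mol in self.molecules:
            if len(mol.read_ids) < min_reads:
                continue
            for e in mol.edits:
                support[e.key()] = support.get(e.key(), 0) + 1
        return support

    def all_read_ids(self) -> set[str]:
        ids: set[str] = set()
        for mol in self.molecules:
            ids.update(mol.read_ids)
        return ids

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("molecule_id\tallele\tumi\tedits\tread_ids\n")
            for mol in self.molecules:
                edits = ",".join(
                    f"{e.kind}:{e.pos}:{e.payload}" for e in mol.edits
                )
                fh.write(
                    f"{mol.molecule_id}\t{mol.allele}\t{mol.umi or '.'}\t"
                    f"{edits or '.'}\t{','.join(mol.read_ids) or '.'}\n"
                )


def build_population(spec: PopulationSpec) -> tuple[list[str], TruthTable]:
    """Draw molecules from the allele mix and sprinkle somatic SNVs.

    Each molecule picks an allele by frequency, then receives
    Binomial(L, somatic_snv_per_mb/1e6) independent somatic SNVs at
    positions not touched by the allele's own edits. Deterministic under
    ``spec.seed``.
    """
    problems = spec.validate()
    if problems:
        raise SpecError("; ".join(problems))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ref = spec.reference.upper()
    L = len(ref)
    freqs = np.array([a.frequency for a in spec.alleles])
    choices = rng.choice(len(spec.alleles), size=spec.n_molecules, p=freqs)
    per_base_rate = spec.somatic_snv_per_mb / 1e6

    blocked: list[np.ndarray] = []
    for allele in spec.alleles:
        mask = np.zeros(L, dtype=bool)
        for e in allele.edits:
            s, t = e.interval()
            mask[s:t] = True
        blocked.append(mask)

    molecules: list[str] = []
    truth_rows: list[MoleculeTruth] = []
    width = len(str(spec.n_molecules - 1))
    for i, ai in enumerate(choices):
        allele = spec.alleles[ai]
        edits = list(allele.edits)
        if per_base_rate > 0:
            k = rng.binomial(L, per_base_rate)
            if k:
                open_pos = np.nonzero(~blocked[ai])[0]
                pos = rng.choice(open_pos, size=min(k, len(open_pos)), replace=False)
                for p in np.sort(pos):
                    alt = _BASES[(_CODE[ref[p]] + rng.integers(1, 4)) % 4]
                    edits.append(Edit("snv", int(p), alt))
        molecules.append(apply_edits(ref, edits))
        truth_rows.append(MoleculeTruth(f"mol{i:0{width}d}", allele.label, edits))
    return molecules, TruthTable(truth_rows)


def _sample_umis(design: UMIDesign, n: int, rng: np.random.Generator) -> list[str]:
    space = umi_space_size(design.umi_pattern)
    if n > space:
        raise SpecError(
            f"{n} molecules exceed the structured-UMI space of {space} "
            f"for pattern {design.umi_pattern!r}"
        )
    codes = rng.choice(space, size=n, replace=False)
    n_pos = [i for i, b in enumerate(design.umi_pattern) if b == "N"]
    umis = []
    for code in codes:
        umi = list(design.umi_pattern)
        c = int(code)
        for i in n_pos:
            umi[i] = _BASES[c & 3]
            c >>= 2
        umis.append("".join(umi))
    return umis


def tag_with_umis(
    molecules: list[str],
    truth: TruthTable,
    design: UMIDesign,
    seed: int,
    two_ended: bool = False,
) -> list[str]:
    """Prepend universal primer + a unique structured UMI to each molecule.

    UMIs are sampled without replacement from the pattern space, so
    collisions are impossible by construction (each molecule is uniquely
    represented by one UMI group). With ``two_ended`` the 3' end receives a
    second, independent tag as well.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = len(molecules)
    umis = _sample_umis(design, 2 * n if two_ended else n, rng)
    tagged = []
    for i, mol in enumerate(molecules):
        seq = design.universal_primer + umis[i] + mol
        if two_ended:
            seq = seq + reverse_complement(design.universal_primer + umis[n + i])
        tagged.append(seq)
        truth.molecules[i].umi = umis[i]
    return tagged


def _mutate(codes: np.ndarray, sub: float, ins: float, dele: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitution/insertion/deletion errors to a coded
    sequence (0..3). Insertions are placed after the position drawn."""
    n = len(codes)
    draw = rng.random(n)
    del_mask = draw < dele
    sub_mask = (draw >= dele) & (draw < dele + sub)
    out_base = codes.copy()
    if sub_mask.any():
        out_base[sub_mask] = (
            codes[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))
        ) % 4
    ins_mask = rng.random(n) < ins
    if not del_mask.any() and not ins_mask.any():
        return out_base
    keep = ~del_mask
    counts = keep.astype(np.int64) + ins_mask.astype(np.int64)
    pos_order = np.repeat(np.arange(n), counts)
    out = out_base[pos_order]
    occ = np.arange(len(out)) - np.repeat(np.cumsum(counts) - counts, counts)
    ins_slots = ins_mask[pos_order] & (occ == counts[pos_order] - 1)
    if ins_slots.any():
        out[ins_slots] = rng.integers(0, 4, size=int(ins_slots.sum()))
    return out


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(len(arr), dtype=np.int64)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def amplify_and_sequence(
    tagged: list[str],
    truth: TruthTable,
    error_model: ErrorModel,
    depth: ReadDepth,
    platform: str,
    seed: int,
) -> list[FastqRead]:
    """PCR-then-sequence each tagged molecule into FASTQ reads.

    One polymerase-error pass (substitutions at ``pcr_per_base``) is applied
    to the barcoded first copy, so a PCR error propagates to every read of
    that molecule. Each read then receives independent sequencing errors.
    Long-read platforms emit full-length reads, about half of them
    reverse-complemented; Illumina mode emits paired ``read_len``-base ends.
    """
    error_model.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_reads = depth.sample(len(tagged), rng)
    paired = platform == "illumina"
    read_len = error_model.read_len
    reads: list[FastqRead] = []
    for mol_i, (seq, k) in enumerate(zip(tagged, n_reads)):
        mol = truth.molecules[mol_i]
        codes = _encode(seq)
        if error_model.pcr_per_base > 0:
            pcr_mask = rng.random(len(codes)) < error_model.pcr_per_base
            if pcr_mask.any():
                codes = codes.copy()
                codes[pcr_mask] = (
                    codes[pcr_mask] + rng.integers(1, 4, size=int(pcr_mask.sum()))
                ) % 4
        for j in range(int(k)):
            read_id = f"{mol.molecule_id}.r{j}"
            out = _mutate(
                codes, error_model.seq_sub, error_model.seq_ins,
                error_model.seq_del, rng,
            )
            if paired:
                L = int(read_len)
                fwd = _decode(out[:L])
                rev = reverse_complement(_decode(out[max(0, len(out) - L):]))
                qual1 = [error_model.base_qual] * len(fwd)
                qual2 = [error_model.base_qual] * len(rev)
                reads.append(FastqRead(read_id, fwd, qual1, mate="r1"))
                reads.append(FastqRead(read_id, rev, qual2, mate="r2"))
            else:
                read_seq = _decode(out)
                if rng.random() < 0.5:
                    read_seq = reverse_complement(read_seq)
                reads.append(
                    FastqRead(read_id, read_seq,
                              [error_model.base_qual] * len(read_seq))
                )
            mol.read_ids.append(read_id)
    return reads


def simulate_run(spec: PopulationSpec) -> tuple[list[FastqRead], TruthTable, dict]:
    """Full simulation: population -> UMI tagging -> amplify & sequence."""
    molecules, truth = build_population(spec)
    tagged = tag_with_umis(
        molecules, truth, spec.umi_design, spec.seed, spec.two_ended
    )
    reads = amplify_and_sequence(
        tagged, truth, spec.error_model, spec.reads_per_molecule,
        spec.platform, spec.seed,
    )
    manifest = {
        "seed": spec.seed,
        "n_molecules": spec.n_molecules,
        "platform": spec.platform,
        "reference_length": len(spec.reference),
        "alleles": {a.label: a.frequency for a in spec.alleles},
        "somatic_snv_per_mb": spec.somatic_snv_per_mb,
        "n_reads": len(reads),
    }
    return reads, truth, manifest


def spec_from_json(path: str | Path) -> PopulationSpec:
    """Load a PopulationSpec from a JSON document (CLI entry point)."""
    with open(path) as fh:
        doc = json.load(fh)
    problems = []
    for req in ("reference", "alleles", "n_molecules", "umi_design"):
        if req not in doc:
            problems.append(f"missing field {req!r}")
    if problems:
        raise SpecError("; ".join(problems))
    reference = doc["reference"]
    if isinstance(reference, str) and Path(reference).exists():
        from .io import read_fasta

        reference = next(iter(read_fasta(reference).values()))
    alleles = [
        AlleleSpec(
            a["label"], a["frequency"],
            [Edit(e["kind"], e["pos"], e["payload"]) for e in a.get("edits", [])],
        )
        for a in doc["alleles"]
    ]
    design = UMIDesign(**doc["umi_design"])
    platform = doc.get("platform", "nanopore")
    if "error_model" in doc:
        error_model = ErrorModel(**doc["error_model"])
    else:
        error_model = ErrorModel.for_platform(platform)
    spec = PopulationSpec(
        reference=reference,
        alleles=alleles,
        n_molecules=doc["n_molecules"],
        umi_design=design,
        somatic_snv_per_mb=doc.get("somatic_snv_per_mb", 0.0),
        error_model=error_model,
        reads_per_molecule=ReadDepth(**doc.get("reads_per_molecule", {})),
        platform=platform,
        two_ended=doc.get("two_ended", False),
        seed=doc.get("seed", 0),
    )
    problems = spec.validate()
    if problems:
        raise SpecError("; ".join(problems))
    return spec
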