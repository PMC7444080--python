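"""Read-to-amplicon alignment with a two-piece affine gap cost.

The aligner is a full dynamic program (no seeding heuristics): semi-global,
with free end gaps on the reference, while unaligned query ends are
soft-clipped at the same two-piece gap charge as an internal gap — cheap
enough to absorb residual adapter, expensive enough that a read never gets
truncated at a large deletion it should align across. The gap cost is
two-piece — a gap of length L costs
``min(gap_open + L*gap_extend, long_gap_open + L*long_gap_extend)`` — so a
multi-kilobase deletion survives as a single D run instead of fragmenting,
which is what makes CIGAR-based structural-variant calling possible.
Inversions are found by realigning poorly-aligned internal read segments to
the reverse complement of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import UmivarError
from .umi import reverse_complement

__all__ = [
    "AlignmentParams",
    "Alignment",
    "InversionEvidence",
    "align_read",
    "detect_inversion",
]

_BASES = "ACGTN"


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 2
    mismatch: float = 4
    gap_open: float = 4
    gap_extend: float = 2
    long_gap_open: float = 24
    # 1/16: cheap enough that a multi-kilobase deletion costs less than the
    # matches its flanks earn, and exactly representable in binary so that
    # accumulated and closed-form gap costs agree bit for bit
    long_gap_extend: float = 0.0625

    def __post_init__(self) -> None:
        if self.long_gap_extend >= self.gap_extend:
            raise UmivarError(
                "long_gap_extend must be < gap_extend (long gaps eventually cheaper)"
            )
        for name in ("mismatch", "gap_open", "gap_extend",
                     "long_gap_open", "long_gap_extend"):
            if getattr(self, name) < 0:
                raise UmivarError(f"{name} must be >= 0")

    def gap_cost(self, length: int) -> float:
        return min(
            self.gap_open + length * self.gap_extend,
            self.long_gap_open + length * self.long_gap_extend,
        )


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class Alignment:
    """Placement of a read on the reference.

    ``cigar`` uses =/X/I/D/S; coordinates are 0-based half-open. ``query``
    is the read sequence in the aligned orientation (reverse-complemented
    when ``strand`` is '-'), so the CIGAR applies to it directly.
    """

    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str
    score: float
    query: str = field(repr=False, default="")

    def cigar_tuples(self) -> list[tuple[str, int]]:
        out = []
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                out.append((ch, int(num)))
                num = ""
        return out

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar_tuples() if op in "=XIS")

    def ref_consumed(self) -> int:
        return sum(n for op, n in self.cigar_tuples() if op in "=XD")


# DP states
_M, _D1, _D2, _I1, _I2, _START = 0, 1, 2, 3, 4, 5
_NEG = -1e18


@njit(cache=True)
def _clip_cost(k, go, ge, lo, le):  # pragma: no cover - jitted
    if k <= 0:
        return 0
    a = go + k * ge
    b = lo + k * le
    return a if a < b else b


@njit(cache=True)
def _dp_fill(q, r, match, mismatch, go, ge, lo, le,
             tbM, tbD1, tbD2, tbI1, tbI2):  # pragma: no cover - jitted
    n = q.shape[0]
    m = r.shape[0]
    Mp = np.full(m + 1, _NEG, np.float64)
    D1p = np.full(m + 1, _NEG, np.float64)
    D2p = np.full(m + 1, _NEG, np.float64)
    I1p = np.full(m + 1, _NEG, np.float64)
    I2p = np.full(m + 1, _NEG, np.float64)
    Mc = np.full(m + 1, _NEG, np.float64)
    D1c = np.full(m + 1, _NEG, np.float64)
    D2c = np.full(m + 1, _NEG, np.float64)
    I1c = np.full(m + 1, _NEG, np.float64)
    I2c = np.full(m + 1, _NEG, np.float64)
    best = _NEG
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        Mc[0] = _NEG
        D1c[0] = _NEG
        D2c[0] = _NEG
        I1c[0] = _NEG
        I2c[0] = _NEG
        qi = q[i - 1]
        lead = -_clip_cost(i - 1, go, ge, lo, le)
        trail = _clip_cost(n - i, go, ge, lo, le)
        for j in range(1, m + 1):
            # match/mismatch state: diagonal predecessor, or a fresh start
            # that pays a gap charge for the i-1 skipped query bases
            diag = lead
            ptr = _START
            if Mp[j - 1] > diag:
                diag = Mp[j - 1]
                ptr = _M
            if D1p[j - 1] > diag:
                diag = D1p[j - 1]
                ptr = _D1
            if D2p[j - 1] > diag:
                diag = D2p[j - 1]
                ptr = _D2
            if I1p[j - 1] > diag:
                diag = I1p[j - 1]
                ptr = _I1
            if I2p[j - 1] > diag:
                diag = I2p[j - 1]
                ptr = _I2
            if qi == r[j - 1] and qi < 4:
                s = diag + match
            else:
                s = diag - mismatch
            Mc[j] = s
            tbM[i, j] = ptr
            # alignment may end here, paying a gap charge for the n-i
            # remaining query bases (reference end gaps stay free)
            if s - trail > best:
                best = s - trail
                bi = i
                bj = j
            # insertion states (consume query, vertical)
            iopen = Mp[j]
            iptr = _M
            if D1p[j] > iopen:
                iopen = D1p[j]
                iptr = _D1
            if D2p[j] > iopen:
                iopen = D2p[j]
                iptr = _D2
            v_open = iopen - go - ge
            v_ext = I1p[j] - ge
            if v_open >= v_ext:
                I1c[j] = v_open
                tbI1[i, j] = iptr + 1
            else:
                I1c[j] = v_ext
                tbI1[i, j] = 0
            v_open = iopen - lo - le
            v_ext = I2p[j] - le
            if v_open >= v_ext:
                I2c[j] = v_open
                tbI2[i, j] = iptr + 1
            else:
                I2c[j] = v_ext
                tbI2[i, j] = 0
            # deletion states (consume reference, horizontal)
            dopen = Mc[j - 1]
            dptr = _M
            if I1c[j - 1] > dopen:
                dopen = I1c[j - 1]
                dptr = _I1
            if I2c[j - 1] > dopen:
                dopen = I2c[j - 1]
                dptr = _I2
            v_open = dopen - go - ge
            v_ext = D1c[j - 1] - ge
            if v_open >= v_ext:
                D1c[j] = v_open
                tbD1[i, j] = dptr + 1
            else:
                D1c[j] = v_ext
                tbD1[i, j] = 0
            v_open = dopen - lo - le
            v_ext = D2c[j - 1] - le
            if v_open >= v_ext:
                D2c[j] = v_open
                tbD2[i, j] = dptr + 1
            else:
                D2c[j] = v_ext
                tbD2[i, j] = 0
        Mp, Mc = Mc, Mp
        D1p, D1c = D1c, D1p
        D2p, D2c = D2c, D2p
        I1p, I1c = I1c, I1p
        I2p, I2c = I2c, I2p
    return best, bi, bj


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        codes[arr == ord(base)] = i
    return codes


def _rle(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def _align_one_strand(
    q: np.ndarray, r: np.ndarray, params: AlignmentParams
) -> tuple[float, int, int, int, list[str]]:
    """Run the DP on one orientation; return (score, qs, rs, re, ops)."""
    n, m = len(q), len(r)
    tbM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbD1 = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbD2 = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbI1 = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbI2 = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best, bi, bj = _dp_fill(
        q, r, params.match, params.mismatch,
        params.gap_open, params.gap_extend,
        params.long_gap_open, params.long_gap_extend,
        tbM, tbD1, tbD2, tbI1, tbI2,
    )
    # traceback from the best-scoring match cell
    ops: list[str] = []
    i, j, state = bi, bj, _M
    while True:
        if state == _M:
            ptr = tbM[i, j]
            ops.append("=" if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else "X")
            i -= 1
            j -= 1
            if ptr == _START:
                break
            state = ptr
        elif state in (_D1, _D2):
            tb = tbD1[i, j] if state == _D1 else tbD2[i, j]
            ops.append("D")
            j -= 1
            if tb != 0:
                state = tb - 1
        else:
            tb = tbI1[i, j] if state == _I1 else tbI2[i, j]
            ops.append("I")
            i -= 1
            if tb != 0:
                state = tb - 1
    ops.reverse()
    return float(best), i, j, bj, ops


def align_read(
    query: str,
    reference: str,
    params: AlignmentParams | None = None,
    read_id: str = "",
    min_score_frac: float = 0.25,
    both_strands: bool = True,
) -> Alignment | None:
    """Align a read to the amplicon reference; try both strands, keep the
    better. Unaligned query ends are soft-clipped at the two-piece gap
    charge; reference end gaps are free. Returns None when the best score
    is below ``min_score_frac * match * len(query)`` (unmappable read)."""
    if not query or not reference:
        raise UmivarError("align_read requires non-empty sequences")
    params = params or DEFAULT_PARAMS
    r = _encode(reference)
    q_fwd = _encode(query)
    candidates = [("+", query, q_fwd)]
    if both_strands:
        rc = reverse_complement(query)
        candidates.append(("-", rc, _encode(rc)))
    best = None
    for strand, oriented, q in candidates:
        score, qs, rs, re_, ops = _align_one_strand(q, r, params)
        if best is None or score > best[0]:
            best = (score, strand, oriented, qs, rs, re_, ops)
    score, strand, oriented, qs, rs, re_, ops = best
    if score < min_score_frac * params.match * len(query):
        return None
    qe = qs + sum(1 for op in ops if op in "=XI")
    full_ops = ["S"] * qs + ops + ["S"] * (len(query) - qe)
    return Alignment(
        read_id=read_id,
        ref_start=rs,
        ref_end=re_,
        strand=strand,
        cigar=_rle(full_ops),
        score=score,
        query=oriented,
    )


@dataclass
class InversionEvidence:
    """A read segment whose best placement is on the minus strand, nested
    inside the read's plus-strand flanks: the signature of an inversion."""

    read_id: str
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    minus_alignment: Alignment
    score: int


def _candidate_segments(alignment: Alignment, min_sv_len: int) -> list[tuple[int, int]]:
    """Query intervals of poorly-aligned internal stretches: long I runs,
    or blocks of X/I/D interrupted only by short exact runs."""
    candidates: list[tuple[int, int]] = []
    qpos = 0
    blocks: list[tuple[int, int, int]] = []  # (q_start, q_end, n_match)
    cur_start, cur_matches, in_block = 0, 0, False
    for op, n in alignment.cigar_tuples():
        q_consumes = op in "=XIS"
        if op == "I" and n >= min_sv_len:
            candidates.append((qpos, qpos + n))
        if op in "XID" and op != "S":
            if not in_block:
                cur_start, cur_matches, in_block = qpos, 0, True
        elif op == "=" and in_block and n <= 12:
            # accidental match runs inside an inverted segment are short;
            # bridging them keeps the candidate in one piece
            cur_matches += n
        else:
            if in_block:
                blocks.append((cur_start, qpos, cur_matches))
                in_block = False
        if q_consumes:
            qpos += n
    if in_block:
        blocks.append((cur_start, qpos, cur_matches))
    for qs, qe, n_match in blocks:
        span = qe - qs
        if span >= min_sv_len and n_match <= 0.75 * span:
            if not any(qs >= s and qe <= e for s, e in candidates):
                candidates.append((qs, qe))
    return candidates


def detect_inversion(
    primary: Alignment,
    reference: str,
    params: AlignmentParams | None = None,
    min_sv_len: int = 31,
    min_score_frac: float = 0.35,
    tol: int = 50,
) -> InversionEvidence | None:
    """Realign suspicious internal segments of ``primary`` to the reverse
    complement of the reference; report evidence when a segment places on
    the minus strand, nested within the primary plus-strand span."""
    params = params or DEFAULT_PARAMS
    rc_ref = reverse_complement(reference)
    L = len(reference)
    best: InversionEvidence | None = None
    for qs, qe in _candidate_segments(primary, min_sv_len):
        segment = primary.query[qs:qe]
        if len(segment) < min_sv_len:
            continue
        hit = align_read(
            segment, rc_ref, params,
            read_id=primary.read_id,
            min_score_frac=min_score_frac,
            both_strands=False,
        )
        if hit is None:
            continue
        ref_interval = (L - hit.ref_end, L - hit.ref_start)
        if ref_interval[1] - ref_interval[0] < min_sv_len:
            continue
        nested = (
            ref_interval[0] >= primary.ref_start - tol
            and ref_interval[1] <= primary.ref_end + tol
        )
        if not nested:
            continue
        evidence = InversionEvidence(
            read_id=primary.read_id,
            ref_interval=ref_interval,
            query_interval=(qs, qe),
            minus_alignment=hit,
            score=hit.score,
        )
        if best is None or evidence.score > best.score:
            best = evidence
    return best
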