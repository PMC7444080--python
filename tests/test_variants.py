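from collections import Counter

import numpy as np
import pytest

from conftest import make_design, make_ref, spikein_spec
from umivar import AlleleSpec, Edit, ErrorModel, PopulationSpec, simulate_run
from umivar.align import Alignment, align_read
from umivar.errors import UmivarError
from umivar.io import write_vcf
from umivar.pipeline import run_analysis
from umivar.umi import reverse_complement
from umivar.variants import (
    FilterParams,
    GroupCalls,
    Pileup,
    call_group,
    call_small_indels,
    call_snvs,
    call_svs,
    group_filter,
    left_align_deletion,
    left_align_insertion,
    merge_and_filter,
    pileup_group,
)

PARAMS = FilterParams()


def _aln(ref, cigar, query, ref_start=0, rid="r"):
    tuples = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            tuples.append((ch, int(num)))
            num = ""
    ref_len = sum(n for op, n in tuples if op in "=XD")
    return Alignment(rid, ref_start, ref_start + ref_len, "+", cigar, 0.0, query)


def _identical_group(ref, n, span=None):
    span = span or (0, len(ref))
    seq = ref[span[0] : span[1]]
    return [
        _aln(ref, f"{len(seq)}=", seq, ref_start=span[0], rid=f"r{i}")
        for i in range(n)
    ]


class TestPileup:
    def test_identical_reads(self):
        ref = make_ref(100, 1)
        pileup = pileup_group(_identical_group(ref, 5), ref)
        assert (pileup.depth == 5).all()
        consensus = pileup.counts[:4].argmax(axis=0)
        assert "".join("ACGT"[c] for c in consensus) == ref

    def test_constructed_mismatch_counts(self):
        ref = "A" * 100
        alns = [
            _aln(ref, "50=1X49=", "A" * 50 + "T" + "A" * 49, rid=f"t{i}")
            for i in range(4)
        ] + [_aln(ref, "100=", "A" * 100, rid="wt")]
        pileup = pileup_group(alns, ref)
        assert pileup.counts[3, 50] == 4  # T
        assert pileup.counts[0, 50] == 1  # A
        assert pileup.depth[50] == 5

    def test_empty_group_rejected(self):
        with pytest.raises(UmivarError):
            pileup_group([], "ACGT")

    def test_error_rate_within_binomial_band(self, ref168):
        # 8 noisy reads: substitution count near 0.05 * 8 * 168
        from umivar.simulate import _decode, _encode, _mutate

        rng = np.random.default_rng(3)
        alns = []
        for i in range(8):
            q = _decode(_mutate(_encode(ref168), 0.05, 0.0, 0.0, rng))
            alns.append(align_read(q, ref168, read_id=f"r{i}"))
        pileup = pileup_group(alns, ref168)
        consensus_mismatches = int(
            pileup.depth.sum() - sum(pileup.counts["ACGT".index(b), i]
                                     for i, b in enumerate(ref168))
        )
        mean = 0.05 * 8 * 168
        sd = np.sqrt(mean * 0.95)
        assert abs(consensus_mismatches - mean) < 3 * sd


class TestCallSnvs:
    def _pileup_at(self, ref, pos, counts: dict):
        p = np.zeros((5, len(ref)), dtype=np.int32)
        for i, b in enumerate(ref):
            p["ACGT".index(b), i] = 5
        p[:, pos] = 0
        for base, n in counts.items():
            p["ACGT".index(base), pos] = n
        return Pileup(p, {}, 5)

    def test_consensus_call(self):
        ref = "A" * 100
        pileup = self._pileup_at(ref, 50, {"T": 4, "A": 1})
        calls = call_snvs(pileup, ref, PARAMS)
        assert calls == [(50, "A", "T", 0.8)]

    def test_below_consensus_no_call(self):
        ref = "A" * 100
        pileup = self._pileup_at(ref, 50, {"T": 3, "A": 2})
        assert call_snvs(pileup, ref, PARAMS) == []

    def test_low_depth_no_call(self):
        ref = "A" * 100
        pileup = self._pileup_at(ref, 50, {"T": 4})
        assert call_snvs(pileup, ref, PARAMS) == []

    def test_monotone_in_consensus_fraction(self, ref168):
        from umivar.simulate import _decode, _encode, _mutate

        rng = np.random.default_rng(5)
        alns = [
            align_read(_decode(_mutate(_encode(ref168), 0.15, 0.0, 0.0, rng)),
                       ref168, read_id=f"r{i}")
            for i in range(6)
        ]
        pileup = pileup_group(alns, ref168)
        counts = [
            len(call_snvs(pileup, ref168, FilterParams(consensus_fraction=f)))
            for f in (0.5, 0.75, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSmallIndels:
    def test_unanimous_small_deletion(self):
        ref = make_ref(300, 2)
        query = ref[:120] + ref[123:]
        alns = [_aln(ref, "120=3D177=", query, rid=f"r{i}") for i in range(5)]
        pileup = pileup_group(alns, ref)
        calls = call_small_indels(alns, pileup, ref, PARAMS)
        assert len(calls) == 1
        pos, kind, length, _seq, frac = calls[0]
        assert kind == "deletion"
        assert length == 3
        assert pos == left_align_deletion(ref, 120, 3)
        assert frac == 1.0

    def test_single_read_insertion_not_called(self):
        ref = make_ref(200, 3)
        clean = [_aln(ref, "200=", ref, rid=f"c{i}") for i in range(7)]
        withins = _aln(ref, "100=1I100=", ref[:100] + "A" + ref[100:], rid="i")
        pileup = pileup_group(clean + [withins], ref)
        assert call_small_indels(clean + [withins], pileup, ref, PARAMS) == []

    def test_left_alignment_of_homopolymer_indels(self):
        ref = "GGGAAAATTT"
        assert left_align_deletion(ref, 5, 2) == 3
        pos, seq = left_align_insertion(ref, 6, "AA")
        assert (pos, seq) == (2, "AA")

    def test_cas9_like_indel_spectrum_recovered(self):
        # truth: -2, -5 and +1 alleles at a cut site, recovered exactly
        ref = make_ref(400, 9)
        cut = 200
        ins_base = "A" if ref[cut] != "A" else "C"
        spec = PopulationSpec(
            reference=ref,
            alleles=[
                AlleleSpec("wt", 0.4),
                AlleleSpec("del2", 0.2, [Edit("deletion", cut - 1, 2)]),
                AlleleSpec("del5", 0.2, [Edit("deletion", cut - 2, 5)]),
                AlleleSpec("ins1", 0.2, [Edit("insertion", cut, ins_base)]),
            ],
            n_molecules=60,
            umi_design=make_design(ref),
            error_model=ErrorModel(pcr_per_base=0.0),
            seed=21,
        )
        reads, truth, _ = simulate_run(spec)
        res = run_analysis(reads, ref, spec.umi_design)
        called = {
            (v.kind, v.pos, v.end if v.kind == "deletion" else v.alt[1:])
            for v in res.callset.variants
        }
        expected = set()
        for kind, pos, payload in (
            ("deletion", cut - 1, 2), ("deletion", cut - 2, 5),
        ):
            p = left_align_deletion(ref, pos, payload)
            expected.add(("deletion", p, p + payload))
        p, seq = left_align_insertion(ref, cut, ins_base)
        expected.add(("insertion", p, seq))
        assert expected <= called


class TestCallSvs:
    def test_recurrent_large_deletion(self):
        ref = make_ref(5700, 4)
        rng = np.random.default_rng(0)
        alns = []
        for i in range(8):
            start = 1000 + int(rng.integers(-3, 4))
            q = ref[:start] + ref[start + 2375:]
            alns.append(_aln(ref, f"{start}=2375D{len(ref)-start-2375}=", q, rid=f"r{i}"))
        calls = call_svs(alns, {}, ref, PARAMS)
        assert len(calls) == 1
        kind, a, b, _seq, frac = calls[0]
        assert kind == "deletion"
        assert b - a == pytest.approx(2375, abs=5)
        assert abs(a - 1000) <= 5
        assert frac == 1.0

    def test_30bp_deletion_is_small_indel_not_sv(self):
        ref = make_ref(500, 5)
        q = ref[:200] + ref[230:]
        alns = [_aln(ref, "200=30D270=", q, rid=f"r{i}") for i in range(8)]
        assert call_svs(alns, {}, ref, PARAMS) == []
        pileup = pileup_group(alns, ref)
        indels = call_small_indels(alns, pileup, ref, PARAMS)
        assert [(k, L) for _p, k, L, _s, _f in indels] == [("deletion", 30)]

    def test_chimeric_minority_not_called(self):
        ref = make_ref(2000, 6)
        clean = [_aln(ref, "2000=", ref, rid=f"c{i}") for i in range(6)]
        chim_q = ref[:700] + ref[1200:]
        chim = [_aln(ref, "700=500D800=", chim_q, rid=f"x{i}") for i in range(2)]
        assert call_svs(clean + chim, {}, ref, PARAMS) == []

    def test_sv_size_boundary_at_31(self):
        ref = make_ref(500, 7)
        q = ref[:200] + ref[231:]
        alns = [_aln(ref, "200=31D269=", q, rid=f"r{i}") for i in range(8)]
        calls = call_svs(alns, {}, ref, PARAMS)
        assert len(calls) == 1
        assert calls[0][0] == "deletion"


class TestGroupFilter:
    def test_clean_group_retained(self, ref168):
        alns = _identical_group(ref168, 6)
        calls = call_group("UMI", alns, {}, ref168, PARAMS)
        assert calls.pass_filter

    def test_umi_collision_dropped(self):
        # 4 reads from a wild-type molecule + 4 from a divergent haplotype
        # (several private SNVs) under one UMI
        ref = make_ref(1000, 8)
        other = list(ref)
        rng = np.random.default_rng(4)
        for pos in rng.choice(1000, 8, replace=False):
            other[pos] = "ACGT"[("ACGT".index(other[pos]) + 1) % 4]
        other = "".join(other)
        alns = [_aln(ref, "1000=", ref, rid=f"a{i}") for i in range(4)] + [
            align_read(other, ref, read_id=f"b{i}") for i in range(4)
        ]
        calls = call_group("UMI", alns, {}, ref, PARAMS)
        assert not calls.pass_filter
        assert "collision" in calls.filter_reason

    def test_mixed_sv_structure_dropped(self):
        # 4 wild-type reads + 4 reads with a 1-kb deletion under one UMI
        ref = make_ref(2000, 9)
        del_q = ref[:500] + ref[1500:]
        alns = [_aln(ref, "2000=", ref, rid=f"w{i}") for i in range(4)] + [
            _aln(ref, "500=1000D500=", del_q, rid=f"d{i}") for i in range(4)
        ]
        calls = call_group("UMI", alns, {}, ref, PARAMS)
        assert not calls.pass_filter

    def test_shuffled_reads_dropped_on_identity(self):
        ref = make_ref(500, 10)
        rng = np.random.default_rng(11)
        alns = []
        for i in range(6):
            q = list(ref)
            for pos in rng.choice(500, 200, replace=False):
                q[pos] = "ACGT"[("ACGT".index(q[pos]) + int(rng.integers(1, 4))) % 4]
            aln = align_read("".join(q), ref, read_id=f"r{i}", min_score_frac=-10)
            alns.append(aln)
        calls = call_group("UMI", alns, {}, ref, PARAMS)
        assert not calls.pass_filter
        assert calls.mean_identity < 0.7

    def test_group_filter_drops_flagged(self):
        good = GroupCalls("A", 6, pass_filter=True)
        bad = GroupCalls("B", 6, pass_filter=False)
        assert group_filter([good, bad], PARAMS) == [good]


class TestMergeAndFilter:
    def _group(self, umi, snvs, n=10):
        return GroupCalls(umi, n, snvs=snvs)

    def test_merge_identical_and_distinct(self):
        ref = make_ref(200, 12)
        groups = [
            self._group("AAA", [(50, ref[50], "T", 1.0)]),
            self._group("CCC", [(50, ref[50], "T", 0.9)]),
            self._group("GGG", [(80, ref[80], "C", 1.0)]),
        ]
        callset, entries = merge_and_filter(groups, ref, PARAMS)
        assert len(callset) == 2
        supports = sorted(v.support for v in callset.variants)
        assert supports == [1, 2]
        assert callset.total_groups == 3
        # one VCF line per (variant, supporting group)
        assert len(entries) == 3
        assert {e.id for e in entries} == {"AAA_10", "CCC_10", "GGG_10"}

    def test_classification(self):
        ref = make_ref(200, 12)
        groups = [
            self._group("AAA", [(50, ref[50], "T", 1.0), (80, ref[80], "C", 1.0),
                                (120, ref[120], "G", 1.0)]),
        ]
        callset, _ = merge_and_filter(
            groups, ref, PARAMS,
            known_variants=[{"kind": "snv", "pos": 80, "alt": "C"}],
            target_variant={"kind": "snv", "pos": 50, "alt": "T"},
        )
        classes = {v.pos: v.class_ for v in callset.variants}
        assert classes == {50: "target", 80: "known", 120: "somatic"}

    def test_vaf_is_supporting_over_total(self):
        ref = make_ref(200, 12)
        groups = [self._group(f"U{i:03d}", [], n=8) for i in range(99)]
        groups.append(self._group("SPIKE", [(50, ref[50], "T", 1.0)], n=8))
        callset, _ = merge_and_filter(groups, ref, PARAMS)
        (v,) = callset.variants
        assert v.vaf == pytest.approx(1 / 100)

    def test_vcf_output_deterministic(self, tmp_path):
        ref = make_ref(200, 12)
        groups = [
            self._group("AAA", [(50, ref[50], "T", 1.0)]),
            self._group("CCC", [(50, ref[50], "T", 1.0)]),
        ]
        outs = []
        for name in ("a.vcf", "b.vcf"):
            callset, entries = merge_and_filter(groups, ref, PARAMS)
            write_vcf(entries, "amp", tmp_path / name, len(ref))
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]
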