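import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from umivar.errors import UmivarError
from umivar.stats import (
    cluster_recurrent_svs,
    expected_error_groups,
    haplotype_partition,
    min_groups_for_detection,
    somatic_load,
    substitution_spectrum,
    vaf_of_variant,
)


class TestSomaticLoad:
    def test_zero_numerator(self):
        assert somatic_load(0, 1000, 5000) == 0.0

    @pytest.mark.parametrize(
        "n_snvs,n_groups,surveyed,expected",
        [(275, 3479, 6995, 11.3), (103, 3867, 6506, 4.1)],
    )
    def test_load_per_mb(self, n_snvs, n_groups, surveyed, expected):
        assert round(somatic_load(n_snvs, n_groups, surveyed), 1) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(UmivarError):
            somatic_load(1, 0, 100)

    @given(
        st.integers(0, 10_000),
        st.integers(1, 100_000),
        st.integers(1, 100_000),
        st.integers(2, 5),
    )
    def test_linear_in_snvs_inverse_in_groups(self, n, g, s, k):
        base = somatic_load(n, g, s)
        assert somatic_load(k * n, g, s) == pytest.approx(k * base)
        assert somatic_load(n, k * g, s) == pytest.approx(base / k)


class TestDetectionPower:
    def test_certain_detection(self):
        assert min_groups_for_detection(1.0, 0.9).n_min == 1

    def test_closed_form_at_equality(self):
        # 1 - 0.5^2 = 0.75 exactly
        assert min_groups_for_detection(0.5, 0.75).n_min == 2

    def test_one_percent_allele_ninety_percent_power(self):
        result = min_groups_for_detection(0.01, 0.90)
        assert result.n_min == 230
        assert result.n_min >= 229

    def test_zero_frequency_rejected(self):
        with pytest.raises(UmivarError):
            min_groups_for_detection(0.0, 0.9)

    @given(
        st.floats(1e-5, 0.999),
        st.floats(0.01, 0.999),
    )
    def test_boundary_invariant(self, f, confidence):
        n = min_groups_for_detection(f, confidence).n_min
        assert 1 - (1 - f) ** n >= confidence
        if n > 1:
            assert 1 - (1 - f) ** (n - 1) < confidence


class TestErrorBudget:
    def test_first_copy_error_budget(self):
        # per-base rate from ~6 errors per 1e6 unique 168-bp molecules
        rate = 6e-6 / 168
        assert expected_error_groups(15_598, 168, rate) == pytest.approx(0.0936, abs=2e-4)
        assert round(expected_error_groups(15_598, 168, rate), 2) == 0.09
        assert expected_error_groups(10**6, 168, rate) == pytest.approx(6.0)

    def test_zero_groups(self):
        assert expected_error_groups(0, 168, 1e-6) == 0.0


class TestRecurrenceClusters:
    def _scattered(self, kind, n, start0, rng, spacing=200):
        out = []
        for i in range(n):
            s = start0 + i * spacing + int(rng.integers(-3, 4))
            out.append((kind, s, s + 60 + int(rng.integers(-3, 4)), f"sc{kind}{i}"))
        return out

    def test_hotspot_shares(self):
        rng = np.random.default_rng(0)
        svs = []
        for i in range(47):
            s = 1000 + int(rng.integers(-3, 4))
            svs.append(("deletion", s, s + 5494, f"a{i}"))
        for i in range(15):
            s = 1200 + int(rng.integers(-3, 4))
            svs.append(("deletion", s, s + 4715, f"b{i}"))
        svs += self._scattered("deletion", 189 - 47 - 15, 20_000, rng)
        clusters = cluster_recurrent_svs(svs, breakpoint_tol=10)
        assert clusters[0].count == 47
        assert round(100 * clusters[0].fraction, 1) == 24.9
        assert clusters[1].count == 15
        assert round(100 * clusters[1].fraction, 1) == 7.9

    def test_all_distinct_gives_singletons(self):
        rng = np.random.default_rng(1)
        svs = self._scattered("deletion", 20, 1000, rng)
        clusters = cluster_recurrent_svs(svs, breakpoint_tol=10)
        assert all(c.count == 1 for c in clusters)

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        svs = self._scattered("deletion", 30, 1000, rng) + self._scattered(
            "insertion", 10, 50_000, rng
        )
        clusters = cluster_recurrent_svs(svs, breakpoint_tol=10)
        assert sum(c.count for c in clusters) == 40
        assert all(0 < c.fraction <= 1 for c in clusters)

    def test_empty(self):
        assert cluster_recurrent_svs([], 10) == []


class TestSpectrum:
    def test_empty(self):
        table = substitution_spectrum([])
        assert table.total == 0
        assert all(v == 0 for v in table.counts.values())

    def test_counts(self):
        table = substitution_spectrum([("G", "A"), ("G", "A"), ("C", "T")])
        assert table.counts["G>A"] == 2
        assert table.counts["C>T"] == 1
        assert table.total == 3
        assert table.collapsed["C>T"] == 3

    def test_invalid_alleles_rejected(self):
        with pytest.raises(UmivarError):
            substitution_spectrum([("N", "A")])
        with pytest.raises(UmivarError):
            substitution_spectrum([("A", "A")])

    def test_transition_fraction_of_biased_draw(self):
        # Ti:Tv = 4 -> transition fraction 0.8; binomial 99% band at n=2000
        rng = np.random.default_rng(3)
        transitions = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
        transversions = [("A", "C"), ("A", "T"), ("G", "C"), ("C", "A")]
        snvs = []
        for _ in range(2000):
            pool = transitions if rng.random() < 0.8 else transversions
            snvs.append(pool[rng.integers(len(pool))])
        frac = substitution_spectrum(snvs).transition_fraction()
        assert abs(frac - 0.8) < 2.58 * np.sqrt(0.8 * 0.2 / 2000)


class TestHaplotypes:
    def test_two_haplotypes_from_three_groups(self):
        # three groups sharing one SV; SNV fingerprints {S1}, {S2}, {S2}
        parts = haplotype_partition(
            {"g1": {(100, "T")}, "g2": {(250, "A")}, "g3": {(250, "A")}}
        )
        assert sorted(len(p) for p in parts) == [1, 2]

    def test_single_group(self):
        assert haplotype_partition({"g1": {(1, "A")}}) == [["g1"]]

    def test_positions_outside_common_coverage_ignored(self):
        parts = haplotype_partition(
            {"g1": {(100, "T"), (900, "C")}, "g2": {(100, "T")}},
            coverage={"g1": (0, 1000), "g2": (0, 500)},
        )
        assert parts == [["g1", "g2"]]

    def test_empty_rejected(self):
        with pytest.raises(UmivarError):
            haplotype_partition({})

    def test_simulated_phased_haplotypes_recovered(self):
        rng = np.random.default_rng(8)
        hap_a = frozenset((int(p), "T") for p in rng.choice(5000, 5, replace=False))
        hap_b = frozenset((int(p), "G") for p in rng.choice(5000, 5, replace=False))
        truth = {}
        groups = {}
        for i in range(12):
            hap = hap_a if i % 2 == 0 else hap_b
            truth[f"g{i:02d}"] = hap
            groups[f"g{i:02d}"] = set(hap)
        parts = haplotype_partition(groups)
        assert len(parts) == 2
        for part in parts:
            assert len({truth[u] for u in part}) == 1


class TestVaf:
    @pytest.mark.parametrize(
        "support,total,expected",
        [(1, 15_598, 6.4e-5), (5, 132_341, 3.8e-5), (4, 3184, 1.26e-3)],
    )
    def test_printed_fractions(self, support, total, expected):
        vaf, _ci = vaf_of_variant(support, total)
        assert vaf == pytest.approx(expected, rel=0.02)

    def test_full_support(self):
        vaf, (lo, hi) = vaf_of_variant(10, 10)
        assert vaf == 1.0
        assert hi == pytest.approx(1.0)

    def test_wilson_interval_brackets_estimate(self):
        vaf, (lo, hi) = vaf_of_variant(3, 3000)
        assert lo < vaf < hi
        assert 0 < lo < 0.001 < hi < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(UmivarError):
            vaf_of_variant(1, 0)
        with pytest.raises(UmivarError):
            vaf_of_variant(5, 4)
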