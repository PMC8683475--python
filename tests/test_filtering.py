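"""Filtering cascade: boundary semantics, commutativity, effective length."""

import itertools

import numpy as np
import pytest
from scipy import stats

from clonemut.coverage import CoverageTrack, read_coverage, write_coverage
from clonemut.filtering import (
    CallSet,
    VariantCall,
    apply_blacklist,
    apply_quality_depth_filters,
    effective_genome_length,
    exclude_sex_chromosomes,
    read_calls,
    run_cascade,
    trim_low_af,
    write_calls,
)
from clonemut.genome import PolymorphismBlacklist, build_toy_genome


def make_call(chrom="virt1", pos=100, ref="C", alt="T", af=0.5, dpp=30, dps=30, q=30.0):
    return VariantCall(chrom, pos, ref, alt, af, dpp, dps, q)


@pytest.fixture(scope="module")
def genome():
    return build_toy_genome(1, 10_000, 2, 1_000_000, seed=1)


class TestVariantCall:
    def test_class_inferred_from_alleles(self):
        assert make_call(ref="C", alt="T").var_class == "SNV"
        assert make_call(ref="C", alt="CAT").var_class == "INS"
        assert make_call(ref="CAT", alt="C").var_class == "DEL"
        assert make_call(ref="CAT", alt="C").indel_length == -2

    def test_inconsistent_class_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            VariantCall("c", 1, "C", "CAT", 0.5, 30, 30, 30.0, var_class="SNV")

    def test_af_bounds(self):
        with pytest.raises(ValueError):
            make_call(af=1.2)


class TestCallSetIO:
    def test_round_trip(self, genome, tmp_path):
        rng = np.random.default_rng(2)
        calls = [
            make_call(pos=int(p), af=int(a) / 30, q=float(q))
            for p, a, q in zip(
                rng.choice(100_000, 120, replace=False),
                rng.integers(1, 30, 120),
                rng.integers(0, 60, 120),
            )
        ]
        cs = CallSet(calls)
        path = tmp_path / "calls.vcf"
        write_calls(cs, str(path), genome)
        assert read_calls(str(path)) == cs

    def test_empty_file_with_header(self, genome, tmp_path):
        path = tmp_path / "empty.vcf"
        write_calls(CallSet([]), str(path), genome)
        assert len(read_calls(str(path))) == 0

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CallSet([make_call(), make_call()])

    def test_missing_required_info_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=c1>\n"
            '##INFO=<ID=DPS,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t5\t.\tC\tT\t30\t.\tDPS=30\n"
        )
        with pytest.raises(ValueError, match="missing INFO"):
            read_calls(str(path))


class TestDepthQuality:
    def test_low_depth_in_either_sample_removed(self):
        cs = CallSet([make_call(pos=1, dpp=9, dps=30)])
        out, rep = apply_quality_depth_filters(cs, min_depth=10)
        assert len(out) == 0
        assert rep.stages[0].n_in == 1 and rep.stages[0].n_out == 0

    def test_quality_threshold_is_inclusive(self):
        cs = CallSet([make_call(pos=1, q=19.0), make_call(pos=2, q=18.9)])
        out, _ = apply_quality_depth_filters(cs, snv_quality_threshold=19.0)
        assert [c.pos for c in out] == [1]

    def test_indel_threshold_differs(self):
        cs = CallSet([make_call(pos=1, ref="C", alt="CA", q=14.0),
                      make_call(pos=2, q=14.0)])
        out, _ = apply_quality_depth_filters(cs)
        assert [c.var_class for c in out] == ["INS"]

    def test_three_call_depth_example(self):
        cs = CallSet(
            [
                make_call(pos=1, dpp=9, dps=30),
                make_call(pos=2, dpp=15, dps=12),
                make_call(pos=3, dpp=40, dps=3),
            ]
        )
        out, _ = apply_quality_depth_filters(cs)
        assert [c.pos for c in out] == [2]


class TestBlacklist:
    def test_allele_aware_matching(self):
        bl = PolymorphismBlacklist({("virt1", 100, "C", "T")})
        same = CallSet([make_call(alt="T")])
        different = CallSet([make_call(alt="G", ref="C")])
        assert len(apply_blacklist(same, bl)[0]) == 0
        assert len(apply_blacklist(different, bl)[0]) == 1

    def test_empty_blacklist_is_identity(self):
        cs = CallSet([make_call()])
        out, _ = apply_blacklist(cs, PolymorphismBlacklist())
        assert out == cs


class TestSexChromosomes:
    def test_mixed_input(self, genome):
        calls = [make_call(pos=p) for p in range(1, 8)]
        calls += [make_call(chrom="chrX", pos=p) for p in range(1, 4)]
        out, _ = exclude_sex_chromosomes(CallSet(calls), genome)
        assert len(out) == 7
        assert all(c.chrom == "virt1" for c in out)

    def test_unknown_chromosome_is_error(self, genome):
        with pytest.raises(ValueError, match="unknown"):
            exclude_sex_chromosomes(CallSet([make_call(chrom="chr99")]), genome)


class TestAfTrim:
    def test_boundary_inclusive(self):
        cs = CallSet([make_call(pos=1, af=0.29), make_call(pos=2, af=0.30)])
        out, rep = trim_low_af(cs, 0.3)
        assert [c.pos for c in out] == [2]
        assert rep.stages[0].n_in - rep.stages[0].n_out == 1

    def test_stricter_tau_removes_more(self):
        cs = CallSet([make_call(pos=1, af=0.35)])
        assert len(trim_low_af(cs, 0.3)[0]) == 1
        assert len(trim_low_af(cs, 0.4)[0]) == 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            trim_low_af(CallSet([]), 1.5)


class TestCascadeProperties:
    @pytest.fixture()
    def inputs(self, genome):
        rng = np.random.default_rng(3)
        calls = []
        for i, pos in enumerate(rng.choice(1_000_000, 300, replace=False)):
            calls.append(
                VariantCall(
                    "virt1" if i % 3 else "chrX",
                    int(pos) + 1,
                    "C",
                    "T",
                    af=float(rng.uniform(0, 1)),
                    dp_parent=int(rng.poisson(15)),
                    dp_sub=int(rng.poisson(15)),
                    quality=float(rng.integers(0, 40)),
                )
            )
        bl = PolymorphismBlacklist(
            {(c.chrom, c.pos, c.ref, c.alt) for c in calls[:40]}
        )
        return CallSet(calls), bl

    def test_stage_order_commutes(self, genome, inputs):
        calls, bl = inputs
        stages = {
            "dq": lambda cs: apply_quality_depth_filters(cs)[0],
            "bl": lambda cs: apply_blacklist(cs, bl)[0],
            "sex": lambda cs: exclude_sex_chromosomes(cs, genome)[0],
            "af": lambda cs: trim_low_af(cs, 0.3)[0],
        }
        results = set()
        for order in itertools.permutations(stages):
            out = calls
            for name in order:
                out = stages[name](out)
            results.add(frozenset(out.keys()))
        assert len(results) == 1

    def test_each_filter_idempotent(self, genome, inputs):
        calls, bl = inputs
        for fn in (
            lambda cs: apply_quality_depth_filters(cs)[0],
            lambda cs: apply_blacklist(cs, bl)[0],
            lambda cs: exclude_sex_chromosomes(cs, genome)[0],
            lambda cs: trim_low_af(cs, 0.3)[0],
        ):
            once = fn(calls)
            assert fn(once) == once

    def test_report_counts_non_increasing(self, genome, inputs):
        calls, bl = inputs
        _, rep = run_cascade(calls, genome, bl, 0.3)
        counts = [s.n_in for s in rep.stages] + [rep.stages[-1].n_out]
        assert counts == sorted(counts, reverse=True)


class TestEffectiveGenomeLength:
    def _track(self, depths_by_chrom, bin_size, lengths):
        return CoverageTrack(
            {c: np.asarray(d, dtype=float) for c, d in depths_by_chrom.items()},
            bin_size,
            lengths,
        )

    def test_uniform_coverage_gives_total_length(self):
        t = self._track({"a": [30] * 10}, 100, {"a": 1000})
        assert effective_genome_length(t, t, 10) == 1000

    def test_half_genome_low_in_one_sample(self):
        lengths = {"a": 1000}
        p = self._track({"a": [30] * 10}, 100, lengths)
        s = self._track({"a": [5] * 5 + [30] * 5}, 100, lengths)
        assert effective_genome_length(p, s, 10) == 500

    def test_poisson_depth_retention_matches_cdf_oracle(self):
        rng = np.random.default_rng(4)
        n = 200_000
        lengths = {"a": n}
        p = self._track({"a": rng.poisson(30, n)}, 1, lengths)
        s = self._track({"a": rng.poisson(30, n)}, 1, lengths)
        expected = stats.poisson.sf(9, 30) ** 2
        got = effective_genome_length(p, s, 10) / n
        assert got == pytest.approx(expected, abs=3e-5)

    def test_mismatched_grids_error(self):
        a = self._track({"a": [30] * 10}, 100, {"a": 1000})
        b = self._track({"a": [30] * 5}, 200, {"a": 1000})
        with pytest.raises(ValueError, match="grid"):
            effective_genome_length(a, b, 10)

    def test_partial_last_bin_counted_correctly(self):
        t = self._track({"a": [30, 30, 30]}, 100, {"a": 250})
        assert effective_genome_length(t, t, 10) == 250


def test_coverage_tsv_round_trip(tmp_path, genome):
    from clonemut.coverage import simulate_coverage

    track = simulate_coverage(genome, 30, 1000, np.random.default_rng(5), sample="p")
    path = tmp_path / "cov.tsv"
    write_coverage(track, str(path))
    back = read_coverage(str(path))
    assert back.bin_size == track.bin_size
    assert back.chrom_lengths == track.chrom_lengths
    for c in track.depths:
        assert np.allclose(back.depths[c], track.depths[c], rtol=1e-5)
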