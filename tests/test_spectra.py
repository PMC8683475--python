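"""Spectra: pyrimidine collapse, 96-context consistency, INDEL statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonemut.filtering import CallSet, VariantCall
from clonemut.genome import build_toy_genome
from clonemut.simulate import (
    GS_SPECTRUM,
    ClonalDesign,
    SimulationParams,
    simulate_clonal_experiment,
)
from clonemut.spectra import test_chromosome_enrichment as enrichment_test
from clonemut.spectra import (
    CONTEXT96_LABELS,
    SIX_TYPES,
    collapse_substitution,
    context96,
    cosine_similarity,
    indel_stats,
    per_chromosome_density,
    read_signature,
    spectrum6,
    write_signature,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def snv(chrom, pos, ref, alt, ctx5="", ctx3="", real=False):
    return VariantCall(chrom, pos, ref, alt, 0.5, 30, 30, 30.0,
                       ctx5=ctx5, ctx3=ctx3, context_real=real)


class TestCollapse:
    @pytest.mark.parametrize(
        "ref,alt,c5,c3,expected",
        [
            ("G", "T", "A", "C", ("C>A", "G", "T")),  # purine: reverse complement
            ("C", "T", "T", "G", ("C>T", "T", "G")),  # CpG context preserved
            ("A", "G", "", "", ("T>C", "", "")),
            ("T", "G", "C", "A", ("T>G", "C", "A")),
        ],
    )
    def test_examples(self, ref, alt, c5, c3, expected):
        assert collapse_substitution(ref, alt, c5, c3) == expected

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            collapse_substitution("N", "T")
        with pytest.raises(ValueError):
            collapse_substitution("C", "C")

    @settings(max_examples=200, deadline=None)
    @given(
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
        c5=st.sampled_from("ACGT"),
        c3=st.sampled_from("ACGT"),
    )
    def test_strand_involution(self, ref, alt, c5, c3):
        """Collapsing a substitution and its reverse complement agree."""
        if ref == alt:
            return
        direct = collapse_substitution(ref, alt, c5, c3)
        flipped = collapse_substitution(
            _COMP[ref], _COMP[alt], _COMP[c3], _COMP[c5]
        )
        assert direct == flipped


class TestSpectrum6:
    def test_single_call(self):
        sp = spectrum6(CallSet([snv("c", 5, "C", "A")]))
        assert sp.counts == {"C>A": 1, "C>G": 0, "C>T": 0, "T>A": 0, "T>C": 0, "T>G": 0}
        assert sp.proportions["C>A"] == 1.0

    def test_cpg_split_partitions_ct(self):
        calls = CallSet(
            [
                snv("c", 1, "C", "T", "A", "G"),  # CpG
                snv("c", 2, "C", "T", "A", "A"),  # other
                snv("c", 3, "G", "A", "C", "T"),  # collapses to C>T, 3' of C is G -> CpG
                snv("c", 4, "C", "A", "A", "G"),
            ]
        )
        sp = spectrum6(calls)
        assert sp.counts["C>T"] == 3
        assert sp.cpg_split == {"CpG": 2, "other": 1, "unknown": 0}

    def test_strand_symmetry_of_profile(self):
        rng = np.random.default_rng(1)
        calls, flipped = [], []
        bases = "ACGT"
        for i in range(300):
            ref = bases[rng.integers(4)]
            alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
            c5, c3 = bases[rng.integers(4)], bases[rng.integers(4)]
            calls.append(snv("c", i + 1, ref, alt, c5, c3))
            flipped.append(
                snv("c", i + 1, _COMP[ref], _COMP[alt], _COMP[c3], _COMP[c5])
            )
        assert spectrum6(CallSet(calls)).counts == spectrum6(CallSet(flipped)).counts

    def test_recovers_generator_proportions(self, full_genome, full_blacklist):
        params = SimulationParams(snv_rate=1.2e-9, indel_rate=0.0,
                                  six_type_probs=GS_SPECTRUM)
        exps = simulate_clonal_experiment(
            ClonalDesign(), params, full_genome, 2, full_blacklist, seed=6
        )
        pooled = CallSet(
            [c for e in exps for c in e.calls if c.phase == "parental"]
        )
        sp = spectrum6(pooled, full_genome)
        n = sp.total
        assert n > 500
        for t in SIX_TYPES:
            se = np.sqrt(GS_SPECTRUM[t] * (1 - GS_SPECTRUM[t]) / n)
            assert sp.proportions[t] == pytest.approx(GS_SPECTRUM[t], abs=4 * se + 0.005)


@pytest.fixture(scope="module")
def ctx_calls():
    genome = build_toy_genome(2, 100_000, 0, 1, seed=7)
    params = SimulationParams(snv_rate=3e-6, indel_rate=0.0, contamination=0.0)
    design = ClonalDesign(subclone_doublings=1)
    (e,) = simulate_clonal_experiment(design, params, genome, 1, seed=8)
    return genome, CallSet([c for c in e.calls if c.var_class == "SNV"])


class TestContext96:

    def test_marginalization_matches_spectrum6(self, ctx_calls):
        genome, calls = ctx_calls
        sig = context96(calls, genome)
        sp = spectrum6(calls, genome)
        assert sig.counts.sum() > 100
        assert sig.marginal_six_type() == {
            t: float(v) for t, v in sp.counts.items()
        }

    def test_virtual_calls_excluded_with_count(self):
        calls = CallSet([snv("virt1", 5, "C", "T", "A", "A", real=False)])
        sig = context96(calls)
        assert sig.counts.sum() == 0 and sig.n_excluded == 1

    def test_tsv_round_trip(self, ctx_calls, tmp_path):
        genome, calls = ctx_calls
        sig = context96(calls, genome)
        path = tmp_path / "sig.tsv"
        write_signature(sig, str(path))
        back = read_signature(str(path))
        assert np.array_equal(back.counts, sig.counts)

    def test_label_order_is_canonical(self):
        assert CONTEXT96_LABELS[0] == "A[C>A]A"
        assert CONTEXT96_LABELS[16] == "A[C>G]A"
        assert CONTEXT96_LABELS[-1] == "T[T>G]T"


class TestCosine:
    def test_identity_orthogonal_scale(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity(v, 2 * v) == pytest.approx(1.0)

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestIndelStats:
    def test_ratio_example(self):
        calls = [VariantCall("c", p, "C", "CA", 0.5, 30, 30, 30.0) for p in range(1, 43)]
        calls += [VariantCall("c", p, "CA", "C", 0.5, 30, 30, 30.0) for p in range(100, 150)]
        st_ = indel_stats(CallSet(calls))
        assert (st_.n_insertions, st_.n_deletions) == (42, 50)
        assert st_.ins_del_ratio == pytest.approx(0.84)

    def test_single_deletion_histogram(self):
        st_ = indel_stats(CallSet([VariantCall("c", 1, "CA", "C", 0.5, 30, 30, 30.0)]))
        assert st_.length_histogram == {-1: 1}
        assert st_.ins_del_ratio == 0.0

    def test_no_deletions_ratio_undefined(self):
        st_ = indel_stats(CallSet([VariantCall("c", 1, "C", "CA", 0.5, 30, 30, 30.0)]))
        assert st_.ins_del_ratio is None

    def test_geometric_lengths_mode_at_one(self, full_genome):
        params = SimulationParams(snv_rate=0.0, indel_rate=0.5e-9,
                                  indel_length_geom_p=0.6, contamination=0.0)
        exps = simulate_clonal_experiment(
            ClonalDesign(subclone_doublings=1), params, full_genome, 3, seed=9
        )
        st_ = indel_stats(CallSet([c for e in exps for c in e.calls]))
        hist = st_.length_histogram
        assert max(hist, key=lambda k: (hist[k], -abs(k))) in (-1, 1)
        by_abs = {}
        for k, v in hist.items():
            by_abs[abs(k)] = by_abs.get(abs(k), 0) + v
        assert by_abs[1] == max(by_abs.values())


class TestChromosomeDensity:
    def test_density_definition(self, full_genome):
        calls = CallSet([snv("virt1", p, "C", "T") for p in range(1, 6)])
        dens = per_chromosome_density(calls, full_genome)
        assert dens["virt1"] == pytest.approx(5 / 110_420_000 * 1e8)
        assert dens["virt2"] == 0.0
        assert "ctx1" not in dens  # below the scaffold length cutoff
        assert "chrX" not in dens

    def test_single_subclone_refused(self, full_genome):
        d = per_chromosome_density(CallSet([]), full_genome)
        with pytest.raises(ValueError):
            enrichment_test([d])

    def test_null_calibration_and_power(self, full_genome):
        rng = np.random.default_rng(10)
        lengths = np.array([110_420_000.0] * 19)
        p_uniform = lengths / lengths.sum()
        null_rej = spike_rej = 0
        n_rep = 60
        # power for a single enriched chromosome among 19 rises with the
        # number of replicate subclones; 10 gives headroom over the 90% bar
        for _ in range(n_rep):
            dens_null, dens_spike = [], []
            for _s in range(10):
                counts = rng.multinomial(300, p_uniform)
                dens_null.append(
                    dict(zip([f"virt{i+1}" for i in range(19)], counts / lengths * 1e8))
                )
                spiked = counts.copy()
                spiked[4] += rng.poisson(9 * 300 * p_uniform[4])
                dens_spike.append(
                    dict(zip([f"virt{i+1}" for i in range(19)], spiked / lengths * 1e8))
                )
            import pandas as pd

            null_rej += (
                enrichment_test([pd.Series(d) for d in dens_null])["p_value"] < 0.05
            )
            spike_rej += (
                enrichment_test([pd.Series(d) for d in dens_spike])["p_value"] < 0.05
            )
        assert null_rej / n_rep <= 0.10   # ~5% type-I
        assert spike_rej / n_rep >= 0.90  # 10x enrichment on one chromosome
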