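"""Mutation classification, codon effects, permutation and dispersion tests."""

import numpy as np
import pytest

from organelle_ma.genomes import COMPLEMENT, AnnotationRecord, ReferenceSet
from organelle_ma.selection import (
    MUTATION_CLASSES,
    NoEligibleSiteError,
    classify_snv,
    compare_count_groups,
    dispersion_test,
    genic_fraction_summary,
    permutation_test_synonymous,
    spectrum_summary,
    synonymous_status,
)


def toy_cds_ref(seq, cds_span=None, strand="+", pad=20):
    cds_span = cds_span or (1, len(seq))
    return ReferenceSet(
        genome_id="plastid",
        sequence=seq + "C" * pad,
        annotation=[AnnotationRecord(feature="CDS", segments=[cds_span], strand=strand)],
    )


class TestClassifySnv:
    @pytest.mark.parametrize(
        "ref,alt,klass",
        [
            ("A", "G", "AT>GC"), ("T", "C", "AT>GC"),
            ("C", "T", "GC>AT"), ("G", "A", "GC>AT"),
            ("A", "C", "AT>CG"), ("T", "G", "AT>CG"),
            ("G", "T", "GC>TA"), ("C", "A", "GC>TA"),
            ("A", "T", "AT>TA"), ("T", "A", "AT>TA"),
            ("G", "C", "GC>CG"), ("C", "G", "GC>CG"),
        ],
    )
    def test_all_ordered_pairs(self, ref, alt, klass):
        assert classify_snv(ref, alt) == klass

    def test_complement_symmetry(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_snv(ref, alt) == classify_snv(
                    COMPLEMENT[ref], COMPLEMENT[alt]
                )

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_snv("A", "A")


class TestSynonymousStatus:
    def test_third_position_wobble(self):
        ref = toy_cds_ref("ATGGGATAA")
        # codon 2 third base: GGA -> GGG, Gly -> Gly
        assert synonymous_status(ref, 6, "G") == "synonymous"

    def test_first_position_change(self):
        ref = toy_cds_ref("ATGGGATAA")
        # codon 1: ATG -> GTG, Met -> Val
        assert synonymous_status(ref, 1, "G") == "nonsynonymous"

    def test_outside_cds(self):
        ref = toy_cds_ref("ATGGGATAA")
        assert synonymous_status(ref, 15, "G") == "not_CDS"

    def test_minus_strand_gene(self):
        # coding sequence is the reverse complement: genome TTACCCCAT
        # reads ATGGGGTAA on the minus strand
        ref = toy_cds_ref("TTACCCCAT", strand="-")
        # genome pos 4 (C) is codon-2 third base on the coding strand:
        # GGG -> GGA (genome C->T), Gly -> Gly
        assert synonymous_status(ref, 4, "T") == "synonymous"
        # genome pos 9 (T) is the first codon base (ATG -> GTG on coding
        # strand when genome T->C)
        assert synonymous_status(ref, 9, "C") == "nonsynonymous"

    def test_multi_segment_cds_codon_phase(self):
        # exons ATG + GGA TAA split across an intron; codon 2 spans the join
        seq = "ATGTTTTTGGATAA"
        ref = ReferenceSet(
            genome_id="plastid",
            sequence=seq + "C" * 10,
            annotation=[
                AnnotationRecord(
                    feature="CDS", segments=[(1, 3), (9, 14)], strand="+"
                ),
                AnnotationRecord(feature="intron", segments=[(4, 8)]),
            ],
        )
        # concatenated coding sequence: ATG GGA TAA; genome pos 11 is the
        # third base of codon 2 (GGA -> GGG)
        assert synonymous_status(ref, 11, "G") == "synonymous"


class TestPermutationTest:
    def test_degenerate_null_p_one(self):
        # every eligible AT>GC site in GGx codons is 4-fold degenerate
        ref = toy_cds_ref("GGAGGTGGA")
        res = permutation_test_synonymous(ref, {"AT>GC": 2}, 2, n_perm=500, seed=0)
        assert res.p_value == 1.0

    def test_observed_zero_p_one(self):
        ref = toy_cds_ref("GGAGAT")
        res = permutation_test_synonymous(ref, {"AT>GC": 2}, 0, n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_exact_enumeration_oracle(self):
        # GGAGAT: eligible AT>GC sites are pos 3 (syn), 5 (nonsyn), 6 (syn)
        ref = toy_cds_ref("GGAGAT")
        n_perm = 10_000
        res = permutation_test_synonymous(ref, {"AT>GC": 1}, 1, n_perm=n_perm, seed=3)
        exact = 2.0 / 3.0
        mc_se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_value - exact) < 3 * mc_se

    def test_missing_eligible_sites_error(self):
        ref = toy_cds_ref("GGCGGCGGC")  # no A/T pair in the CDS
        with pytest.raises(NoEligibleSiteError, match="AT>GC"):
            permutation_test_synonymous(ref, {"AT>GC": 1}, 0, n_perm=10, seed=0)

    def test_super_uniform_under_self_generated_null(self):
        from organelle_ma.selection import _class_site_tables

        ref = toy_cds_ref("GGAGAT")
        positions, syn = _class_site_tables(ref)["AT>GC"]
        rng = np.random.default_rng(11)
        reps, n_perm, count = 400, 1000, 3
        pvals = []
        for _ in range(reps):
            observed = int(syn[rng.integers(0, len(positions), size=count)].sum())
            res = permutation_test_synonymous(
                ref, {"AT>GC": count}, observed, n_perm=n_perm, rng=rng
            )
            pvals.append(res.p_value)
        pvals = np.asarray(pvals)
        for q in (0.05, 0.1, 0.5):
            mc = 3 * np.sqrt(q * (1 - q) / reps) + 1.0 / n_perm
            assert (pvals <= q).mean() <= q + mc

    def test_seed_reproducibility(self):
        ref = toy_cds_ref("GGAGAT")
        a = permutation_test_synonymous(ref, {"AT>GC": 2}, 1, n_perm=2000, seed=7)
        b = permutation_test_synonymous(ref, {"AT>GC": 2}, 1, n_perm=2000, seed=7)
        assert a.p_value == b.p_value

    def test_monte_carlo_error_halves_with_4x_permutations(self):
        ref = toy_cds_ref("GGAGATGATTTA")
        spread = {}
        for n_perm in (250, 1000):
            ps = [
                permutation_test_synonymous(
                    ref, {"AT>GC": 2}, 2, n_perm=n_perm, seed=s
                ).p_value
                for s in range(60)
            ]
            spread[n_perm] = np.std(ps, ddof=1)
        ratio = spread[250] / spread[1000]
        assert 1.4 < ratio < 2.9  # theoretical factor 2


class TestDispersionTest:
    def test_equal_counts_underdispersed(self):
        res = dispersion_test([4, 4, 4, 4, 4, 4])
        assert res.statistic < 0
        assert res.p_value > 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dispersion_test([0, 0, 0])

    def test_agrees_with_brute_force_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.poisson(rng.uniform(1, 10), size=int(rng.integers(5, 40)))
            if y.sum() == 0:
                continue
            res = dispersion_test(y)
            ybar = y.mean()
            z = sum((yi - ybar) ** 2 - yi for yi in y) / (
                ybar * np.sqrt(2 * len(y))
            )
            assert res.statistic == pytest.approx(z)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            y = rng.poisson(5, size=22)
            rejections += dispersion_test(y).p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_overdispersion(self):
        rng = np.random.default_rng(19)
        # negative binomial with variance 3x mean: mean 5, r = 2.5
        r, mean = 2.5, 5.0
        rejections = 0
        reps = 1000
        for _ in range(reps):
            y = rng.negative_binomial(r, r / (r + mean), size=22)
            rejections += dispersion_test(y).p_value < 0.05
        assert rejections / reps > 0.5


class TestSummaries:
    def _variant(self, pos, ref, alt, freq=1.0, klass="SNV"):
        from organelle_ma.calling import Variant

        v = Variant(
            line_id="M1_1", genome_id="plastid", pos=pos, ref=ref, alt=alt,
            klass=klass, depth=100, alt_count=50, ref_count=50,
            raw_frequency=freq,
        )
        v.corrected_frequency = freq
        return v

    def test_genic_fraction_counts(self):
        ref = toy_cds_ref("ATGGGATAA", pad=30)
        vs = [
            self._variant(6, "A", "G"),    # CDS, synonymous
            self._variant(1, "A", "G"),    # CDS, nonsynonymous
            self._variant(20, "C", "T"),   # intergenic
        ]
        out = genic_fraction_summary(vs, ref)
        assert out["counts"]["CDS"] == 2
        assert out["counts"]["intergenic"] == 1
        assert out["synonymous_CDS"] == 1
        assert out["genic_fraction"] == pytest.approx(2 / 3)

    def test_empty_summary(self):
        ref = toy_cds_ref("ATGGGATAA")
        out = genic_fraction_summary([], ref)
        assert out["total"] == 0

    def test_spectrum_counts(self):
        vs = [
            self._variant(1, "A", "G"),
            self._variant(2, "T", "C"),
            self._variant(3, "G", "T", freq=0.5),
        ]
        out = spectrum_summary(vs)
        assert out["counts"]["AT>GC"] == 2
        assert out["counts"]["GC>TA"] == 1
        assert out["transition_fraction"] == pytest.approx(2 / 3)
        assert out["gc_gaining_weight"] == pytest.approx(2.0)
        assert out["gc_losing_weight"] == pytest.approx(0.5)

    def test_spectrum_empty(self):
        out = spectrum_summary([])
        assert out["total"] == 0
        assert all(v == 0 for v in out["counts"].values())

    def test_count_group_comparison_detects_difference(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(7.0, 22)
        b = rng.poisson(3.4, 20)
        for method in ("poisson", "t", "mannwhitney"):
            out = compare_count_groups(a, b, method=method)
            assert out["p_value"] < 0.05
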