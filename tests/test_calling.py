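"""Filtering-cascade behaviour: thresholds, background rule, exclusions,
numt correction, MNV merging, zygosity labels."""

import numpy as np
import pytest

from organelle_ma import simulate
from organelle_ma.calling import (
    BackgroundProfile,
    EmptyWTSetError,
    Variant,
    call_candidates,
    call_pipeline,
    compute_background,
    correct_numt_frequency,
    estimate_nuclear_coverage,
    exclude_repeat_copies,
    exclude_structural_artifacts,
    label_zygosity,
    merge_mnv,
)
from organelle_ma.genomes import reverse_complement

from conftest import make_table


def empty_background(table):
    return BackgroundProfile(
        genome_id=table.genome_id,
        pos=table.pos.copy(),
        base_freq=np.zeros_like(table.base_counts, dtype=float),
        indel_freq={},
        n_wt=1,
    )


def snv(pos=100, ref="A", alt="G", genome="mitochondrial", depth=100,
        alt_count=40, ref_count=60, raw=0.40, line="M1_1", klass="SNV"):
    return Variant(
        line_id=line, genome_id=genome, pos=pos, ref=ref, alt=alt,
        klass=klass, depth=depth, alt_count=alt_count, ref_count=ref_count,
        raw_frequency=raw,
    )


class TestBackground:
    def test_requires_wt_lines(self):
        with pytest.raises(EmptyWTSetError):
            compute_background([])

    def test_zero_counts_zero_background(self, toy_refs):
        tables = [make_table(toy_refs["plastid"], line_id=f"W{i}") for i in range(3)]
        bg = compute_background(tables)
        assert bg.base_freq.sum() == 0.0
        assert bg.indel_freq == {}

    def test_mean_of_per_line_frequencies(self, toy_refs):
        ref = toy_refs["plastid"]
        pos = int(ref.included_positions[10])
        alt = "G" if ref.base_at(pos) != "G" else "C"
        tables = [
            make_table(ref, line_id=f"W{i}", depth=100,
                       alt_counts={(pos, alt): c})
            for i, c in enumerate((10, 20, 30))
        ]
        bg = compute_background(tables)
        assert bg.base_background(pos, alt) == pytest.approx(0.2)

    def test_brute_force_recomputation(self, toy_refs, toy_lines):
        cfg = simulate.SimulationConfig(seed=6, mean_depth=120)
        truth, tables, _ = simulate.simulate_experiment(
            toy_refs, toy_lines, cfg, np.random.default_rng(6)
        )
        wt = [tables[(l.line_id, "plastid")] for l in toy_lines if l.genotype == "WT"]
        bg = compute_background(wt)
        ref_idx = wt[0].ref_index
        rng = np.random.default_rng(0)
        rows = rng.integers(0, len(wt[0].pos), size=50)
        for row in rows:
            for j, base in enumerate("ACGT"):
                if j == ref_idx[row]:
                    continue
                expected = np.mean(
                    [
                        t.base_counts[row, j] / t.depth[row] if t.depth[row] else 0.0
                        for t in wt
                    ]
                )
                assert bg.base_freq[row, j] == pytest.approx(expected)


class TestCandidateGates:
    @pytest.mark.parametrize(
        "depth,alt_count,expect_call",
        [
            (49, 45, False),   # depth gate
            (100, 19, False),  # frequency gate: 0.19 < 0.20
            (100, 20, True),   # at the threshold
        ],
    )
    def test_frequency_and_depth_gates(self, toy_refs, depth, alt_count, expect_call):
        ref = toy_refs["plastid"]
        pos = int(ref.included_positions[5])
        alt = "A" if ref.base_at(pos) != "A" else "T"
        table = make_table(ref, depth=depth, alt_counts={(pos, alt): alt_count})
        calls = call_candidates(table, empty_background(table))
        assert bool(calls) is expect_call

    def test_background_fold_rule(self, toy_refs):
        ref = toy_refs["plastid"]
        pos = int(ref.included_positions[7])
        alt = "A" if ref.base_at(pos) != "A" else "T"
        table = make_table(ref, depth=100, alt_counts={(pos, alt): 25})
        bg = empty_background(table)
        row = int(np.searchsorted(bg.pos, pos))
        bg.base_freq[row, "ACGT".index(alt)] = 0.10
        assert call_candidates(table, bg) == []  # 0.25 < 3 x 0.10
        table31 = make_table(ref, depth=100, alt_counts={(pos, alt): 31})
        assert len(call_candidates(table31, bg)) == 1

    def test_multiple_alt_alleles_each_reported(self, toy_refs):
        ref = toy_refs["plastid"]
        pos = int(ref.included_positions[3])
        others = [b for b in "ACGT" if b != ref.base_at(pos)][:2]
        table = make_table(
            ref, depth=100,
            alt_counts={(pos, others[0]): 30, (pos, others[1]): 25},
        )
        calls = call_candidates(table, empty_background(table))
        assert sorted(v.alt for v in calls) == sorted(others)

    def test_indel_gates(self, toy_refs):
        ref = toy_refs["plastid"]
        pos = int(ref.included_positions[9])
        table = make_table(ref, depth=100, indels={pos: {"del:1": 25, "ins:A": 10}})
        calls = call_candidates(table, empty_background(table))
        assert [(v.klass, v.alt) for v in calls] == [("deletion", "del:1")]

    def test_monotone_in_thresholds(self, toy_refs):
        ref = toy_refs["plastid"]
        rng = np.random.default_rng(12)
        alt_counts = {}
        for _ in range(40):
            pos = int(rng.choice(ref.included_positions))
            base = "ACGT"[rng.integers(4)]
            if base != ref.base_at(pos):
                alt_counts[(pos, base)] = int(rng.integers(0, 80))
        table = make_table(ref, depth=80, alt_counts=alt_counts)
        bg = empty_background(table)
        loose = {(v.pos, v.alt) for v in call_candidates(table, bg, 0.10, 30, 1.0)}
        for kwargs in ({"min_freq": 0.3}, {"min_depth": 90}, {"bg_fold": 3.0}):
            strict = {
                (v.pos, v.alt)
                for v in call_candidates(
                    table, bg,
                    kwargs.get("min_freq", 0.10),
                    kwargs.get("min_depth", 30),
                    kwargs.get("bg_fold", 1.0),
                )
            }
            assert strict <= loose

    def test_lowering_threshold_only_adds_low_frequency_calls(self, toy_refs):
        ref = toy_refs["plastid"]
        rng = np.random.default_rng(13)
        alt_counts = {}
        for _ in range(30):
            pos = int(rng.choice(ref.included_positions))
            base = "ACGT"[rng.integers(4)]
            if base != ref.base_at(pos):
                alt_counts[(pos, base)] = int(rng.integers(5, 60))
        table = make_table(ref, depth=100, alt_counts=alt_counts)
        bg = empty_background(table)
        at20 = {(v.pos, v.alt) for v in call_candidates(table, bg, 0.20)}
        at10 = call_candidates(table, bg, 0.10)
        extra = [v for v in at10 if (v.pos, v.alt) not in at20]
        assert all(0.10 <= v.raw_frequency < 0.20 for v in extra)


class TestExclusions:
    def test_repeat_interval_membership(self, toy_refs):
        ref = toy_refs["plastid"]
        start, end = ref.excluded_repeats[0]
        inside = snv(pos=start, genome="plastid")
        boundary = snv(pos=start - 1, genome="plastid")
        kept = exclude_repeat_copies([inside, boundary], ref)
        assert kept == [boundary]

    def test_artefact_context_match(self, toy_refs):
        ref = toy_refs["plastid"]
        pos = 500
        v = snv(pos=pos, ref=ref.base_at(pos), alt="A" if ref.base_at(pos) != "A" else "C",
                genome="plastid")
        k = 20
        context = (
            ref.sequence[pos - 1 - k : pos - 1] + v.alt + ref.sequence[pos : pos + k]
        )
        junk = "GATC" * 10
        artefact = junk + context + junk
        assert exclude_structural_artifacts([v], [artefact], ref, k=k) == []
        # reverse-complement of the artefact also matches
        assert exclude_structural_artifacts(
            [v], [reverse_complement(artefact)], ref, k=k
        ) == []
        assert exclude_structural_artifacts([v], [], ref, k=k) == [v]
        assert exclude_structural_artifacts([v], [junk * 3], ref, k=k) == [v]

    def test_planted_artefacts_removed_true_variants_kept(self, toy_refs):
        ref = toy_refs["plastid"]
        rng = np.random.default_rng(3)
        k = 20
        positions = rng.choice(ref.included_positions[100:-100], size=10, replace=False)
        variants, artefacts = [], []
        for i, pos in enumerate(sorted(int(p) for p in positions)):
            alt = "A" if ref.base_at(pos) != "A" else "G"
            v = snv(pos=pos, ref=ref.base_at(pos), alt=alt, genome="plastid")
            variants.append(v)
            if i < 5:
                ctx = (
                    ref.sequence[pos - 1 - k : pos - 1]
                    + alt + ref.sequence[pos : pos + k]
                )
                artefacts.append("TTTT" + ctx + "AAAA")
        kept = exclude_structural_artifacts(variants, artefacts, ref, k=k)
        assert kept == variants[5:]


class TestNuclearCoverage:
    def test_arithmetic(self):
        assert estimate_nuclear_coverage(300e6, 300e6, 150_000_000) == 0.0
        assert estimate_nuclear_coverage(300e6, 150e6, 150_000_000) == 1.0
        with pytest.raises(ValueError):
            estimate_nuclear_coverage(100, 200, 1000)
        with pytest.raises(ValueError):
            estimate_nuclear_coverage(100, 50, 0)


class TestNumtCorrection:
    def test_worked_example(self):
        v = snv(alt_count=40, ref_count=60, depth=100, raw=0.40)
        out = correct_numt_frequency(v, nuclear_coverage=20.0, numt_copies=1)
        assert out.corrected_frequency == pytest.approx(0.50)

    def test_clamping(self):
        v = snv(alt_count=80, ref_count=20, depth=100, raw=0.80)
        out = correct_numt_frequency(v, nuclear_coverage=30.0, numt_copies=1)
        # only the 20 reference reads can be removed: 80 / 80 = 1.0
        assert out.corrected_frequency == pytest.approx(1.0)

    def test_zero_copies_pass_through(self):
        v = snv(alt_count=40, ref_count=60, depth=100, raw=0.40)
        out = correct_numt_frequency(v, nuclear_coverage=20.0, numt_copies=0)
        assert out.corrected_frequency == v.raw_frequency

    def test_plastid_pass_through(self):
        v = snv(genome="plastid", alt_count=40, ref_count=60, depth=100, raw=0.40)
        out = correct_numt_frequency(v, nuclear_coverage=20.0, numt_copies=3)
        assert out.corrected_frequency == v.raw_frequency

    def test_never_lowers_and_never_exceeds_one(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            depth = int(rng.integers(50, 500))
            alt = int(rng.integers(1, depth))
            v = snv(alt_count=alt, ref_count=depth - alt, depth=depth,
                    raw=alt / depth)
            out = correct_numt_frequency(
                v, float(rng.uniform(0, 50)), int(rng.integers(0, 4))
            )
            assert v.raw_frequency <= out.corrected_frequency <= 1.0

    def test_uncorrectable_flag(self):
        v = snv(alt_count=0, ref_count=100, depth=100, raw=0.0)
        out = correct_numt_frequency(v, nuclear_coverage=200.0, numt_copies=1)
        assert out.uncorrectable


class TestMnvMerge:
    def test_adjacent_same_line_merged(self):
        a = snv(pos=10, ref="A", alt="G", raw=0.5)
        b = snv(pos=11, ref="T", alt="C", raw=0.7)
        merged = merge_mnv([a, b])
        assert len(merged) == 1
        mnv = merged[0]
        assert (mnv.klass, mnv.pos, mnv.ref, mnv.alt) == ("MNV", 10, "AT", "GC")
        assert mnv.raw_frequency == pytest.approx(0.6)

    def test_different_lines_not_merged(self):
        a = snv(pos=10, line="M1_1")
        b = snv(pos=11, line="M2_1")
        assert {v.klass for v in merge_mnv([a, b])} == {"SNV"}

    def test_non_adjacent_not_merged(self):
        a = snv(pos=10)
        b = snv(pos=12)
        assert {v.klass for v in merge_mnv([a, b])} == {"SNV"}

    def test_insertion_plus_snv_replacement(self):
        a = snv(pos=10, ref="A", alt="G", raw=0.4)
        ins = snv(pos=10, ref="A", alt="ins:C", raw=0.6, klass="insertion")
        merged = merge_mnv([a, ins])
        assert len(merged) == 1
        assert merged[0].klass == "MNV"
        assert merged[0].alt == "GC"  # one base pair replaced by a dinucleotide


class TestZygosity:
    @pytest.mark.parametrize(
        "genome,freq,label",
        [
            ("plastid", 0.98, "homoplasmic_candidate"),
            ("plastid", 0.979, "heteroplasmic"),
            ("mitochondrial", 0.90, "heteroplasmic"),   # strict >
            ("mitochondrial", 0.901, "homoplasmic_candidate"),
            ("plastid", 0.50, "heteroplasmic"),
        ],
    )
    def test_thresholds(self, genome, freq, label):
        v = snv(genome=genome, raw=freq)
        v.corrected_frequency = freq
        assert label_zygosity(v).zygosity_label == label


class TestPipeline:
    def test_wt_only_fixture_empty_and_deterministic(self, toy_refs):
        lines = simulate.default_lines(n_mutant=0, n_wt=6)
        cfg = simulate.SimulationConfig(seed=2)
        results = []
        for _ in range(2):
            truth, tables, stats = simulate.simulate_experiment(
                toy_refs, lines, cfg, np.random.default_rng(cfg.seed)
            )
            bg = {
                g: compute_background(
                    [tables[(l.line_id, g)] for l in lines]
                )
                for g in toy_refs
            }
            cov = {
                lid: estimate_nuclear_coverage(
                    s["total_read_bases"], s["organelle_mapped_bases"],
                    int(s["nuclear_genome_size"]),
                )
                for lid, s in stats.items()
            }
            calls = call_pipeline(
                list(tables.values()), bg, toy_refs, nuclear_coverage=cov
            )
            results.append(calls)
            assert truth.mutations == []
        assert results[0] == [] and results[1] == []

    def test_recovers_planted_set(self, toy_refs, toy_lines):
        from organelle_ma.evaluate import score_calls

        cfg = simulate.SimulationConfig(seed=21)
        truth, tables, stats = simulate.simulate_experiment(
            toy_refs, toy_lines, cfg, np.random.default_rng(21)
        )
        bg = {
            g: compute_background(
                [tables[(l.line_id, g)] for l in toy_lines if l.genotype == "WT"]
            )
            for g in toy_refs
        }
        cov = {
            lid: estimate_nuclear_coverage(
                s["total_read_bases"], s["organelle_mapped_bases"],
                int(s["nuclear_genome_size"]),
            )
            for lid, s in stats.items()
        }
        calls = call_pipeline(
            list(tables.values()), bg, toy_refs, nuclear_coverage=cov
        )
        report = score_calls(truth, calls, min_truth_frequency=0.25)
        assert report.missed == []
        assert report.false_positives == []
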