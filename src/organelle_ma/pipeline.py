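"""End-to-end orchestration: simulate -> call -> rates -> tests -> indels.

A ``RunConfig`` pins every input, threshold, and seed; ``run_all``
executes the stages, persists every intermediate as TSV/JSON under the
output directory, and returns (and writes) a machine-readable summary.
All randomness flows from the one root seed through per-stage spawned
streams, so stages are independently reproducible.  Logs go to stderr
and a run log file, never to the data outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .calling import (
    BackgroundProfile,
    CallParams,
    SiteCountTable,
    Variant,
    call_pipeline,
    compute_background,
    estimate_nuclear_coverage,
)
from .genomes import ReferenceSet, reduced_length
from .indels import indel_bias_summary, homopolymer_genome_profile
from .rates import (
    format_rate,
    indel_rate,
    snv_rate,
    spectrum_rates,
    total_generations,
    wt_upper_bound,
)
from .selection import (
    classify_snv,
    dispersion_test,
    genic_fraction_summary,
    permutation_test_synonymous,
    spectrum_summary,
    synonymous_status,
)
from .simulate import (
    LineMeta,
    SimulationConfig,
    default_lines,
    default_references,
    simulate_experiment,
    write_fixture,
)

logger = logging.getLogger("organelle_ma")


@dataclass
class RunConfig:
    """A fully serialisable pipeline run description."""

    outdir: str = "results/run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    call: CallParams = field(default_factory=CallParams)
    mito_length: int = 50_000
    plastid_length: int = 20_000
    n_mutant: int = 22
    n_wt: int = 20
    n_perm: int = 10_000
    write_fixture_files: bool = False

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class HeatmapMatrix:
    """Background-normalised variant-frequency matrix.

    Rows are distinct (genome, pos, alt) with at least one passing call,
    columns are lines; values are max(frequency − WT mean background, 0).
    """

    rows: list[tuple[str, int, str]]
    lines: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.rows, names=["genome", "pos", "alt"])
        return pd.DataFrame(self.values, index=index, columns=self.lines)


def build_heatmap(
    variants: list[Variant],
    backgrounds: dict[str, BackgroundProfile],
    line_ids: list[str],
) -> HeatmapMatrix:
    """One row per called (genome, pos, alt); per-line normalised value
    max(raw frequency − WT background mean, 0), zero where not called."""
    keys = sorted({(v.genome_id, v.pos, v.alt) for v in variants})
    key_index = {k: i for i, k in enumerate(keys)}
    line_index = {l: j for j, l in enumerate(line_ids)}
    values = np.zeros((len(keys), len(line_ids)))
    for v in variants:
        i = key_index[(v.genome_id, v.pos, v.alt)]
        j = line_index.get(v.line_id)
        if j is None:
            continue
        values[i, j] = max(v.raw_frequency - v.wt_background_mean, 0.0)
    return HeatmapMatrix(rows=keys, lines=list(line_ids), values=values)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    filelog = logging.FileHandler(outdir / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, filelog):
        h.setFormatter(fmt)
        logger.addHandler(h)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dictionary that is
    also written to ``summary.json``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    root = np.random.SeedSequence(config.seed)
    ref_seed, sim_seed, test_seed = root.spawn(3)
    logger.info(
        "run: seed=%d thresholds min_freq=%.2f min_depth=%d bg_fold=%.1f",
        config.seed, config.call.min_freq, config.call.min_depth,
        config.call.bg_fold,
    )

    # --- simulate ---------------------------------------------------------
    refs = default_references(
        np.random.default_rng(ref_seed),
        mito_length=config.mito_length,
        plastid_length=config.plastid_length,
    )
    lines = default_lines(n_mutant=config.n_mutant, n_wt=config.n_wt)
    truth, tables, read_stats = simulate_experiment(
        refs, lines, config.sim, np.random.default_rng(sim_seed)
    )
    if config.write_fixture_files:
        write_fixture(
            outdir / "fixture", refs, lines, truth, tables, read_stats, config.sim
        )
    logger.info("simulated %d planted mutations", len(truth.mutations))

    # --- call -------------------------------------------------------------
    wt_ids = [ln.line_id for ln in lines if ln.genotype == "WT"]
    backgrounds = {
        gid: compute_background(
            [tables[(lid, gid)] for lid in wt_ids]
        )
        for gid in refs
    }
    coverage = {
        lid: estimate_nuclear_coverage(
            st["total_read_bases"], st["organelle_mapped_bases"],
            int(st["nuclear_genome_size"]),
        )
        for lid, st in read_stats.items()
    }
    variants = call_pipeline(
        list(tables.values()), backgrounds, refs,
        nuclear_coverage=coverage, params=config.call,
    )
    oio.write_variants_tsv(outdir / "variants.tsv", variants)
    oio.write_variants_vcf(outdir / "variants.vcf", variants)
    wt_calls = [v for v in variants if v.line_id in wt_ids]
    logger.info("called %d variants (%d in WT lines)", len(variants), len(wt_calls))

    # --- rates ------------------------------------------------------------
    mutant_lines = [ln for ln in lines if ln.genotype == "msh1"]
    N = total_generations(mutant_lines)
    rate_report = {}
    for gid, ref in refs.items():
        G = reduced_length(ref)
        snvs = [v for v in variants if v.genome_id == gid and v.line_id not in wt_ids]
        est = snv_rate([v for v in snvs if v.klass in ("SNV", "MNV")], G, N)
        n_indels = sum(1 for v in snvs if v.klass in ("insertion", "deletion"))
        ind = indel_rate(n_indels, G, N, genome_id=gid)
        bound = wt_upper_bound(G, N, genome_id=gid)
        rate_report[gid] = {
            "G": G, "N": N,
            "snv_weighted_V": est.V, "snv_mu": est.mu,
            "snv_mu_str": format_rate(est.mu),
            "indel_count": n_indels, "indel_mu": ind.mu,
            "indel_mu_str": format_rate(ind.mu),
            "wt_upper_bound_mu": bound.mu,
            "spectrum_class_mu": spectrum_rates(
                [v for v in snvs if v.klass == "SNV"], ref, N
            ),
        }
    with open(outdir / "rates.json", "w") as fh:
        json.dump(rate_report, fh, indent=2)

    # --- tests ------------------------------------------------------------
    rng_tests = np.random.default_rng(test_seed)
    mutant_ids = [ln.line_id for ln in mutant_lines]
    per_line_counts = [
        sum(
            1 for v in variants
            if v.line_id == lid and v.klass in ("SNV", "MNV")
        )
        for lid in mutant_ids
    ]
    test_report: dict = {"per_line_snv_counts": per_line_counts}
    if any(per_line_counts):
        disp = dispersion_test(per_line_counts)
        test_report["dispersion"] = {
            "statistic": disp.statistic, "p_value": disp.p_value,
            "mean": disp.mean, "variance": disp.variance,
        }
    observed_by_class: dict[str, dict[str, int]] = {}
    observed_syn = 0
    for gid, ref in refs.items():
        class_counts: dict[str, int] = {}
        for v in variants:
            if v.genome_id != gid or v.klass != "SNV" or v.line_id in wt_ids:
                continue
            status = synonymous_status(ref, v.pos, v.alt)
            if status == "not_CDS":
                continue
            klass = classify_snv(v.ref, v.alt)
            class_counts[klass] = class_counts.get(klass, 0) + 1
            if status == "synonymous":
                observed_syn += 1
        if class_counts:
            observed_by_class[gid] = class_counts
    if observed_by_class:
        perm = permutation_test_synonymous(
            refs, observed_by_class, observed_syn,
            n_perm=config.n_perm, rng=rng_tests,
        )
        test_report["synonymous_permutation"] = {
            "observed_synonymous": observed_syn,
            "n_perm": perm.n_perm, "p_value": perm.p_value,
            "null_mean": perm.null_mean, "null_sd": perm.null_sd,
        }
    for gid, ref in refs.items():
        summary = genic_fraction_summary(
            [v for v in variants if v.genome_id == gid and v.line_id not in wt_ids],
            ref,
        )
        test_report[f"genic_{gid}"] = summary
    test_report["spectrum"] = {
        gid: spectrum_summary(
            [v for v in variants if v.genome_id == gid and v.line_id not in wt_ids]
        )
        for gid in refs
    }
    with open(outdir / "tests.json", "w") as fh:
        json.dump(test_report, fh, indent=2)

    # --- indel contexts ---------------------------------------------------
    mutant_indels = [
        v for v in variants
        if v.klass in ("insertion", "deletion") and v.line_id not in wt_ids
    ]
    indel_summary = indel_bias_summary(mutant_indels, refs)
    indel_summary.to_frame().to_csv(outdir / "indel_contexts.tsv", sep="\t", index=False)
    hp_profiles = {gid: homopolymer_genome_profile(ref) for gid, ref in refs.items()}

    # --- heatmap ----------------------------------------------------------
    heatmap = build_heatmap(variants, backgrounds, [ln.line_id for ln in lines])
    heatmap.to_frame().to_csv(outdir / "heatmap.tsv", sep="\t")

    summary = {
        "seed": config.seed,
        "n_planted": len(truth.mutations),
        "n_planted_surviving": len(truth.surviving()),
        "n_called": len(variants),
        "n_wt_calls": len(wt_calls),
        "rates": rate_report,
        "tests": {
            k: v for k, v in test_report.items() if k != "per_line_snv_counts"
        },
        "indel_context_total": indel_summary.total,
        "homopolymer_profiles": {
            gid: {
                "A/T_total": p["A/T_total"],
                "G/C_total": p["G/C_total"],
                "at_gc_ratio": p["at_gc_ratio"],
            }
            for gid, p in hp_profiles.items()
        },
        "heatmap_shape": list(heatmap.values.shape),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("summary written to %s", outdir / "summary.json")
    return summary
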