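"""Replicated synthetic experiments that characterise the pipeline.

Three standing experiments, each run at the default study conditions
(50 kb mitochondrial + 20 kb plastid reference pair, 22 mutator lines at
7/6 generations, 20 WT lines, 500x mean depth, 0.2% base error with
homopolymer inflation, numt contamination of the mitochondrial tables):

* the WT null — with WT mutation rates at zero, the caller must emit
  zero variants across WT panels (the empty-control property);
* planted-variant recovery — recall of planted mutations whose final
  frequency cleared a threshold, and the false-positive count, judged
  against the truth ledger;
* weighted-rate recovery — the frequency-weighted SNV estimator against
  the planted frequency-mass rate r·f0 (rate x initial frequency), which
  drift leaves invariant in expectation.
"""

from __future__ import annotations

import numpy as np

from .calling import call_pipeline, compute_background, estimate_nuclear_coverage
from .evaluate import score_calls
from .genomes import reduced_length
from .rates import snv_rate, total_generations
from .simulate import (
    SimulationConfig,
    default_lines,
    default_references,
    simulate_experiment,
    simulate_pedigree_mutations,
)


def _run_one(refs, lines, cfg, rng):
    truth, tables, stats = simulate_experiment(refs, lines, cfg, rng)
    wt_ids = [ln.line_id for ln in lines if ln.genotype == "WT"]
    backgrounds = {
        gid: compute_background([tables[(lid, gid)] for lid in wt_ids])
        for gid in refs
    }
    coverage = {
        lid: estimate_nuclear_coverage(
            s["total_read_bases"], s["organelle_mapped_bases"],
            int(s["nuclear_genome_size"]),
        )
        for lid, s in stats.items()
    }
    calls = call_pipeline(
        list(tables.values()), backgrounds, refs, nuclear_coverage=coverage
    )
    return truth, calls, wt_ids


def wt_null_experiment(n_replicates: int = 50, seed: int = 0) -> dict:
    """WT-only panels with zero mutation rates: count any call that slips
    through the thresholds over replicate error realisations."""
    root = np.random.SeedSequence(seed)
    ref_rng, *rep_seeds = root.spawn(n_replicates + 1)
    refs = default_references(np.random.default_rng(ref_rng))
    lines = default_lines(n_mutant=0, n_wt=20)
    cfg = SimulationConfig()
    false_calls = 0
    for rep_seed in rep_seeds:
        _, calls, _ = _run_one(refs, lines, cfg, np.random.default_rng(rep_seed))
        false_calls += len(calls)
    return {"false_calls": false_calls, "n_replicates": n_replicates}


def recovery_experiment(
    n_replicates: int = 50, seed: int = 0, min_truth_frequency: float = 0.25
) -> dict:
    """Full panels: recall of planted mutations at final frequency >=
    ``min_truth_frequency`` and total false positives over replicates."""
    root = np.random.SeedSequence(seed)
    ref_rng, *rep_seeds = root.spawn(n_replicates + 1)
    refs = default_references(np.random.default_rng(ref_rng))
    lines = default_lines()
    cfg = SimulationConfig()
    recovered = missed = false_positives = wt_calls = 0
    for rep_seed in rep_seeds:
        truth, calls, wt_ids = _run_one(
            refs, lines, cfg, np.random.default_rng(rep_seed)
        )
        report = score_calls(truth, calls, min_truth_frequency=min_truth_frequency)
        recovered += len(report.recovered)
        missed += len(report.missed)
        false_positives += len(report.false_positives)
        wt_calls += sum(1 for v in calls if v.line_id in wt_ids)
    denom = recovered + missed
    return {
        "recall": recovered / denom if denom else 1.0,
        "n_qualifying": denom,
        "recovered": recovered,
        "missed": missed,
        "false_positives": false_positives,
        "wt_calls": wt_calls,
        "n_replicates": n_replicates,
    }


def rate_recovery_experiment(
    n_replicates: int = 200, seed: int = 0, genome_id: str = "plastid"
) -> dict:
    """Truth-level weighted-rate estimation over replicate pedigrees.

    Counts are not synthesised: the estimator's drift-unbiasedness is a
    property of the frequency weighting itself, so the planted final
    frequencies stand in for perfectly measured ones.
    """
    root = np.random.SeedSequence(seed)
    ref_rng, *rep_seeds = root.spawn(n_replicates + 1)
    refs = default_references(np.random.default_rng(ref_rng))
    lines = [ln for ln in default_lines() if ln.genotype == "msh1"]
    cfg = SimulationConfig()
    G = reduced_length(refs[genome_id])
    N = total_generations(lines)
    estimates = []
    for rep_seed in rep_seeds:
        truth = simulate_pedigree_mutations(
            refs, lines, cfg, np.random.default_rng(rep_seed)
        )
        V = sum(
            m.final_frequency
            for m in truth.mutations
            if m.genome_id == genome_id and m.klass == "SNV"
        )
        estimates.append(V / (G * N))
    estimates = np.asarray(estimates)
    planted = cfg.rates[genome_id].total_snv_rate * cfg.initial_frequency
    se = float(estimates.std(ddof=1) / np.sqrt(n_replicates))
    return {
        "mean_estimate": float(estimates.mean()),
        "planted_weighted_rate": planted,
        "standard_error": se,
        "z": float((estimates.mean() - planted) / se) if se else 0.0,
        "n_replicates": n_replicates,
    }
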