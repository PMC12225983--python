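#!/usr/bin/env python
"""Estimate mutation rates from the called variants.

Computes the frequency-weighted SNV rate and the unweighted indel rate
per genome (μ = V / G·N over the reduced genome length and the summed
homozygous generations), the per-class spectrum rates normalised by AT/GC
base-pair counts, and — for the WT panels, which carry no calls — the
Poisson zero-observation upper bound.  Writes rates.json / rates.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from organelle_ma import io as oio
from organelle_ma.genomes import reduced_length
from organelle_ma.rates import (
    format_rate,
    indel_rate,
    snv_rate,
    spectrum_rates,
    total_generations,
    wt_upper_bound,
)

FIXTURE = Path("results/experiment")
OUTDIR = Path("results/analysis")


def main() -> None:
    refs = oio.read_reference_bundle(FIXTURE)
    lines = oio.read_line_metadata(FIXTURE / "lines.tsv")
    variants = oio.read_variants_tsv(OUTDIR / "variants.tsv")
    mutant_ids = {ln.line_id for ln in lines if ln.genotype == "msh1"}
    wt_lines = [ln for ln in lines if ln.genotype == "WT"]
    N = total_generations([ln for ln in lines if ln.genotype == "msh1"])
    N_wt = total_generations(wt_lines)

    report = {}
    rows = []
    for gid, ref in refs.items():
        G = reduced_length(ref)
        calls = [v for v in variants if v.genome_id == gid and v.line_id in mutant_ids]
        snvs = [v for v in calls if v.klass in ("SNV", "MNV")]
        n_indels = sum(1 for v in calls if v.klass in ("insertion", "deletion"))
        weighted = snv_rate(snvs, G, N)
        unweighted_indel = indel_rate(n_indels, G, N, genome_id=gid)
        wt_bound = wt_upper_bound(G, N_wt, genome_id=gid)
        report[gid] = {
            "G": G, "N": N,
            "snv_weighted_V": weighted.V,
            "snv_mu": weighted.mu,
            "indel_count": n_indels,
            "indel_mu": unweighted_indel.mu,
            "wt_N": N_wt,
            "wt_upper_bound_mu": wt_bound.mu,
            "spectrum_class_mu": spectrum_rates(
                [v for v in snvs if v.klass == "SNV"], ref, N
            ),
        }
        rows.append(
            {
                "genome": gid, "G": G, "N": N,
                "weighted_V": round(weighted.V, 3),
                "snv_mu": format_rate(weighted.mu),
                "indel_count": n_indels,
                "indel_mu": format_rate(unweighted_indel.mu),
                "wt_upper_bound_mu": format_rate(wt_bound.mu),
            }
        )
        print(
            f"{gid}: weighted SNV mu = {format_rate(weighted.mu)} "
            f"(V = {weighted.V:.2f}, G = {G}, N = {N}); "
            f"indel mu = {format_rate(unweighted_indel.mu)} ({n_indels} indels); "
            f"WT upper bound = {format_rate(wt_bound.mu)} (N = {N_wt})"
        )
    with open(OUTDIR / "rates.json", "w") as fh:
        json.dump(report, fh, indent=2)
    pd.DataFrame(rows).to_csv(OUTDIR / "rates.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
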