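#!/usr/bin/env python
"""Test the called SNVs for signatures of selection and overdispersion.

Per-line SNV counts are compared to a Poisson expectation with the
Cameron–Trivedi score test; CDS substitutions are re-placed 10,000 times
(holding count and mutation class fixed, per genome) to build the null
distribution of the synonymous count; and the catalogue is summarised by
genomic feature class and by mutation spectrum.  Writes tests.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

from organelle_ma import io as oio
from organelle_ma.selection import (
    classify_snv,
    dispersion_test,
    genic_fraction_summary,
    permutation_test_synonymous,
    spectrum_summary,
    synonymous_status,
)

FIXTURE = Path("results/experiment")
OUTDIR = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    refs = oio.read_reference_bundle(FIXTURE)
    lines = oio.read_line_metadata(FIXTURE / "lines.tsv")
    variants = oio.read_variants_tsv(OUTDIR / "variants.tsv")
    mutant_ids = [ln.line_id for ln in lines if ln.genotype == "msh1"]
    calls = [v for v in variants if v.line_id in mutant_ids]
    report = {}

    counts = [
        sum(1 for v in calls if v.line_id == lid and v.klass in ("SNV", "MNV"))
        for lid in mutant_ids
    ]
    disp = dispersion_test(counts)
    report["dispersion"] = {
        "per_line_counts": counts,
        "statistic": disp.statistic,
        "p_value": disp.p_value,
    }
    print(
        f"per-line SNV counts range {min(counts)}-{max(counts)}; "
        f"overdispersion z = {disp.statistic:.2f}, one-sided P = {disp.p_value:.3f}"
    )

    observed_by_class, observed_syn = {}, 0
    for gid, ref in refs.items():
        per_class = {}
        for v in calls:
            if v.genome_id != gid or v.klass != "SNV":
                continue
            status = synonymous_status(ref, v.pos, v.alt)
            if status == "not_CDS":
                continue
            klass = classify_snv(v.ref, v.alt)
            per_class[klass] = per_class.get(klass, 0) + 1
            observed_syn += status == "synonymous"
        if per_class:
            observed_by_class[gid] = per_class
    if observed_by_class:
        perm = permutation_test_synonymous(
            refs, observed_by_class, observed_syn,
            n_perm=10_000, rng=np.random.default_rng(SEED),
        )
        report["synonymous_permutation"] = {
            "observed_synonymous": observed_syn,
            "null_mean": perm.null_mean,
            "p_value": perm.p_value,
        }
        print(
            f"CDS substitutions: {sum(sum(c.values()) for c in observed_by_class.values())} "
            f"({observed_syn} synonymous); permutation null mean "
            f"{perm.null_mean:.2f}, one-tailed P = {perm.p_value:.3f}"
        )
    else:
        print("no CDS substitutions called; permutation test skipped")

    for gid, ref in refs.items():
        summary = genic_fraction_summary(
            [v for v in calls if v.genome_id == gid], ref
        )
        report[f"genic_{gid}"] = summary
        print(
            f"{gid}: genic fraction of calls = {summary['genic_fraction']:.2f} "
            f"({summary['counts']})"
        )
    report["spectrum"] = {
        gid: spectrum_summary([v for v in calls if v.genome_id == gid])
        for gid in refs
    }
    for gid, spec in report["spectrum"].items():
        print(
            f"{gid}: transition fraction {spec['transition_fraction']:.2f} "
            f"over {spec['total']} SNVs"
        )
    with open(OUTDIR / "tests.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
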