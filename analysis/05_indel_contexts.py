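#!/usr/bin/env python
"""Assign indel calls to repeat contexts and summarise insertion/deletion
bias, alongside the homopolymer composition of the two genomes.

Writes indel_contexts.tsv (long-format, plot-ready) and prints the
per-context insertion:deletion balance and the A/T : G/C homopolymer
abundance ratio per genome.
"""

from pathlib import Path

from organelle_ma import io as oio
from organelle_ma.indels import homopolymer_genome_profile, indel_bias_summary

FIXTURE = Path("results/experiment")
OUTDIR = Path("results/analysis")


def main() -> None:
    refs = oio.read_reference_bundle(FIXTURE)
    lines = oio.read_line_metadata(FIXTURE / "lines.tsv")
    variants = oio.read_variants_tsv(OUTDIR / "variants.tsv")
    mutant_ids = {ln.line_id for ln in lines if ln.genotype == "msh1"}
    indel_calls = [
        v for v in variants
        if v.klass in ("insertion", "deletion") and v.line_id in mutant_ids
    ]
    summary = indel_bias_summary(indel_calls, refs)
    summary.to_frame().to_csv(OUTDIR / "indel_contexts.tsv", sep="\t", index=False)
    in_hp = sum(
        summary.counts(gid, ctx)[0] + summary.counts(gid, ctx)[1]
        for gid in refs
        for ctx in ("A/T_homopolymer", "G/C_homopolymer")
    )
    print(
        f"{summary.total} indels called; "
        f"{in_hp} ({100 * in_hp / summary.total:.0f}%) in homopolymer context"
        if summary.total else "no indels called"
    )
    for gid in refs:
        for ctx in ("A/T_homopolymer", "G/C_homopolymer"):
            ins, dels = summary.counts(gid, ctx)
            if ins + dels:
                print(f"  {gid} {ctx}: {ins} insertions, {dels} deletions")
    for gid, ref in refs.items():
        profile = homopolymer_genome_profile(ref)
        print(
            f"{gid}: {profile['A/T_total']} A/T vs {profile['G/C_total']} G/C "
            f"homopolymers (ratio {profile['at_gc_ratio']:.1f})"
        )


if __name__ == "__main__":
    main()
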