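#!/usr/bin/env python
"""Simulate the default synthetic MA experiment and persist it as a fixture.

Generates the 50 kb mitochondrial + 20 kb plastid reference pair, a panel
of 22 msh1 mutator lines (18 at 7 generations, 4 at 6) and 20 WT control
lines, plants germline mutations under the mutator regime, drifts their
heteroplasmic frequencies through per-generation bottlenecks, and writes
per-line pileup count tables with sequencing error, homopolymer error
inflation, and numt contamination.  Everything downstream (02-05) reads
the files written here.
"""

import sys
from pathlib import Path

import numpy as np

from organelle_ma import simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUTDIR = Path("results/experiment")


def main() -> None:
    root = np.random.SeedSequence(SEED)
    ref_seed, sim_seed = root.spawn(2)
    refs = simulate.default_references(np.random.default_rng(ref_seed))
    lines = simulate.default_lines()
    cfg = simulate.SimulationConfig(seed=SEED)
    truth, tables, read_stats = simulate.simulate_experiment(
        refs, lines, cfg, np.random.default_rng(sim_seed)
    )
    simulate.write_fixture(OUTDIR, refs, lines, truth, tables, read_stats, cfg)
    surviving = truth.surviving()
    print(f"wrote fixture to {OUTDIR}/ (seed {SEED})")
    print(
        f"planted {len(truth.mutations)} mutations; "
        f"{len(surviving)} survived drift "
        f"({sum(m.klass == 'SNV' for m in surviving)} SNVs, "
        f"{sum(m.klass in ('insertion', 'deletion') for m in surviving)} indels)"
    )


if __name__ == "__main__":
    main()
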