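import numpy as np
import pytest

from organelle_ma import simulate
from organelle_ma.calling import SiteCountTable
from organelle_ma.genomes import ReferenceSet


@pytest.fixture(scope="session")
def toy_refs():
    """A deterministic small mito + plastid reference pair with
    annotation, an excluded repeat, and a numt interval."""
    rng = np.random.default_rng(20240901)
    return simulate.default_references(rng, mito_length=8000, plastid_length=4000)


@pytest.fixture(scope="session")
def toy_lines():
    return simulate.default_lines(n_mutant=4, n_wt=4)


def make_table(
    ref: ReferenceSet,
    line_id: str = "L1",
    depth: int = 100,
    alt_counts: dict[tuple[int, str], int] | None = None,
    indels: dict[int, dict[str, int]] | None = None,
) -> SiteCountTable:
    """A count table with uniform depth, all-reference counts, and the
    given alt counts spliced in."""
    positions = ref.included_positions
    n = len(positions)
    ref_bases = "".join(ref.sequence[p - 1] for p in positions)
    base_counts = np.zeros((n, 4), dtype=np.int64)
    ref_idx = np.array(["ACGT".index(b) for b in ref_bases])
    depth_arr = np.full(n, depth, dtype=np.int64)
    base_counts[np.arange(n), ref_idx] = depth
    pos_to_row = {int(p): i for i, p in enumerate(positions)}
    for (pos, base), count in (alt_counts or {}).items():
        row = pos_to_row[pos]
        base_counts[row, ref_idx[row]] = 0
        base_counts[row, "ACGT".index(base)] = count
        base_counts[row, ref_idx[row]] = depth - base_counts[row].sum()
    return SiteCountTable(
        line_id=line_id,
        genome_id=ref.genome_id,
        pos=positions.astype(np.int64),
        ref_bases=ref_bases,
        depth=depth_arr,
        base_counts=base_counts,
        indels=indels or {},
    )
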