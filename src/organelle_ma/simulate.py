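"""Synthetic mutation-accumulation (MA) experiments with known ground truth.

The generator emulates the data that a resequenced MA panel yields *after*
read mapping: one per-site allele-count table per line per organelle
genome.  An experiment consists of wild-type (WT) control lines and
mutator (``msh1``) lines propagated by single-seed descent; in the
mutator regime new organelle mutations arise each generation, enter at a
configurable initial heteroplasmic frequency, and then drift by
per-generation binomial resampling through a transmission bottleneck
until sampling (many reach fixation or loss — heteroplasmic sorting).

Error structure mirrors what makes real organelle pileups hard:

* a base sequencing-error rate at every site,
* error inflation at homopolymer runs (growing with run length, capped),
  affecting both substitution and single-base indel miscalls,
* numt contamination of mitochondrial tables — nuclear copies of
  mitochondrial regions contribute reference-allele reads in proportion
  to nuclear coverage and copy number, depressing observed variant
  frequencies there.

The ``TruthLedger`` of planted mutations is the oracle for every
downstream recovery test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .genomes import (
    AnnotationRecord,
    HomopolymerRun,
    ReferenceSet,
    COMPLEMENT,
    find_homopolymers,
    reduced_length,
)
from .calling import SiteCountTable
from . import io as oio

MUTATION_CLASSES = ("AT>GC", "GC>AT", "AT>CG", "GC>TA", "AT>TA", "GC>CG")

# target base on the genome strand, per class, given the genome-strand ref base
_CLASS_TARGET = {
    ("AT>GC", "A"): "G", ("AT>GC", "T"): "C",
    ("AT>CG", "A"): "C", ("AT>CG", "T"): "G",
    ("AT>TA", "A"): "T", ("AT>TA", "T"): "A",
    ("GC>AT", "G"): "A", ("GC>AT", "C"): "T",
    ("GC>TA", "G"): "T", ("GC>TA", "C"): "A",
    ("GC>CG", "G"): "C", ("GC>CG", "C"): "G",
}


@dataclass
class LineMeta:
    """One MA line: genotype decides the mutation-rate regime, and
    ``generations`` counts homozygous generations contributing mutations
    (7 for F8 lines, 6 for F7 lines in the emulated design)."""

    line_id: str
    genotype: str  # "WT" | "msh1"
    founder: str
    generations: int

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.genotype not in ("WT", "msh1"):
            raise ValueError(f"genotype must be WT or msh1, got {self.genotype!r}")


@dataclass
class GenomeRates:
    """Per-genome mutation parameters for the mutator regime.

    ``snv_rates`` are per-bp (of the reduced genome) per-generation rates
    by strand-symmetric class.  ``hp_indel_rate`` is per homopolymer
    locus (>= ``hp_min_len``) per generation; ``hp_insertion_frac`` gives
    the insertion fraction per run class (deletion-biased at A/T runs,
    insertion-biased at G/C runs, as observed).  ``mnv_rate`` is per line
    per generation.  ``bottleneck`` is the per-generation variance-
    effective number of segregating genome copies.
    """

    snv_rates: dict[str, float]
    hp_indel_rate: float
    hp_insertion_frac: dict[str, float] = field(
        default_factory=lambda: {"A/T": 0.35, "G/C": 0.55}
    )
    mnv_rate: float = 1.0 / 150.0
    bottleneck: int = 25

    @property
    def total_snv_rate(self) -> float:
        return float(sum(self.snv_rates.values()))


def default_mito_rates() -> GenomeRates:
    # spectrum: AT>GC and GC>AT transitions roughly balanced (~47%/43%),
    # transversions rare; totals sized to the mutator regime's observed scale
    return GenomeRates(
        snv_rates={
            "AT>GC": 4.3e-7, "GC>AT": 3.9e-7,
            "AT>CG": 2.5e-8, "GC>TA": 2.5e-8, "AT>TA": 2.5e-8, "GC>CG": 2.5e-8,
        },
        hp_indel_rate=2.0e-3,
        bottleneck=8,
    )


def default_plastid_rates() -> GenomeRates:
    # strongly GC-biased spectrum (~83% AT>GC); smaller bottleneck gives
    # the faster heteroplasmic sorting seen for plastids
    return GenomeRates(
        snv_rates={
            "AT>GC": 3.2e-6, "GC>AT": 3.1e-7,
            "AT>CG": 1.0e-7, "GC>TA": 1.0e-7, "AT>TA": 1.0e-7, "GC>CG": 1.0e-7,
        },
        hp_indel_rate=6.0e-3,
        bottleneck=3,
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic MA experiment."""

    rates: dict[str, GenomeRates] = field(
        default_factory=lambda: {
            "mitochondrial": default_mito_rates(),
            "plastid": default_plastid_rates(),
        }
    )
    wt_rates: dict[str, GenomeRates] | None = None  # None => WT plants nothing
    initial_frequency: float = 0.5
    # depth model: negative binomial around the mean (fixed when sd == 0)
    mean_depth: float = 500.0
    depth_nb_size: float = 50.0
    fixed_depth: bool = False
    # error model
    base_error_rate: float = 0.002
    hp_error_inflation: float = 5.0
    hp_error_exponent: float = 1.0
    hp_error_cap: float = 0.4
    hp_min_len: int = 5
    hp_indel_error_del_frac: float = 0.6
    # numt contamination (mitochondrial tables only)
    nuclear_coverage: float = 20.0
    nuclear_genome_size: int = 150_000_000
    # founder sharing: probability that one family carries a shared
    # pre-existing heteroplasmy (off by default; the emulated design saw one)
    founder_mutation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.initial_frequency <= 1):
            raise ValueError("initial_frequency must be in [0, 1]")
        for rates in list(self.rates.values()) + list((self.wt_rates or {}).values()):
            if any(r < 0 for r in rates.snv_rates.values()) or rates.hp_indel_rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class PlantedMutation:
    line_id: str
    genome_id: str
    pos: int
    ref: str
    alt: str  # base for SNVs, two bases for MNVs, "ins:SEQ"/"del:N" for indels
    klass: str  # SNV | MNV | insertion | deletion
    generation_origin: int
    final_frequency: float

    @property
    def lost(self) -> bool:
        return self.final_frequency == 0.0


@dataclass
class TruthLedger:
    """Planted mutations, including those lost to drift (frequency 0)."""

    mutations: list[PlantedMutation] = field(default_factory=list)

    def for_line(self, line_id: str, genome_id: str) -> list[PlantedMutation]:
        return [
            m for m in self.mutations
            if m.line_id == line_id and m.genome_id == genome_id
        ]

    def surviving(self, min_frequency: float = 0.0) -> list[PlantedMutation]:
        return [
            m for m in self.mutations
            if m.final_frequency > 0.0 and m.final_frequency >= min_frequency
        ]


def default_lines(
    n_mutant: int = 22, n_wt: int = 20, mutant_generations: tuple[int, ...] = None
) -> list[LineMeta]:
    """The emulated panel: 22 mutator lines (18 at 7 generations, 4 at 6)
    and 20 WT lines at 7 generations, in three founder families each."""
    if mutant_generations is None:
        mutant_generations = tuple([7] * 18 + [6] * 4)[:n_mutant]
        if len(mutant_generations) < n_mutant:
            mutant_generations = mutant_generations + (7,) * (
                n_mutant - len(mutant_generations)
            )
    lines = []
    for i in range(n_mutant):
        fam = f"M{i % 3 + 1}"
        lines.append(
            LineMeta(f"{fam}_{i // 3 + 1}", "msh1", fam, mutant_generations[i])
        )
    for i in range(n_wt):
        fam = f"W{i % 3 + 1}"
        lines.append(LineMeta(f"{fam}_{i // 3 + 1}", "WT", fam, 7))
    return lines


# ---------------------------------------------------------------------------
# reference synthesis

def random_reference(
    genome_id: str,
    length: int,
    rng: np.random.Generator,
    at_fraction: float = 0.55,
    excluded_repeat_span: float = 0.04,
    numt_span: float = 0.2,
    numt_copies: int = 1,
    nuclear_genome_size: int = 150_000_000,
    n_genes: int = 8,
) -> ReferenceSet:
    """A synthetic organelle reference with the structural features the
    pipeline must handle: one excluded repeat copy, a numt interval map
    (mitochondrial only), and a small CDS/rRNA/tRNA annotation."""
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    seq = "".join(rng.choice(list("ATGC"), size=length, p=[p_at, p_at, p_gc, p_gc]))
    ex_len = int(length * excluded_repeat_span)
    excluded = []
    if ex_len >= 10:
        start = length - ex_len + 1
        excluded = [(start, length + 1)]  # half-open; tail of the genome
    numt_map = []
    if genome_id == "mitochondrial" and numt_span > 0:
        span = int(length * numt_span)
        numt_map = [(1, span + 1, numt_copies)]
    annotation = _random_annotation(seq, excluded, rng, n_genes=n_genes)
    return ReferenceSet(
        genome_id=genome_id,
        sequence=seq,
        excluded_repeats=excluded,
        numt_map=numt_map,
        nuclear_genome_size=nuclear_genome_size,
        annotation=annotation,
    )


def _random_annotation(
    seq: str, excluded, rng: np.random.Generator, n_genes: int
) -> list[AnnotationRecord]:
    """Non-overlapping CDS / rRNA / tRNA features over the included span."""
    length = len(seq)
    limit = min((s for s, e in excluded), default=length + 1) - 1
    records: list[AnnotationRecord] = []
    cursor = 1
    features = (["CDS"] * max(n_genes - 2, 1) + ["rRNA", "tRNA"])[:n_genes]
    for feature in features:
        gap = int(rng.integers(50, 200))
        cursor += gap
        if feature == "CDS":
            n_codons = int(rng.integers(60, 200))
            flen = 3 * n_codons
        elif feature == "rRNA":
            flen = int(rng.integers(300, 800))
        else:
            flen = int(rng.integers(70, 90))
        end = cursor + flen - 1
        if end > limit:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            AnnotationRecord(
                feature=feature, segments=[(cursor, end)], strand=strand,
                gene_id=f"{feature.lower()}{len(records)}",
            )
        )
        cursor = end + 1
    return records


def default_references(
    rng: np.random.Generator,
    mito_length: int = 50_000,
    plastid_length: int = 20_000,
) -> dict[str, ReferenceSet]:
    """The default study pair: a 50 kb mitochondrial and 20 kb plastid
    stand-in (scaled-down lengths; composition AT-richer in the plastid)."""
    return {
        "mitochondrial": random_reference(
            "mitochondrial", mito_length, rng, at_fraction=0.55
        ),
        "plastid": random_reference(
            "plastid", plastid_length, rng, at_fraction=0.65, numt_span=0.0,
        ),
    }


# ---------------------------------------------------------------------------
# pedigree mutation simulation

def _drift(freq: float, generations: int, bottleneck: int,
           rng: np.random.Generator) -> float:
    """Unbiased binomial resampling of a heteroplasmic frequency."""
    f = freq
    for _ in range(generations):
        if f in (0.0, 1.0):
            break
        f = rng.binomial(bottleneck, f) / bottleneck
    return f


def _eligible_positions(ref: ReferenceSet) -> dict[str, np.ndarray]:
    """Included positions by source pair class ('AT' or 'GC')."""
    seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    mask = ref.included_mask
    at = np.flatnonzero(((seq == ord("A")) | (seq == ord("T"))) & mask) + 1
    gc = np.flatnonzero(((seq == ord("G")) | (seq == ord("C"))) & mask) + 1
    return {"AT": at, "GC": gc}


def simulate_pedigree_mutations(
    refs: dict[str, ReferenceSet],
    lines: list[LineMeta],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthLedger:
    """Plant germline mutations per line and generation and drift them.

    Per generation each mutation class contributes Poisson(rate x G) new
    SNVs at uniformly chosen eligible sites, each homopolymer locus
    mutates with its per-locus rate, and MNVs arrive at their per-line
    rate; every new heteroplasmy then drifts through the remaining
    generations.  WT lines use ``wt_rates`` (no mutations by default).
    A position already mutated in the same line is resampled.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    ledger = TruthLedger()
    eligible = {gid: _eligible_positions(ref) for gid, ref in refs.items()}
    hp_runs = {
        gid: find_homopolymers(ref, cfg.hp_min_len) for gid, ref in refs.items()
    }
    founder_mutations: dict[tuple[str, str], PlantedMutation] = {}
    if cfg.founder_mutation_prob > 0:
        families = sorted({ln.founder for ln in lines if ln.genotype == "msh1"})
        for fam in families:
            if rng.random() < cfg.founder_mutation_prob:
                gid = "mitochondrial" if "mitochondrial" in refs else next(iter(refs))
                pos_pool = eligible[gid]["AT"]
                pos = int(pos_pool[rng.integers(len(pos_pool))])
                ref_base = refs[gid].base_at(pos)
                founder_mutations[(fam, gid)] = PlantedMutation(
                    line_id="", genome_id=gid, pos=pos, ref=ref_base,
                    alt=_CLASS_TARGET[("AT>GC", ref_base)], klass="SNV",
                    generation_origin=0, final_frequency=cfg.initial_frequency,
                )
    for line in lines:
        regime = cfg.rates if line.genotype == "msh1" else (cfg.wt_rates or {})
        for gid, ref in refs.items():
            rates = regime.get(gid)
            taken: set[int] = set()
            new: list[PlantedMutation] = []
            founder = founder_mutations.get((line.founder, gid))
            if founder is not None and line.genotype == "msh1":
                f = _drift(
                    founder.final_frequency, line.generations,
                    (rates or cfg.rates[gid]).bottleneck, rng,
                )
                new.append(
                    PlantedMutation(
                        line_id=line.line_id, genome_id=gid, pos=founder.pos,
                        ref=founder.ref, alt=founder.alt, klass="SNV",
                        generation_origin=0, final_frequency=f,
                    )
                )
                taken.add(founder.pos)
            if rates is None:
                ledger.mutations.extend(new)
                continue
            g_len = reduced_length(ref)
            runs = hp_runs[gid]
            for gen in range(1, line.generations + 1):
                remaining = line.generations - gen
                # SNVs per class
                for klass, rate in rates.snv_rates.items():
                    n_new = rng.poisson(rate * g_len)
                    source = klass[:2]
                    pool = eligible[gid][source]
                    for _ in range(n_new):
                        for _attempt in range(100):
                            pos = int(pool[rng.integers(len(pool))])
                            if pos not in taken:
                                break
                        taken.add(pos)
                        ref_base = ref.base_at(pos)
                        alt = _CLASS_TARGET[(klass, ref_base)]
                        f = _drift(
                            cfg.initial_frequency, remaining, rates.bottleneck, rng
                        )
                        new.append(
                            PlantedMutation(
                                line_id=line.line_id, genome_id=gid, pos=pos,
                                ref=ref_base, alt=alt, klass="SNV",
                                generation_origin=gen, final_frequency=f,
                            )
                        )
                # homopolymer indels, per locus
                if rates.hp_indel_rate > 0 and runs:
                    n_hits = rng.binomial(len(runs), min(rates.hp_indel_rate, 1.0))
                    hit_idx = rng.choice(len(runs), size=n_hits, replace=False)
                    for ri in hit_idx:
                        run = runs[ri]
                        if run.start in taken:
                            continue
                        taken.add(run.start)
                        ins_frac = rates.hp_insertion_frac[run.klass]
                        is_ins = rng.random() < ins_frac
                        size = int(rng.choice([1, 2, 3], p=[0.9, 0.08, 0.02]))
                        size = min(size, run.length)  # deletions cannot exceed the run
                        if is_ins:
                            alt = f"ins:{run.base * size}"
                            klass = "insertion"
                        else:
                            alt = f"del:{size}"
                            klass = "deletion"
                        f = _drift(
                            cfg.initial_frequency, remaining, rates.bottleneck, rng
                        )
                        new.append(
                            PlantedMutation(
                                line_id=line.line_id, genome_id=gid,
                                pos=run.start, ref=run.base, alt=alt,
                                klass=klass, generation_origin=gen,
                                final_frequency=f,
                            )
                        )
                # MNVs: two adjacent substitutions
                if rng.random() < rates.mnv_rate:
                    pool = eligible[gid]["AT"]
                    for _attempt in range(100):
                        pos = int(pool[rng.integers(len(pool))])
                        if (
                            pos not in taken and pos + 1 not in taken
                            and pos + 1 <= len(ref.sequence)
                            and ref.is_included(pos + 1)
                        ):
                            break
                    taken.update((pos, pos + 1))
                    ref2 = ref.sequence[pos - 1 : pos + 1]
                    alt2 = "".join(
                        _CLASS_TARGET[("AT>GC", b)] if b in "AT"
                        else _CLASS_TARGET[("GC>AT", b)]
                        for b in ref2
                    )
                    f = _drift(cfg.initial_frequency, remaining, rates.bottleneck, rng)
                    new.append(
                        PlantedMutation(
                            line_id=line.line_id, genome_id=gid, pos=pos,
                            ref=ref2, alt=alt2, klass="MNV",
                            generation_origin=gen, final_frequency=f,
                        )
                    )
            ledger.mutations.extend(new)
    return ledger


# ---------------------------------------------------------------------------
# count synthesis

def _hp_error_rates(
    ref: ReferenceSet, cfg: SimulationConfig
) -> tuple[list[HomopolymerRun], np.ndarray]:
    """Per-run indel-miscall rate: base_error x inflation x
    (len - min_len + 1)^exponent, capped."""
    runs = find_homopolymers(ref, cfg.hp_min_len)
    rates = np.array(
        [
            min(
                cfg.base_error_rate
                * cfg.hp_error_inflation
                * (run.length - cfg.hp_min_len + 1) ** cfg.hp_error_exponent,
                cfg.hp_error_cap,
            )
            for run in runs
        ]
    )
    return runs, rates


def synthesize_counts(
    ref: ReferenceSet,
    truth: TruthLedger,
    line: LineMeta,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SiteCountTable:
    """One per-site count table for one line on one genome.

    Depth is negative-binomial around the configured mean (or fixed);
    true-allele reads are binomial at each planted mutation's final
    frequency; substitution miscalls arrive per alt base at one third of
    the per-site error rate; indel miscalls arrive at homopolymer run
    starts at the inflated rate; mitochondrial tables gain Poisson
    reference-allele reads over numt intervals at copy_count x nuclear
    coverage.  Only included (non-excluded-repeat) positions are emitted.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    positions = ref.included_positions
    n = len(positions)
    ref_bases = "".join(ref.sequence[p - 1] for p in positions)
    ref_idx = np.frombuffer(
        ref_bases.encode().translate(bytes.maketrans(b"ACGT", bytes(range(4)))),
        dtype=np.uint8,
    ).astype(np.int64)
    if cfg.fixed_depth:
        organelle_depth = np.full(n, int(cfg.mean_depth), dtype=np.int64)
    else:
        # NB(mean m, size k): variance m + m^2/k
        k = cfg.depth_nb_size
        p = k / (k + cfg.mean_depth)
        organelle_depth = rng.negative_binomial(k, p, size=n).astype(np.int64)
    pos_to_row = {int(p): i for i, p in enumerate(positions)}

    # substitution errors: per alt base at rate e/3 (inflated inside runs)
    err_rate = np.full(n, cfg.base_error_rate)
    runs, run_err = _hp_error_rates(ref, cfg)
    for run, e in zip(runs, run_err):
        i0 = pos_to_row.get(run.start)
        if i0 is None:
            continue
        err_rate[i0 : i0 + run.length] = np.maximum(
            err_rate[i0 : i0 + run.length], e
        )
    base_counts = rng.binomial(
        organelle_depth[:, None], (err_rate / 3.0)[:, None] * np.ones((1, 4))
    ).astype(np.int64)
    rows = np.arange(n)
    base_counts[rows, ref_idx] = 0

    # planted mutations
    planted = truth.for_line(line.line_id, ref.genome_id)
    indels: dict[int, dict[str, int]] = {}
    snv_alt_reads = np.zeros(n, dtype=np.int64)
    for m in planted:
        if m.final_frequency <= 0:
            continue
        if m.klass in ("SNV", "MNV"):
            for offset, alt_base in enumerate(m.alt):
                row = pos_to_row.get(m.pos + offset)
                if row is None:
                    continue
                reads = rng.binomial(organelle_depth[row], m.final_frequency)
                j = "ACGT".index(alt_base)
                base_counts[row, j] += reads
                snv_alt_reads[row] += reads
        else:
            row = pos_to_row.get(m.pos)
            if row is None:
                continue
            reads = int(rng.binomial(organelle_depth[row], m.final_frequency))
            if reads:
                indels.setdefault(m.pos, {})
                indels[m.pos][m.alt] = indels[m.pos].get(m.alt, 0) + reads

    # indel miscalls at run starts
    for run, e in zip(runs, run_err):
        row = pos_to_row.get(run.start)
        if row is None:
            continue
        d = organelle_depth[row]
        n_del = int(rng.binomial(d, e * cfg.hp_indel_error_del_frac))
        n_ins = int(rng.binomial(d, e * (1.0 - cfg.hp_indel_error_del_frac)))
        if n_del or n_ins:
            cell = indels.setdefault(run.start, {})
            if n_del:
                cell["del:1"] = cell.get("del:1", 0) + n_del
            if n_ins:
                key = f"ins:{run.base}"
                cell[key] = cell.get(key, 0) + n_ins

    # reference reads fill the remaining depth (clamped at zero when
    # error + variant reads already exhaust it)
    ref_reads = organelle_depth - base_counts.sum(axis=1)
    np.maximum(ref_reads, 0, out=ref_reads)
    base_counts[rows, ref_idx] = ref_reads

    # numt contamination: extra reference-allele reads
    if ref.genome_id == "mitochondrial" and cfg.nuclear_coverage > 0:
        copies = ref.numt_copy_array[positions - 1]
        in_numt = copies > 0
        if in_numt.any():
            numt_reads = rng.poisson(
                copies[in_numt] * cfg.nuclear_coverage
            ).astype(np.int64)
            base_counts[rows[in_numt], ref_idx[in_numt]] += numt_reads
    depth = base_counts.sum(axis=1)
    return SiteCountTable(
        line_id=line.line_id,
        genome_id=ref.genome_id,
        pos=positions.astype(np.int64),
        ref_bases=ref_bases,
        depth=depth,
        base_counts=base_counts,
        indels=indels,
    )


def simulate_experiment(
    refs: dict[str, ReferenceSet],
    lines: list[LineMeta],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TruthLedger, dict[tuple[str, str], SiteCountTable], dict]:
    """Pedigree + counts for a whole panel.

    Returns the truth ledger, tables keyed (line_id, genome_id), and
    per-line read statistics consistent with the configured nuclear
    coverage (so nuclear coverage is recoverable downstream the same way
    it would be from mapping summaries).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    truth = simulate_pedigree_mutations(refs, lines, cfg, rng)
    tables: dict[tuple[str, str], SiteCountTable] = {}
    read_stats: dict[str, dict[str, float]] = {}
    for line in lines:
        organelle_bases = 0
        for gid, ref in refs.items():
            table = synthesize_counts(ref, truth, line, cfg, rng)
            tables[(line.line_id, gid)] = table
            organelle_bases += int(table.depth.sum())
        read_stats[line.line_id] = {
            "total_read_bases": float(
                organelle_bases + cfg.nuclear_coverage * cfg.nuclear_genome_size
            ),
            "organelle_mapped_bases": float(organelle_bases),
            "nuclear_genome_size": float(cfg.nuclear_genome_size),
        }
    return truth, tables, read_stats


# ---------------------------------------------------------------------------
# fixture output

def write_fixture(
    outdir: str | Path,
    refs: dict[str, ReferenceSet],
    lines: list[LineMeta],
    truth: TruthLedger,
    tables: dict[tuple[str, str], SiteCountTable],
    read_stats: dict | None = None,
    cfg: SimulationConfig | None = None,
) -> dict[str, str]:
    """Emit the whole experiment as plain-text files; deterministic given
    identical inputs.  Returns a name -> sha256 manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    oio.write_fasta(outdir / "reference.fasta", {g: r.sequence for g, r in refs.items()})
    oio.write_gff3(outdir / "annotation.gff3", {g: r.annotation for g, r in refs.items()})
    for gid, ref in refs.items():
        if ref.excluded_repeats:
            oio.write_bed(outdir / f"{gid}.excluded.bed", ref.excluded_repeats, gid)
        if ref.numt_map:
            oio.write_bed(outdir / f"{gid}.numt.bed", ref.numt_map, gid)
    oio.write_line_metadata(outdir / "lines.tsv", lines)
    oio.write_truth(outdir / "truth.tsv", truth)
    for (line_id, gid), table in sorted(tables.items()):
        oio.write_pileup(outdir / f"{line_id}.{gid}.pileup.tsv", table)
    if read_stats is not None:
        oio.write_read_stats(outdir / "read_stats.tsv", read_stats)
    if cfg is not None:
        payload = asdict(cfg)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
    manifest = {}
    for path in sorted(outdir.iterdir()):
        if path.is_file():
            manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest
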