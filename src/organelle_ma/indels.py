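"""Repeat-context assignment and bias summaries for small indels.

Organelle indels in the mutator background are overwhelmingly
replication-slippage events: whole-unit expansions or contractions of
homopolymer runs (>= 5 bp) and, more rarely, of tandem dinucleotide
arrays.  Each called indel gets exactly one context class — A/T
homopolymer, G/C homopolymer, dinucleotide, or other — and summaries
tabulate insertion/deletion bias and length spectra per class and genome.
No frequency weighting is applied anywhere here, consistent with the
unweighted indel rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomes import (
    DinucleotideRepeat,
    HomopolymerRun,
    ReferenceSet,
    find_dinucleotide_repeats,
    find_homopolymers,
)

CONTEXT_CLASSES = ("A/T_homopolymer", "G/C_homopolymer", "dinucleotide", "other")
_LENGTH_BINS = ("1", "2", "3", ">3")


def _length_bin(n: int) -> str:
    return str(n) if n <= 3 else ">3"


def _indel_payload(v) -> tuple[str, str | None, int]:
    """(kind, inserted sequence or None, length) from an indel variant."""
    kind, payload = v.alt.split(":", 1)
    if kind == "ins":
        return "insertion", payload.upper(), len(payload)
    return "deletion", None, int(payload)


def assign_indel_context(
    v,
    ref: ReferenceSet,
    hp_track: list[HomopolymerRun] | None = None,
    dinuc_track: list[DinucleotideRepeat] | None = None,
    min_len: int = 5,
    min_units: int = 3,
) -> str:
    """Context class of a left-aligned indel call.

    Homopolymer context requires a whole-number expansion/contraction of
    a run of length >= ``min_len``: the inserted (or deleted) sequence is
    a repetition of the run base and the indel position lies at or within
    the run.  Dinucleotide context analogously requires whole units of
    the array's 2-mer.  Homopolymer takes precedence; anything else is
    "other".
    """
    if v.klass not in ("insertion", "deletion"):
        raise ValueError(f"not an indel: {v.klass}")
    if hp_track is None:
        hp_track = find_homopolymers(ref, min_len)
    if dinuc_track is None:
        dinuc_track = find_dinucleotide_repeats(ref, min_units)
    kind, inserted, length = _indel_payload(v)
    for run in hp_track:
        if not (run.start <= v.pos <= run.end + 1):
            continue
        if kind == "insertion":
            if inserted == run.base * length:
                return f"{run.klass}_homopolymer"
        else:
            deleted = ref.sequence[v.pos - 1 : v.pos - 1 + length]
            if deleted == run.base * length and v.pos + length - 1 <= run.end:
                return f"{run.klass}_homopolymer"
    for arr in dinuc_track:
        if not (arr.start <= v.pos <= arr.end + 1):
            continue
        unit = arr.unit
        if kind == "insertion":
            if length % 2 == 0 and _is_unit_repetition(inserted, unit):
                return "dinucleotide"
        else:
            deleted = ref.sequence[v.pos - 1 : v.pos - 1 + length]
            if (
                length % 2 == 0
                and v.pos + length - 1 <= arr.end
                and _is_unit_repetition(deleted, unit)
            ):
                return "dinucleotide"
    return "other"


def _is_unit_repetition(seq: str, unit: str) -> bool:
    """True when seq is whole repeats of unit in either phase."""
    if not seq or len(seq) % 2:
        return False
    phased = unit * (len(seq) // 2)
    shifted = (unit[1] + unit[0]) * (len(seq) // 2)
    return seq == phased or seq == shifted


@dataclass
class IndelContextSummary:
    """Insertion/deletion counts and length spectra per genome x context."""

    table: dict[tuple[str, str], dict] = field(default_factory=dict)

    def _cell(self, genome: str, context: str) -> dict:
        key = (genome, context)
        if key not in self.table:
            self.table[key] = {
                "insertions": 0,
                "deletions": 0,
                "by_length": {b: 0 for b in _LENGTH_BINS},
            }
        return self.table[key]

    @property
    def total(self) -> int:
        return sum(
            c["insertions"] + c["deletions"] for c in self.table.values()
        )

    def counts(self, genome: str, context: str) -> tuple[int, int]:
        cell = self.table.get((genome, context))
        if cell is None:
            return (0, 0)
        return cell["insertions"], cell["deletions"]

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready long format: genome, context, direction, length, count."""
        rows = []
        for (genome, context), cell in sorted(self.table.items()):
            for direction in ("insertions", "deletions"):
                rows.append(
                    {
                        "genome": genome, "context": context,
                        "direction": direction, "length": "all",
                        "count": cell[direction],
                    }
                )
            for lbin, count in cell["by_length"].items():
                rows.append(
                    {
                        "genome": genome, "context": context,
                        "direction": "both", "length": lbin, "count": count,
                    }
                )
        return pd.DataFrame(
            rows, columns=["genome", "context", "direction", "length", "count"]
        )


def indel_bias_summary(
    variants, refs: dict[str, ReferenceSet], min_len: int = 5, min_units: int = 3
) -> IndelContextSummary:
    """Tabulate insertions vs deletions per context class and genome."""
    tracks = {
        gid: (find_homopolymers(r, min_len), find_dinucleotide_repeats(r, min_units))
        for gid, r in refs.items()
    }
    summary = IndelContextSummary()
    for v in variants:
        if v.klass not in ("insertion", "deletion"):
            continue
        hp, dinuc = tracks[v.genome_id]
        context = assign_indel_context(
            v, refs[v.genome_id], hp, dinuc, min_len=min_len, min_units=min_units
        )
        cell = summary._cell(v.genome_id, context)
        kind, _, length = _indel_payload(v)
        cell["insertions" if kind == "insertion" else "deletions"] += 1
        cell["by_length"][_length_bin(length)] += 1
    return summary


def homopolymer_genome_profile(
    ref: ReferenceSet, min_len: int = 5
) -> dict:
    """Run counts by class and length over the reduced genome, with the
    A/T : G/C abundance ratio."""
    runs = find_homopolymers(ref, min_len)
    by_class: dict[str, dict[int, int]] = {"A/T": {}, "G/C": {}}
    for run in runs:
        by_class[run.klass][run.length] = by_class[run.klass].get(run.length, 0) + 1
    at_total = sum(by_class["A/T"].values())
    gc_total = sum(by_class["G/C"].values())
    return {
        "by_class_length": by_class,
        "A/T_total": at_total,
        "G/C_total": gc_total,
        "at_gc_ratio": at_total / gc_total if gc_total else float("inf"),
    }
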