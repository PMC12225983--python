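"""Scoring called variants against a synthetic truth ledger.

A planted mutation is *recovered* when some call in the same line and
genome covers it: exact (position, allele) identity for SNVs and indels,
with MNV calls credited against the planted substitutions they span
(adjacent planted SNVs legitimately merge into one MNV call, and a
planted MNV may surface as its member substitutions).  A call matching
no planted mutation that survived drift is a *false positive*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import Variant
from .simulate import PlantedMutation, TruthLedger


@dataclass
class RecoveryReport:
    recovered: list[PlantedMutation] = field(default_factory=list)
    missed: list[PlantedMutation] = field(default_factory=list)
    false_positives: list[Variant] = field(default_factory=list)

    @property
    def recall(self) -> float:
        n = len(self.recovered) + len(self.missed)
        return len(self.recovered) / n if n else 1.0


def _call_keys(v: Variant) -> set[tuple[int, str]]:
    """(position, allele) keys a call can account for."""
    if v.klass in ("insertion", "deletion"):
        return {(v.pos, v.alt)}
    if v.klass == "SNV":
        return {(v.pos, v.alt)}
    # MNV: each member substitution plus the full-span allele, and any
    # replacement-type insertion payload at the anchor
    keys = {(v.pos, v.alt)}
    for offset, (r, a) in enumerate(zip(v.ref, v.alt)):
        keys.add((v.pos + offset, a))
    if len(v.alt) > len(v.ref):
        keys.add((v.pos + len(v.ref) - 1, f"ins:{v.alt[len(v.ref):]}"))
    return keys


def _truth_keys(m: PlantedMutation) -> set[tuple[int, str]]:
    if m.klass in ("insertion", "deletion"):
        return {(m.pos, m.alt)}
    if m.klass == "SNV":
        return {(m.pos, m.alt)}
    keys = {(m.pos, m.alt)}
    for offset, a in enumerate(m.alt):
        keys.add((m.pos + offset, a))
    return keys


def score_calls(
    truth: TruthLedger,
    variants: list[Variant],
    min_truth_frequency: float = 0.0,
) -> RecoveryReport:
    """Match calls to planted mutations per (line, genome).

    ``min_truth_frequency`` restricts the recall denominator to planted
    mutations at or above that final frequency; false positives are
    judged against *all* surviving planted mutations, so a call on a real
    but low-frequency mutation is not a false positive.
    """
    report = RecoveryReport()
    surviving = truth.surviving()
    truth_index: dict[tuple[str, str], list[PlantedMutation]] = {}
    for m in surviving:
        truth_index.setdefault((m.line_id, m.genome_id), []).append(m)
    call_index: dict[tuple[str, str], list[Variant]] = {}
    for v in variants:
        call_index.setdefault((v.line_id, v.genome_id), []).append(v)
    for group, calls in call_index.items():
        planted = truth_index.get(group, [])
        truth_key_sets = [(_truth_keys(m), m) for m in planted]
        for v in calls:
            ck = _call_keys(v)
            if not any(ck & tk for tk, _ in truth_key_sets):
                report.false_positives.append(v)
    for group, planted in truth_index.items():
        calls = call_index.get(group, [])
        call_key_union: set[tuple[int, str]] = set()
        for v in calls:
            call_key_union |= _call_keys(v)
        for m in planted:
            if m.final_frequency < min_truth_frequency:
                continue
            if _truth_keys(m) & call_key_union:
                report.recovered.append(m)
            else:
                report.missed.append(m)
    return report
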