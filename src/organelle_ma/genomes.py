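"""Organelle reference genomes and their sequence-context tracks.

The two genomes of interest are the plant mitochondrial and plastid
(chloroplast) genomes.  Both carry large repeats that are effectively
identical in sequence and interconvert by recombination, so one copy of
each repeat pair is excluded from variant calling and from the genome
length ``G`` used as the denominator of mutation-rate estimates.  The
mitochondrial genome additionally has a large nuclear copy (numt) whose
reads contaminate mitochondrial allele counts; the numt copy structure is
carried here as an interval map.

Coordinates are 1-based throughout.  Excluded-repeat and numt intervals
are half-open ``[start, end)``; annotation segments are inclusive
``(start, end)`` to match the convention of GFF-style records.
Genomes are treated as linear: repeat and homopolymer scans do not merge
runs across the circular origin (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

FEATURE_CLASSES = ("CDS", "rRNA", "tRNA", "intron", "intergenic")
# classify_position precedence when records nest (intron inside a gene span)
_FEATURE_PRIORITY = {"CDS": 0, "rRNA": 1, "tRNA": 2, "intron": 3}


class InvalidReferenceError(ValueError):
    """Raised when a reference set violates its structural invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class AnnotationRecord:
    """One annotated feature.

    ``segments`` is an ordered list of 1-based inclusive intervals; CDS
    features with introns carry one segment per exon, concatenated in
    translation order (genome order for + strand genes, reversed and
    complemented for − strand genes when the coding sequence is built).
    ``frame_anchor`` is the position of the first codon base and must be
    the first coordinate of the first segment for + strand CDS records
    (last coordinate of the last segment for − strand).
    """

    feature: str
    segments: list[tuple[int, int]]
    strand: str = "+"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.feature not in ("CDS", "rRNA", "tRNA", "intron"):
            raise ValueError(f"unknown feature type {self.feature!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.segments:
            raise ValueError("annotation record needs at least one segment")
        for start, end in self.segments:
            if start < 1 or end < start:
                raise ValueError(f"bad segment ({start}, {end})")
        if self.feature == "CDS" and self.coding_length % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id or self.segments} has length "
                f"{self.coding_length}, not a multiple of 3"
            )

    @property
    def coding_length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.segments)


@dataclass
class HomopolymerRun:
    """A maximal single-nucleotide repeat."""

    base: str
    start: int  # 1-based position of the first base of the run
    length: int

    @property
    def end(self) -> int:
        """1-based position of the last base of the run."""
        return self.start + self.length - 1

    @property
    def klass(self) -> str:
        return "A/T" if self.base in "AT" else "G/C"


@dataclass
class DinucleotideRepeat:
    """A maximal tandem array of a two-base unit (bases differ).

    Reported in canonical (leftmost-start) phase.  ``units`` counts full
    units only; a partial trailing unit extends ``end`` but not ``units``.
    """

    unit: str
    start: int
    end: int  # 1-based inclusive, includes any partial trailing unit
    units: int


@dataclass
class ReferenceSet:
    """An organelle reference genome plus its context tracks.

    ``excluded_repeats`` are 1-based half-open intervals removed from
    calling and from the reduced length G.  ``numt_map`` entries are
    ``(start, end, copy_count)`` half-open intervals giving how many
    copies of that mitochondrial region exist in the nuclear numt
    (empty for the plastid genome).
    """

    genome_id: str
    sequence: str
    excluded_repeats: list[tuple[int, int]] = field(default_factory=list)
    numt_map: list[tuple[int, int, int]] = field(default_factory=list)
    nuclear_genome_size: int = 0
    annotation: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidReferenceError("empty sequence")
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise InvalidReferenceError(f"non-ACGT characters in sequence: {bad}")
        n = len(self.sequence)
        prev_end = 0
        for start, end in sorted(self.excluded_repeats):
            if start < 1 or end > n + 1 or end <= start:
                raise InvalidReferenceError(
                    f"excluded repeat [{start}, {end}) outside [1, {n}]"
                )
            if start < prev_end:
                raise InvalidReferenceError("excluded repeats overlap")
            prev_end = end
        for start, end, copies in self.numt_map:
            if copies < 0:
                raise InvalidReferenceError("numt copy count must be >= 0")
            if start < 1 or end > n + 1 or end <= start:
                raise InvalidReferenceError(f"numt interval [{start}, {end}) invalid")
        if reduced_length(self) <= 0:
            raise InvalidReferenceError("excluded repeats cover the whole genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        return self.sequence[pos - 1]

    @property
    def included_mask(self) -> np.ndarray:
        """Boolean array, index ``pos - 1``; True where calling is allowed."""
        mask = np.ones(len(self.sequence), dtype=bool)
        for start, end in self.excluded_repeats:
            mask[start - 1 : end - 1] = False
        return mask

    def is_included(self, pos: int) -> bool:
        return all(not (start <= pos < end) for start, end in self.excluded_repeats)

    @property
    def included_positions(self) -> np.ndarray:
        """Sorted 1-based positions eligible for variant calling."""
        return np.flatnonzero(self.included_mask) + 1

    def numt_copies_at(self, pos: int) -> int:
        total = 0
        for start, end, copies in self.numt_map:
            if start <= pos < end:
                total += copies
        return total

    @property
    def numt_copy_array(self) -> np.ndarray:
        copies = np.zeros(len(self.sequence), dtype=np.int64)
        for start, end, count in self.numt_map:
            copies[start - 1 : end - 1] += count
        return copies


def reduced_length(ref: ReferenceSet) -> int:
    """Genome length minus total excluded-repeat length (the G of μ = V/GN)."""
    excluded = sum(end - start for start, end in ref.excluded_repeats)
    g = len(ref.sequence) - excluded
    if g <= 0:
        raise InvalidReferenceError(f"reduced length {g} <= 0")
    return g


def base_pair_composition(ref: ReferenceSet) -> tuple[int, int]:
    """Counts of A:T and G:C base pairs over the reduced genome.

    Strand-symmetric: an A or a T position is one A:T pair, a G or C
    position one G:C pair, so ``AT + GC == reduced_length``.
    """
    seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    mask = ref.included_mask
    at = int(np.count_nonzero(((seq == ord("A")) | (seq == ord("T"))) & mask))
    gc = int(np.count_nonzero(((seq == ord("G")) | (seq == ord("C"))) & mask))
    return at, gc


def _runs(sequence: str) -> list[tuple[str, int, int]]:
    """All maximal runs as (base, 1-based start, length), via change points."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    if arr.size == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [arr.size]))
    return [
        (sequence[s], int(s) + 1, int(e - s)) for s, e in zip(starts, ends)
    ]


def find_homopolymers(ref: ReferenceSet, min_len: int = 5) -> list[HomopolymerRun]:
    """Maximal single-base runs of length >= min_len outside excluded repeats.

    A run that overlaps an excluded repeat at all is dropped (its copy in
    the retained repeat arm is surveyed there instead).  Sorted by start.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    out = []
    for base, start, length in _runs(ref.sequence):
        if length < min_len:
            continue
        end = start + length  # half-open
        overlaps = any(start < e and s < end for s, e in ref.excluded_repeats)
        if not overlaps:
            out.append(HomopolymerRun(base=base, start=start, length=length))
    return out


def find_dinucleotide_repeats(
    ref: ReferenceSet, min_units: int = 3
) -> list[DinucleotideRepeat]:
    """Maximal tandem dinucleotide arrays with >= min_units full units.

    The two unit bases must differ (homopolymers are not dinucleotide
    arrays).  Arrays are reported in leftmost phase; a trailing partial
    unit extends the span but not the unit count.  Arrays overlapping an
    excluded repeat are dropped.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    seq = ref.sequence
    n = len(seq)
    out = []
    i = 0
    while i < n - 1:
        a, b = seq[i], seq[i + 1]
        if a == b:
            i += 1
            continue
        # count full units of (a, b) starting at i
        j = i
        while j + 1 < n and seq[j] == a and seq[j + 1] == b:
            j += 2
        units = (j - i) // 2
        end = j  # 0-based one-past the last full unit
        if units >= min_units:
            span_end = end
            if span_end < n and seq[span_end] == a:  # partial trailing unit
                span_end += 1
            start_1 = i + 1
            end_1 = span_end  # inclusive 1-based == 0-based one-past
            ex_overlap = any(
                start_1 < e and s <= end_1 for s, e in ref.excluded_repeats
            )
            if not ex_overlap:
                out.append(
                    DinucleotideRepeat(unit=a + b, start=start_1, end=end_1, units=units)
                )
            i = span_end
        else:
            i += 1
    return out


def classify_position(ref: ReferenceSet, pos: int) -> str:
    """Feature class of a position: CDS, rRNA, tRNA, intron, or intergenic.

    Positions covered by no annotation record are intergenic.  When
    records nest (an intron annotated within a gene's span), the most
    specific gene feature wins per the priority CDS > rRNA > tRNA > intron.
    """
    if pos < 1 or pos > len(ref.sequence):
        raise ValueError(f"position {pos} outside [1, {len(ref.sequence)}]")
    hits = [rec for rec in ref.annotation if rec.contains(pos)]
    if not hits:
        return "intergenic"
    return min(hits, key=lambda r: _FEATURE_PRIORITY[r.feature]).feature
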