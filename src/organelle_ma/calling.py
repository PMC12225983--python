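"""Heteroplasmic variant calling from per-site allele counts.

The procedure is deliberately threshold-based (no genotype likelihoods):

1. candidate emission — allele frequency >= 20%, depth >= 50x, and at
   least 3-fold above the mean frequency of the same allele across all
   wild-type (WT) control lines (the WT background absorbs locus-specific
   sequencing-error profiles, e.g. at long homopolymers);
2. removal of calls in excluded large-repeat copies;
3. removal of calls whose alt-containing flank context occurs verbatim in
   a supplied artefact sequence (structural-rearrangement junctions, the
   numt) on either strand;
4. numt frequency correction for mitochondrial variants — nuclear
   numt copies contribute reference-allele reads, so the expected number
   of nuclear-derived reads is subtracted from the reference count and
   the total depth before recomputing the frequency;
5. merging of adjacent substitutions (and substitution+insertion at one
   site) into multi-nucleotide variants (MNVs);
6. homoplasmy labelling (plastid >= 98%; mitochondrial > 90% after numt
   correction — strict, because the correction is approximate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genomes import ReferenceSet, reverse_complement, _BASES, _BASE_INDEX


@dataclass
class SiteCountTable:
    """Per-line, per-position allele counts for one organelle genome.

    ``pos`` is strictly increasing 1-based positions (excluded-repeat
    positions are normally absent).  ``base_counts`` has one row per
    position with columns A, C, G, T; the reference-base column holds the
    reference-allele count.  ``indels`` maps position -> allele -> count
    with alleles keyed ``ins:SEQ`` / ``del:LEN`` left-aligned to the
    start of their repeat run.
    """

    line_id: str
    genome_id: str
    pos: np.ndarray
    ref_bases: str
    depth: np.ndarray
    base_counts: np.ndarray
    indels: dict[int, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.depth < self.base_counts.sum(axis=1)):
            raise ValueError("depth below the sum of recorded allele counts")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def ref_index(self) -> np.ndarray:
        return np.frombuffer(
            self.ref_bases.encode().translate(bytes.maketrans(b"ACGT", bytes(range(4)))),
            dtype=np.uint8,
        ).astype(np.int64)


@dataclass
class Variant:
    """A filtered heteroplasmic/homoplasmic call."""

    line_id: str
    genome_id: str
    pos: int
    ref: str
    alt: str
    klass: str  # SNV | MNV | insertion | deletion
    depth: int
    alt_count: int
    ref_count: int
    raw_frequency: float
    wt_background_mean: float = 0.0
    corrected_frequency: float = 0.0
    zygosity_label: str | None = None
    context: str | None = None
    uncorrectable: bool = False

    def __post_init__(self) -> None:
        if self.corrected_frequency == 0.0:
            self.corrected_frequency = self.raw_frequency


@dataclass
class BackgroundProfile:
    """Mean per-allele variant frequency across all WT lines.

    ``base_freq`` is aligned with the shared position vector ``pos``
    (rows) x base columns A,C,G,T; ``indel_freq`` maps
    (pos, allele) -> mean frequency.  The profile is per-allele, not
    summed non-reference: a real variant in one WT line then cannot mask
    a different alternate allele at the same site.
    """

    genome_id: str
    pos: np.ndarray
    base_freq: np.ndarray
    indel_freq: dict[tuple[int, str], float]
    n_wt: int

    def base_background(self, pos: int, base: str) -> float:
        i = int(np.searchsorted(self.pos, pos))
        if i >= len(self.pos) or self.pos[i] != pos:
            return 0.0
        return float(self.base_freq[i, _BASE_INDEX[base]])

    def indel_background(self, pos: int, allele: str) -> float:
        return self.indel_freq.get((pos, allele), 0.0)


class EmptyWTSetError(ValueError):
    """The 3-fold background rule is undefined without WT lines."""


def compute_background(wt_tables: list[SiteCountTable]) -> BackgroundProfile:
    """Per-position, per-allele mean frequency over WT lines.

    Frequencies are count/depth per line (0 where depth is 0), averaged
    with equal weight per line.  Indel alleles observed in any WT line
    get a mean over *all* WT lines (absent alleles contribute 0).
    """
    if not wt_tables:
        raise EmptyWTSetError("at least one WT table is required")
    first = wt_tables[0]
    for t in wt_tables[1:]:
        if t.genome_id != first.genome_id or not np.array_equal(t.pos, first.pos):
            raise ValueError("WT tables must share genome and position vector")
    n = len(wt_tables)
    freq_sum = np.zeros_like(first.base_counts, dtype=float)
    for t in wt_tables:
        depth = np.where(t.depth > 0, t.depth, 1)
        freq_sum += t.base_counts / depth[:, None] * (t.depth > 0)[:, None]
    # the reference allele is not a variant; keep alt-allele backgrounds only
    freq_sum[np.arange(len(first)), first.ref_index] = 0.0
    indel_sum: dict[tuple[int, str], float] = {}
    for t in wt_tables:
        pos_to_idx = None
        for pos, alleles in t.indels.items():
            if pos_to_idx is None:
                pos_to_idx = {int(p): i for i, p in enumerate(t.pos)}
            d = t.depth[pos_to_idx[pos]]
            if d == 0:
                continue
            for allele, count in alleles.items():
                key = (pos, allele)
                indel_sum[key] = indel_sum.get(key, 0.0) + count / d
    return BackgroundProfile(
        genome_id=first.genome_id,
        pos=first.pos.copy(),
        base_freq=freq_sum / n,
        indel_freq={k: v / n for k, v in indel_sum.items()},
        n_wt=n,
    )


def call_candidates(
    table: SiteCountTable,
    bg: BackgroundProfile,
    min_freq: float = 0.20,
    min_depth: int = 50,
    bg_fold: float = 3.0,
) -> list[Variant]:
    """Emit candidates passing frequency, depth, and WT-background gates.

    A (position, allele) passes when frequency >= ``min_freq``, depth >=
    ``min_depth``, and frequency >= ``bg_fold`` x the WT mean for that
    allele (a zero background leaves only the first two gates).  Several
    alt alleles at one site may each be emitted.
    """
    if not (0 < min_freq <= 1):
        raise ValueError("min_freq must be in (0, 1]")
    if min_depth < 1 or bg_fold < 1:
        raise ValueError("min_depth >= 1 and bg_fold >= 1 required")
    out: list[Variant] = []
    depth = table.depth
    safe_depth = np.where(depth > 0, depth, 1)
    freq = table.base_counts / safe_depth[:, None]
    ref_idx = table.ref_index
    rows = np.arange(len(table))
    freq[rows, ref_idx] = 0.0  # the reference allele is never a variant
    bg_freq = bg.base_freq if np.array_equal(bg.pos, table.pos) else None
    passing = (freq >= min_freq) & (depth[:, None] >= min_depth)
    if bg_freq is not None:
        passing &= freq >= bg_fold * bg_freq
    for i, j in zip(*np.nonzero(passing)):
        pos = int(table.pos[i])
        base = _BASES[j]
        bg_mean = (
            float(bg_freq[i, j]) if bg_freq is not None else bg.base_background(pos, base)
        )
        if bg_freq is None and freq[i, j] < bg_fold * bg_mean:
            continue
        out.append(
            Variant(
                line_id=table.line_id, genome_id=table.genome_id, pos=pos,
                ref=table.ref_bases[i], alt=base, klass="SNV",
                depth=int(depth[i]),
                alt_count=int(table.base_counts[i, j]),
                ref_count=int(table.base_counts[i, ref_idx[i]]),
                raw_frequency=float(freq[i, j]),
                wt_background_mean=bg_mean,
            )
        )
    pos_to_idx = {int(p): i for i, p in enumerate(table.pos)}
    for pos, alleles in sorted(table.indels.items()):
        i = pos_to_idx[pos]
        d = int(depth[i])
        if d < min_depth or d == 0:
            continue
        for allele, count in sorted(alleles.items()):
            f = count / d
            bg_mean = bg.indel_background(pos, allele)
            if f >= min_freq and f >= bg_fold * bg_mean:
                kind, payload = allele.split(":", 1)
                out.append(
                    Variant(
                        line_id=table.line_id, genome_id=table.genome_id,
                        pos=pos, ref=table.ref_bases[i], alt=allele,
                        klass="insertion" if kind == "ins" else "deletion",
                        depth=d, alt_count=int(count),
                        ref_count=int(table.base_counts[i, table.ref_index[i]]),
                        raw_frequency=float(f), wt_background_mean=bg_mean,
                    )
                )
    out.sort(key=lambda v: (v.pos, v.alt))
    return out


def exclude_repeat_copies(variants: list[Variant], ref: ReferenceSet) -> list[Variant]:
    """Drop variants inside the excluded large-repeat copies."""
    return [v for v in variants if ref.is_included(v.pos)]


def _alt_context(v: Variant, ref: ReferenceSet, k: int) -> str:
    """k-bp flanks around the variant with the alt allele substituted."""
    seq = ref.sequence
    p0 = v.pos - 1  # 0-based
    left = seq[max(p0 - k, 0) : p0]
    if v.klass == "SNV" or v.klass == "MNV":
        alt = v.alt
        right = seq[p0 + len(v.ref) : p0 + len(v.ref) + k]
        return left + alt + right
    kind, payload = v.alt.split(":", 1)
    if kind == "ins":
        # inserted sequence follows the anchor base
        return left + seq[p0] + payload + seq[p0 + 1 : p0 + 1 + k]
    dlen = int(payload)
    return left + seq[p0 + dlen : p0 + dlen + k]


def exclude_structural_artifacts(
    variants: list[Variant],
    artefact_seqs: list[str],
    ref: ReferenceSet,
    k: int = 20,
) -> list[Variant]:
    """Drop variants whose alt context occurs exactly in an artefact sequence.

    This is the deterministic stand-in for similarity-search screening of
    candidate calls against rearrangement-junction and numt sequences: a
    call whose alt-containing context (k-bp flank each side) exists
    verbatim in any artefact sequence, on either strand, is explainable
    by mismapped reads from that artefact and is excluded.
    """
    if k < 8:
        raise ValueError("flank size k must be >= 8")
    if not artefact_seqs:
        return list(variants)
    haystacks = [s.upper() for s in artefact_seqs]
    haystacks += [reverse_complement(s) for s in haystacks]
    kept = []
    for v in variants:
        ctx = _alt_context(v, ref, k)
        if not any(ctx in h for h in haystacks):
            kept.append(v)
    return kept


def estimate_nuclear_coverage(
    total_read_bases: float, organelle_mapped_bases: float, nuclear_genome_size: int
) -> float:
    """Fold coverage of the nuclear genome from non-organelle read bases."""
    if nuclear_genome_size <= 0:
        raise ValueError("nuclear_genome_size must be positive")
    remainder = total_read_bases - organelle_mapped_bases
    if remainder < 0:
        raise ValueError("organelle-mapped bases exceed total read bases")
    return remainder / nuclear_genome_size


def correct_numt_frequency(
    v: Variant, nuclear_coverage: float, numt_copies: int
) -> Variant:
    """Recompute a mitochondrial variant frequency net of numt reads.

    The numt carries the reference allele, so the expected number of
    nuclear-derived reads (nuclear coverage x numt copy count, kept as a
    real number) is subtracted from both the reference-allele count and
    the total depth before recomputing the frequency.  The correction can
    only raise the frequency; the result is capped at 1.0.  Plastid
    variants and sites with zero numt copies pass through unchanged.
    """
    if nuclear_coverage < 0:
        raise ValueError("nuclear coverage must be >= 0")
    if v.genome_id != "mitochondrial" or numt_copies == 0:
        return replace(v, corrected_frequency=v.raw_frequency)
    expected = nuclear_coverage * numt_copies
    removed = min(expected, v.ref_count)
    total = v.depth - removed
    if total <= 0:
        return replace(v, corrected_frequency=v.raw_frequency, uncorrectable=True)
    corrected = min(v.alt_count / total, 1.0)
    return replace(v, corrected_frequency=max(corrected, v.raw_frequency))


def merge_mnv(variants: list[Variant]) -> list[Variant]:
    """Merge adjacent substitutions (per line and genome) into MNVs.

    A chain of SNVs at consecutive positions becomes one MNV whose
    frequency is the mean of its members'; an insertion co-located with
    an SNV at the same position becomes a replacement-type MNV (one base
    pair replaced by a longer tract).  Members are removed from the SNV
    pool so MNVs are not double-counted.
    """
    by_group: dict[tuple[str, str], list[Variant]] = {}
    passthrough: list[Variant] = []
    for v in variants:
        if v.klass in ("SNV", "insertion"):
            by_group.setdefault((v.line_id, v.genome_id), []).append(v)
        else:
            passthrough.append(v)
    out: list[Variant] = []
    for group in by_group.values():
        snvs = sorted((v for v in group if v.klass == "SNV"), key=lambda v: v.pos)
        insertions = [v for v in group if v.klass == "insertion"]
        used_ins: set[int] = set()
        i = 0
        while i < len(snvs):
            j = i
            while j + 1 < len(snvs) and snvs[j + 1].pos == snvs[j].pos + 1:
                j += 1
            members = snvs[i : j + 1]
            ins_here = [
                w for w in insertions
                if id(w) not in used_ins and any(w.pos == m.pos for m in members)
            ]
            if len(members) == 1 and not ins_here:
                out.append(members[0])
            else:
                all_members = members + ins_here
                for w in ins_here:
                    used_ins.add(id(w))
                ref = "".join(m.ref for m in members)
                alt = "".join(m.alt for m in members)
                for w in ins_here:
                    alt += w.alt.split(":", 1)[1]
                raw = float(np.mean([m.raw_frequency for m in all_members]))
                corr = float(np.mean([m.corrected_frequency for m in all_members]))
                first = members[0]
                out.append(
                    Variant(
                        line_id=first.line_id, genome_id=first.genome_id,
                        pos=first.pos, ref=ref, alt=alt, klass="MNV",
                        depth=first.depth, alt_count=first.alt_count,
                        ref_count=first.ref_count, raw_frequency=raw,
                        wt_background_mean=first.wt_background_mean,
                        corrected_frequency=corr,
                    )
                )
            i = j + 1
        out.extend(v for v in insertions if id(v) not in used_ins)
    out.extend(passthrough)
    out.sort(key=lambda v: (v.genome_id, v.line_id, v.pos, v.alt))
    return out


# homoplasmy thresholds: plastid calls at >= 98% frequency are treated as
# fixed; mitochondrial calls need > 90% *corrected* frequency (strict)
# because the numt correction is approximate.
PLASTID_HOMOPLASMY_MIN = 0.98
MITO_HOMOPLASMY_GT = 0.90


def label_zygosity(v: Variant) -> Variant:
    if v.genome_id == "plastid":
        homo = v.corrected_frequency >= PLASTID_HOMOPLASMY_MIN
    else:
        homo = v.corrected_frequency > MITO_HOMOPLASMY_GT
    return replace(
        v, zygosity_label="homoplasmic_candidate" if homo else "heteroplasmic"
    )


@dataclass
class CallParams:
    min_freq: float = 0.20
    min_depth: int = 50
    bg_fold: float = 3.0
    flank_k: int = 20


def call_pipeline(
    tables: list[SiteCountTable],
    backgrounds: dict[str, BackgroundProfile],
    refs: dict[str, ReferenceSet],
    artefacts: dict[str, list[str]] | None = None,
    nuclear_coverage: dict[str, float] | None = None,
    params: CallParams | None = None,
) -> list[Variant]:
    """Full cascade: candidates -> repeat exclusion -> artefact exclusion
    -> numt correction -> MNV merge -> zygosity labels.  Deterministic."""
    params = params or CallParams()
    artefacts = artefacts or {}
    nuclear_coverage = nuclear_coverage or {}
    out: list[Variant] = []
    for table in tables:
        ref = refs[table.genome_id]
        variants = call_candidates(
            table, backgrounds[table.genome_id],
            min_freq=params.min_freq, min_depth=params.min_depth,
            bg_fold=params.bg_fold,
        )
        variants = exclude_repeat_copies(variants, ref)
        variants = exclude_structural_artifacts(
            variants, artefacts.get(table.genome_id, []), ref, k=params.flank_k
        )
        if table.genome_id == "mitochondrial":
            cov = nuclear_coverage.get(table.line_id, 0.0)
            copies = ref.numt_copy_array
            variants = [
                correct_numt_frequency(v, cov, int(copies[v.pos - 1]))
                if v.klass == "SNV" else v
                for v in variants
            ]
        variants = merge_mnv(variants)
        out.extend(label_zygosity(v) for v in variants)
    out.sort(key=lambda v: (v.genome_id, v.line_id, v.pos, v.alt))
    return out
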