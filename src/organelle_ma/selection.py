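"""Selection and distributional tests on the called variant set.

Three questions an MA analysis asks of its SNV catalogue:

* Is the count of synonymous changes compatible with no selection?  A
  spectrum-preserving permutation test holds the number and class of CDS
  substitutions fixed and re-places them uniformly on eligible coding
  sites, building a null distribution of the total synonymous count.
* Are per-line SNV counts Poisson, as independent accumulation predicts?
  The Cameron–Trivedi score test for overdispersion answers one-sidedly.
* Do variants fall in genic sequence in proportion to its share of the
  genome?  Summaries by feature class and mutation class cover this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

from .genomes import AnnotationRecord, ReferenceSet, COMPLEMENT, reverse_complement

MUTATION_CLASSES = ("AT>GC", "GC>AT", "AT>CG", "GC>TA", "AT>TA", "GC>CG")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_PAIR = {"A": "AT", "T": "AT", "G": "GC", "C": "GC"}


def classify_snv(ref_base: str, alt_base: str) -> str:
    """Strand-symmetric mutation class: A→G and T→C are both AT>GC, etc."""
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise ValueError(f"bases must be ACGT, got {ref_base!r}->{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt are identical")
    r, a = ref_base, alt_base
    if r in "TC":  # normalise to the A/G representative of the pair
        r, a = COMPLEMENT[r], COMPLEMENT[a]
    return {
        ("A", "G"): "AT>GC", ("A", "C"): "AT>CG", ("A", "T"): "AT>TA",
        ("G", "A"): "GC>AT", ("G", "T"): "GC>TA", ("G", "C"): "GC>CG",
    }[(r, a)]


TRANSITIONS = ("AT>GC", "GC>AT")


# ---------------------------------------------------------------------------
# codon-level machinery

def _cds_layout(ref: ReferenceSet) -> list[tuple[AnnotationRecord, str, dict[int, int]]]:
    """For each CDS record: its coding-strand sequence and a map
    genome position -> index within that coding sequence."""
    out = []
    for rec in ref.annotation:
        if rec.feature != "CDS":
            continue
        genome_positions: list[int] = []
        for start, end in rec.segments:
            genome_positions.extend(range(start, end + 1))
        concat = "".join(ref.sequence[p - 1] for p in genome_positions)
        if rec.strand == "-":
            coding = reverse_complement(concat)
            order = list(reversed(genome_positions))
        else:
            coding = concat
            order = genome_positions
        pos_to_idx = {p: i for i, p in enumerate(order)}
        out.append((rec, coding, pos_to_idx))
    return out


def synonymous_status(ref: ReferenceSet, pos: int, alt_base: str) -> str:
    """'synonymous' | 'nonsynonymous' | 'not_CDS' for a substitution.

    Translates the affected codon (standard genetic code) before and
    after the change, on the coding strand; multi-segment CDS records
    are concatenated in annotation order before codon phasing.
    """
    if alt_base not in "ACGT":
        raise ValueError(f"alt base must be ACGT, got {alt_base!r}")
    for rec, coding, pos_to_idx in _cds_layout(ref):
        idx = pos_to_idx.get(pos)
        if idx is None:
            continue
        coding_alt = alt_base if rec.strand == "+" else COMPLEMENT[alt_base]
        codon_start = (idx // 3) * 3
        codon = coding[codon_start : codon_start + 3]
        mutant = (
            codon[: idx % 3] + coding_alt + codon[idx % 3 + 1 :]
        )
        if _CODON_TO_AA[codon] == _CODON_TO_AA[mutant]:
            return "synonymous"
        return "nonsynonymous"
    return "not_CDS"


@dataclass
class PermutationResult:
    observed_synonymous: int
    n_perm: int
    p_value: float
    null_mean: float
    null_sd: float
    null_counts: np.ndarray
    seed: int | None = None

    @property
    def below_resolution(self) -> bool:
        """True when no permutation reached the observed count (p printed
        as < 1/n_perm)."""
        return self.p_value == 0.0


class NoEligibleSiteError(ValueError):
    pass


def _class_site_tables(ref: ReferenceSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per mutation class: (eligible CDS genome positions, synonymous flag).

    A site is eligible for a class when its reference base pair matches
    the class's source pair; the target base at that site is then fixed
    by the class and the site's genome-strand base.
    """
    tables: dict[str, tuple[list[int], list[bool]]] = {
        c: ([], []) for c in MUTATION_CLASSES
    }
    seen: set[int] = set()
    for rec, coding, pos_to_idx in _cds_layout(ref):
        for pos, idx in pos_to_idx.items():
            if pos in seen or not ref.is_included(pos):
                continue
            seen.add(pos)
            base = ref.sequence[pos - 1]
            source = _PAIR[base]
            codon_start = (idx // 3) * 3
            codon = coding[codon_start : codon_start + 3]
            aa = _CODON_TO_AA[codon]
            offset = idx % 3
            for klass in MUTATION_CLASSES:
                if not klass.startswith(source):
                    continue
                alt = _target_base(base, klass.split(">")[1])
                coding_alt = alt if rec.strand == "+" else COMPLEMENT[alt]
                mutant = codon[:offset] + coding_alt + codon[offset + 1 :]
                syn = _CODON_TO_AA[mutant] == aa
                tables[klass][0].append(pos)
                tables[klass][1].append(syn)
    return {
        c: (np.array(p, dtype=np.int64), np.array(s, dtype=bool))
        for c, (p, s) in tables.items()
    }


def _target_base(ref_base: str, target_pair: str) -> str:
    """The genome-strand alt base a class implies at a given site."""
    # the pair notation is oriented: AT>GC means A->G (and T->C on the
    # complement); the class-defining purine/pyrimidine identity is kept
    mapping = {
        ("A", "GC"): "G", ("T", "GC"): "C",
        ("A", "CG"): "C", ("T", "CG"): "G",
        ("A", "TA"): "T", ("T", "TA"): "A",
        ("G", "AT"): "A", ("C", "AT"): "T",
        ("G", "TA"): "T", ("C", "TA"): "A",
        ("G", "CG"): "C", ("C", "CG"): "G",
    }
    return mapping[(ref_base, target_pair)]


def permutation_test_synonymous(
    refs: dict[str, ReferenceSet] | ReferenceSet,
    observed_by_class: dict[str, dict[str, int]] | dict[str, int],
    observed_syn: int,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Spectrum-preserving permutation test for synonymous enrichment.

    ``observed_by_class`` maps genome -> class -> CDS substitution count
    (or class -> count for a single reference).  Each permutation places
    every substitution uniformly at random on a CDS site whose reference
    pair matches its class (placements independent), sums the synonymous
    outcomes across genomes, and the one-tailed p-value is the fraction
    of permutations with at least the observed synonymous count.
    """
    if isinstance(refs, ReferenceSet):
        refs = {refs.genome_id: refs}
        observed_by_class = {next(iter(refs)): observed_by_class}  # type: ignore[dict-item]
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = np.zeros(n_perm, dtype=np.int64)
    for gid, class_counts in observed_by_class.items():
        tables = _class_site_tables(refs[gid])
        for klass, count in class_counts.items():
            if count == 0:
                continue
            positions, syn = tables[klass]
            if len(positions) == 0:
                raise NoEligibleSiteError(
                    f"no eligible CDS site for class {klass} in {gid}"
                )
            draws = rng.integers(0, len(positions), size=(n_perm, count))
            totals += syn[draws].sum(axis=1)
    p = float(np.mean(totals >= observed_syn))
    return PermutationResult(
        observed_synonymous=observed_syn,
        n_perm=n_perm,
        p_value=p,
        null_mean=float(totals.mean()),
        null_sd=float(totals.std(ddof=1)) if n_perm > 1 else 0.0,
        null_counts=totals,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Poisson overdispersion

@dataclass
class DispersionResult:
    counts: np.ndarray
    mean: float
    variance: float
    statistic: float  # Cameron–Trivedi score statistic
    p_value: float  # one-sided, alternative: overdispersion
    statistic_aux: float  # auxiliary one-sample-t formulation
    p_value_aux: float


def dispersion_test(per_line_counts) -> DispersionResult:
    """Cameron–Trivedi score test of Poisson vs var = mean·(1+α), α > 0.

    z = Σ[(yᵢ−ȳ)² − yᵢ] / (ȳ·√(2n)), referred to a standard normal,
    one-sided.  The auxiliary formulation regresses
    ((yᵢ−ȳ)² − yᵢ)/ȳ on an intercept and reports its t statistic, for
    cross-checking.
    """
    y = np.asarray(per_line_counts, dtype=float)
    if y.size < 2:
        raise ValueError("need counts from at least two lines")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("all counts are zero; dispersion undefined")
    n = y.size
    aux = (y - ybar) ** 2 - y
    z = aux.sum() / (ybar * np.sqrt(2.0 * n))
    p = float(stats.norm.sf(z))
    scaled = aux / ybar
    se = scaled.std(ddof=1) / np.sqrt(n)
    t = float(scaled.mean() / se) if se > 0 else 0.0
    p_aux = float(stats.norm.sf(t))
    return DispersionResult(
        counts=y,
        mean=float(ybar),
        variance=float(y.var(ddof=1)),
        statistic=float(z),
        p_value=p,
        statistic_aux=t,
        p_value_aux=p_aux,
    )


# ---------------------------------------------------------------------------
# summaries

def genic_fraction_summary(variants, ref: ReferenceSet) -> dict[str, dict]:
    """Variant counts per feature class, with a synonymous sub-count for CDS."""
    from .genomes import classify_position

    counts = {c: 0 for c in ("CDS", "rRNA", "tRNA", "intron", "intergenic")}
    synonymous = 0
    for v in variants:
        if v.genome_id != ref.genome_id:
            continue
        feature = classify_position(ref, v.pos)
        counts[feature] += 1
        if feature == "CDS" and v.klass == "SNV":
            if synonymous_status(ref, v.pos, v.alt) == "synonymous":
                synonymous += 1
    total = sum(counts.values())
    genic = counts["CDS"] + counts["rRNA"] + counts["tRNA"]
    return {
        "counts": counts,
        "synonymous_CDS": synonymous,
        "total": total,
        "genic_fraction": genic / total if total else 0.0,
    }


def spectrum_summary(variants) -> dict:
    """Per-class counts and fractions over classified SNVs, with the
    transition fraction and GC-gaining vs GC-losing weighted sums."""
    counts = {c: 0 for c in MUTATION_CLASSES}
    gc_gain = 0.0
    gc_loss = 0.0
    for v in variants:
        if v.klass != "SNV":
            continue
        klass = classify_snv(v.ref, v.alt)
        counts[klass] += 1
        if klass in ("AT>GC", "AT>CG"):
            gc_gain += v.corrected_frequency
        elif klass in ("GC>AT", "GC>TA"):
            gc_loss += v.corrected_frequency
    total = sum(counts.values())
    fractions = {c: (n / total if total else 0.0) for c, n in counts.items()}
    transition_fraction = (
        (counts["AT>GC"] + counts["GC>AT"]) / total if total else 0.0
    )
    return {
        "counts": counts,
        "fractions": fractions,
        "total": total,
        "transition_fraction": transition_fraction,
        "gc_gaining_weight": gc_gain,
        "gc_losing_weight": gc_loss,
    }


def compare_count_groups(a, b, method: str = "poisson") -> dict:
    """Generic two-sample comparison of per-line mutation counts.

    ``poisson`` conditions on the total count and tests the split against
    the group-size expectation (binomial); ``t`` is Welch's t test;
    ``mannwhitney`` the rank test.  One utility, three conventional
    choices — the appropriate test for count panels this small is
    genuinely arguable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "poisson":
        total = int(a.sum() + b.sum())
        res = stats.binomtest(int(a.sum()), total, a.size / (a.size + b.size))
        p = res.pvalue
        statistic = float(a.sum())
    elif method == "t":
        statistic, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        statistic, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "method": method,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "statistic": float(statistic),
        "p_value": float(p),
    }
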