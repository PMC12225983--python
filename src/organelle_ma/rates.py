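"""Mutation-rate estimation for MA-line panels: μ = V / (G · N).

``V`` is the effective variant count — the sum of heteroplasmic
frequencies for SNVs (a variant at 40% frequency contributes 0.4 of a
mutation's worth of frequency mass), the unscaled count for indels
(homopolymer error makes indel frequencies unreliable); ``G`` is the
reduced genome length (large-repeat copies excluded); ``N`` is the total
number of homozygous generations summed over lines.

With zero observed mutations only an upper bound is available: the
smallest μ that would still have given a 95% chance of observing at
least one mutation under a Poisson model, μ = ln(1/0.05) / (G·N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genomes import ReferenceSet, base_pair_composition
from .selection import classify_snv


@dataclass
class RateEstimate:
    genome_id: str
    variant_class: str  # "SNV" | "indel"
    V: float
    G: int
    N: int
    mu: float
    mode: str  # weighted | unweighted | upper_bound | single_variant

    def __str__(self) -> str:
        return (
            f"{self.genome_id} {self.variant_class} mu = "
            f"{format_rate(self.mu)} per bp per generation "
            f"({self.mode}; V={self.V:g}, G={self.G}, N={self.N})"
        )


def format_rate(mu: float, sig: int = 2) -> str:
    """Scientific notation at ``sig`` significant figures, e.g. 4.8e-06."""
    if mu == 0:
        return "0"
    return f"{mu:.{sig - 1}e}"


def round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")


def total_generations(lines) -> int:
    """Sum of per-line homozygous generation counts (N)."""
    if not lines:
        raise ValueError("no lines")
    return int(sum(ln.generations for ln in lines))


def snv_rate(variants, G: int, N: int, use_corrected: bool = True) -> RateEstimate:
    """Frequency-weighted SNV rate.  MNVs count once, at their frequency.

    Mitochondrial frequencies are taken post numt correction by default.
    """
    if G <= 0 or N <= 0:
        raise ValueError("G and N must be positive")
    if variants:
        genome = variants[0].genome_id
    else:
        genome = "?"
    V = float(
        sum(
            (v.corrected_frequency if use_corrected else v.raw_frequency)
            for v in variants
            if v.klass in ("SNV", "MNV")
        )
    )
    return RateEstimate(genome, "SNV", V, G, N, V / (G * N), "weighted")


def indel_rate(indel_count: int, G: int, N: int, genome_id: str = "?") -> RateEstimate:
    """Unweighted indel rate from a raw count."""
    if G <= 0 or N <= 0:
        raise ValueError("G and N must be positive")
    mu = indel_count / (G * N)
    return RateEstimate(genome_id, "indel", float(indel_count), G, N, mu, "unweighted")


def wt_upper_bound(
    G: int, N: int, alpha: float = 0.05, genome_id: str = "?"
) -> RateEstimate:
    """Poisson zero-observation bound: μ = ln(1/alpha) / (G·N)."""
    if G <= 0 or N <= 0:
        raise ValueError("G and N must be positive")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    mu = math.log(1.0 / alpha) / (G * N)
    return RateEstimate(genome_id, "SNV", math.log(1.0 / alpha), G, N, mu, "upper_bound")


def single_variant_rate(G: int, N: int, genome_id: str = "?") -> RateEstimate:
    """The rate one homoplasmic variant would have implied: 1 / (G·N)."""
    if G <= 0 or N <= 0:
        raise ValueError("G and N must be positive")
    return RateEstimate(genome_id, "SNV", 1.0, G, N, 1.0 / (G * N), "single_variant")


def spectrum_rates(
    variants, ref: ReferenceSet, N: int, use_corrected: bool = True
) -> dict[str, float]:
    """Per-class rates normalised by the matching base-pair count.

    Each of the six strand-symmetric classes is weighted by frequency and
    divided by (AT pairs or GC pairs of the reduced genome) x N, so
    biased genome composition does not masquerade as mutation bias.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    at_pairs, gc_pairs = base_pair_composition(ref)
    sums: dict[str, float] = {
        c: 0.0 for c in
        ("AT>GC", "GC>AT", "AT>CG", "GC>TA", "AT>TA", "GC>CG")
    }
    for v in variants:
        if v.klass != "SNV":
            continue
        klass = classify_snv(v.ref, v.alt)
        sums[klass] += v.corrected_frequency if use_corrected else v.raw_frequency
    out = {}
    for klass, weighted in sums.items():
        pairs = at_pairs if klass.startswith("AT") else gc_pairs
        out[klass] = weighted / (pairs * N) if pairs else float("nan")
    return out
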