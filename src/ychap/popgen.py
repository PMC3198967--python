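"""Diversity and between-group distance statistics on haplotype tables.

Haplotype diversity here is the probability that two randomly drawn Y
chromosomes carry different haplotypes, h = 1 - sum(p_i^2); the
sample-size-corrected (n/(n-1)) form is available behind a flag but the
plain form is the default reporting convention.  The Dad statistic is
the per-motif absolute difference between two groups' individual-
weighted mean repeat counts; because microsatellite mutation rate
falls with motif length, Dad ordered mono > tri > penta is the
fingerprint of mutation accumulation rather than ancient divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .haplotypes import HaplotypeTable

__all__ = [
    "DiversityResult",
    "DadResult",
    "haplotype_diversity",
    "haplotypes_per_individual",
    "private_haplotypes",
    "dad_statistic",
    "mean_repeat_distance",
    "per_nucleotide_divergence",
    "divergence_ratio",
]

#: The three repeat motifs, longest to shortest, with the haplotype
#: attribute carrying each repeat count.
MOTIFS: Mapping[str, str] = {
    "penta": "penta_repeats",
    "tri": "tri_repeats",
    "mono": "mono_repeats",
}


@dataclass(frozen=True)
class DiversityResult:
    h: float
    n: int
    k: int
    estimator: str  # "biased" or "unbiased"


@dataclass(frozen=True)
class DadResult:
    """Per-motif |mean repeat difference| between two groups."""

    differences: Mapping[str, float]
    groups: tuple[str, str]

    @property
    def mean(self) -> float:
        return sum(self.differences.values()) / len(self.differences)


def haplotype_diversity(
    table: HaplotypeTable,
    group: str | Sequence[str] = "all",
    unbiased: bool = False,
) -> DiversityResult:
    """Haplotype diversity h = 1 - sum(p_i^2) within a group.

    With ``unbiased=True`` the estimate is multiplied by n/(n-1).
    """
    counts = table.group_counts(group)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n == 0:
        raise ValueError(f"empty group {group!r}")
    p = counts / n
    h = 1.0 - float((p**2).sum())
    if unbiased:
        if n < 2:
            raise ValueError("unbiased estimator requires n >= 2")
        h *= n / (n - 1)
    return DiversityResult(h=h, n=n, k=len(counts), estimator="unbiased" if unbiased else "biased")


def haplotypes_per_individual(table: HaplotypeTable, group: str | Sequence[str] = "all") -> float:
    """Average number of individuals per distinct haplotype, n/k."""
    counts = table.group_counts(group)
    k = int((counts > 0).sum())
    if k == 0:
        raise ValueError(f"empty group {group!r}")
    return float(counts.sum()) / k


def private_haplotypes(table: HaplotypeTable) -> dict[str, list[str]]:
    """Haplotype ids with nonzero count in exactly one species group."""
    groups = table.species
    if len(groups) < 2:
        raise ValueError("private haplotypes require at least two groups")
    presence = {g: table.group_counts(g) > 0 for g in groups}
    result: dict[str, list[str]] = {g: [] for g in groups}
    for hap_id in table.ids:
        present_in = [g for g in groups if bool(presence[g][hap_id])]
        if len(present_in) == 1:
            result[present_in[0]].append(hap_id)
    return result


def _mean_repeats(table: HaplotypeTable, group, attr: str) -> float:
    counts = table.group_counts(group)
    n = int(counts.sum())
    if n == 0:
        raise ValueError(f"empty group {group!r}")
    total = sum(getattr(h, attr) * int(counts[h.id]) for h in table.haplotypes)
    return total / n


def dad_statistic(
    table: HaplotypeTable,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
) -> DadResult:
    """Per-motif absolute difference of individual-weighted mean repeat
    counts between two groups (symmetric in group order)."""
    diffs = {
        motif: abs(_mean_repeats(table, group_a, attr) - _mean_repeats(table, group_b, attr))
        for motif, attr in MOTIFS.items()
    }
    name = lambda g: g if isinstance(g, str) else "+".join(g)  # noqa: E731
    return DadResult(differences=diffs, groups=(name(group_a), name(group_b)))


def mean_repeat_distance(
    table: HaplotypeTable,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
) -> float:
    """Mean over the three motifs of the per-motif Dad entries."""
    return dad_statistic(table, group_a, group_b).mean


def per_nucleotide_divergence(n_diffs: int, aln_len: int) -> float:
    """Observed substitutions per nucleotide, n_diffs / aln_len."""
    if aln_len <= 0:
        raise ValueError("alignment length must be positive")
    if not 0 <= n_diffs <= aln_len:
        raise ValueError("n_diffs must lie in [0, aln_len]")
    return n_diffs / aln_len


def divergence_ratio(reference_distance: float, value: float) -> float:
    """How many times larger a reference per-nucleotide distance is than
    the given one (e.g. mtDNA clade divergence vs Y-chromosome)."""
    if value <= 0:
        raise ValueError("divergence value must be positive")
    return reference_distance / value
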