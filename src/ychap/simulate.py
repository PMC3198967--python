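"""Synthetic data generators.

Two generators back the analysis:

``simulate_founder_chain`` produces composite Y haplotype tables under
the demographic scenario the method is designed to detect: a west-to-
east chain of haploid Wright-Fisher demes founded serially, each new
deme seeded by a small founder sample from the most recently founded
deme.  Microsatellites mutate by single repeat steps with motif-length-
dependent rates (mono >> tri > penta, penta about half of tri).  The
two SNP sites mutate at most once each (infinite-sites behaviour) and
their mutations enter during founder events: with a small probability
per colonization, one founder copy acquires the derived allele, which
then surfs eastward with the expansion front.  Placing SNP origins on
the front is what produces a genuine west-to-east cline of mean
derived-allele frequency; under strictly uniform mutation in space and
time the expected frequency profile of a neutral allele is flat (drift
is a martingale), and long-lived western demes would accumulate
local-only variants instead.  Between-end-deme repeat distances remain
ordered by motif mutability (mono > tri > penta).

``simulate_alignment`` evolves nucleotide sequences on a fixed tree
under the T92 substitution model with optional discrete-gamma rate
heterogeneity (5 categories), for distance-estimator consistency
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist
from skbio import TreeNode

import pandas as pd

from .haplotypes import CompositeHaplotype, HaplotypeTable
from .seqdist import Alignment, SubstitutionModelParams

__all__ = [
    "SimConfig",
    "SeqSimConfig",
    "ANCESTRAL_STATE",
    "simulate_founder_chain",
    "simulate_alignment",
    "t92_rate_matrix",
    "discrete_gamma_rates",
]

# column layout of the internal individual matrix
_PENTA, _TRI, _MONO, _SRY, _STR = range(5)

#: Ancestral composite haplotype of the chain: both SNPs in the
#: plesiomorphic A state, few repeats at every motif.
ANCESTRAL_STATE = np.array([6, 2, 9, 0, 0], dtype=np.int64)


@dataclass(frozen=True)
class SimConfig:
    """Serial-founder chain parameters.

    Microsatellite rates are per lineage per generation; defaults keep
    the mutability ordering mono >> tri > penta with penta = tri / 2.
    ``snp_rate`` is the probability, per site and per founding event,
    that one founder copy carries a new derived allele; the default
    gives about two derived SNP origins per 12-deme chain, the few-SNP
    regime the composite-haplotype method assumes.
    """

    n_demes: int = 12
    deme_size: int = 100
    founder_size: int = 10
    generations_per_stage: int = 50
    mu_mono: float = 5e-3
    mu_tri: float = 5e-4
    mu_penta: float = 2.5e-4
    snp_rate: float = 0.1
    up_bias: float = 0.0  # added to the 0.5 probability of a +1 step
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_mono", "mu_tri", "mu_penta", "snp_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.founder_size > self.deme_size:
            raise ValueError("founder_size cannot exceed deme_size")
        if not -0.5 <= self.up_bias <= 0.5:
            raise ValueError("up_bias must lie in [-0.5, 0.5]")
        if self.n_demes < 1 or self.deme_size < 1 or self.generations_per_stage < 0:
            raise ValueError("invalid demographic parameters")


def _mutate_strs(deme: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> None:
    """One generation of stepwise microsatellite mutation, in place."""
    n = deme.shape[0]
    for col, mu in ((_PENTA, cfg.mu_penta), (_TRI, cfg.mu_tri), (_MONO, cfg.mu_mono)):
        hits = rng.random(n) < mu
        if hits.any():
            steps = np.where(rng.random(int(hits.sum())) < 0.5 + cfg.up_bias, 1, -1)
            deme[hits, col] = np.maximum(deme[hits, col] + steps, 1)


def _mutate_founders(
    founders: np.ndarray, cfg: SimConfig, rng: np.random.Generator, snp_used: list[bool]
) -> None:
    """SNP origination at a founding event, in place.

    Each still-ancestral site acquires its one derived mutation on a
    random founder copy with probability ``snp_rate`` (allele surfing:
    variants born on the expansion front ride eastward with it)."""
    for site, col in enumerate((_SRY, _STR)):
        if snp_used[site]:
            continue
        if rng.random() < cfg.snp_rate:
            founders[rng.integers(0, founders.shape[0]), col] = 1
            snp_used[site] = True


def simulate_founder_chain(config: SimConfig | None = None) -> tuple[HaplotypeTable, dict]:
    """Evolve the deme chain and return (table, history).

    The table is in the composite-haplotype schema (ids H01, H02, ...;
    one count column per deme) and parses through the same pipeline as
    empirical tables.  ``history`` records the ancestral state, the
    founding order, and per-deme derived-SNP frequencies for cline
    tests.  Output is a deterministic function of the seed.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    snp_used = [False, False]

    demes: list[np.ndarray] = [np.tile(ANCESTRAL_STATE, (cfg.deme_size, 1))]
    founding_order = [0]
    for stage in range(cfg.n_demes):
        if stage > 0:
            source = demes[-1]
            founders = source[rng.choice(source.shape[0], cfg.founder_size, replace=False)].copy()
            _mutate_founders(founders, cfg, rng, snp_used)
            new = founders[rng.integers(0, cfg.founder_size, cfg.deme_size)].copy()
            demes.append(new)
            founding_order.append(stage)
        for _ in range(cfg.generations_per_stage):
            for deme in demes:
                resampled = deme[rng.integers(0, deme.shape[0], deme.shape[0])].copy()
                _mutate_strs(resampled, cfg, rng)
                deme[:] = resampled

    # collapse to a haplotype x deme count table
    deme_names = [f"deme{i + 1:02d}" for i in range(cfg.n_demes)]
    seen: dict[tuple, np.ndarray] = {}
    for d_idx, deme in enumerate(demes):
        rows, counts = np.unique(deme, axis=0, return_counts=True)
        for row, c in zip(rows, counts):
            key = tuple(int(x) for x in row)
            if key not in seen:
                seen[key] = np.zeros(cfg.n_demes, dtype=int)
            seen[key][d_idx] += int(c)

    ordered = sorted(seen)  # deterministic id assignment
    haplotypes = []
    count_rows = {}
    for i, key in enumerate(ordered):
        penta, tri, mono, sry, strs = key
        hap_id = f"H{i + 1:02d}"
        haplotypes.append(
            CompositeHaplotype(
                id=hap_id,
                sry_snp="G" if sry else "A",
                penta_repeats=penta,
                tri_repeats=tri,
                str_snp="T" if strs else "A",
                mono_repeats=mono,
            )
        )
        count_rows[hap_id] = seen[key]
    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=deme_names)
    counts.index.name = "id"
    table = HaplotypeTable(haplotypes, counts)

    history = {
        "ancestral": tuple(int(x) for x in ANCESTRAL_STATE),
        "founding_order": deme_names,
        "derived_freq": {
            name: {
                "sry_snp": float((demes[i][:, _SRY] == 1).mean()),
                "str_snp": float((demes[i][:, _STR] == 1).mean()),
            }
            for i, name in enumerate(deme_names)
        },
        "seed": cfg.seed,
    }
    return table, history


# ----------------------------------------------------------------------
# sequence evolution under T92 (+ discrete gamma)
# ----------------------------------------------------------------------

_BASES = "ACGT"


def t92_rate_matrix(params: SubstitutionModelParams) -> tuple[np.ndarray, np.ndarray]:
    """T92 instantaneous rate matrix (order ACGT) scaled to one expected
    substitution per unit branch length, and its stationary frequencies."""
    theta = params.theta
    pi = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    ts_sum = sum(pi[i] * pi[j] for i, j in transitions)
    tv_sum = sum(
        pi[i] * pi[j]
        for i in range(4)
        for j in range(4)
        if i != j and (i, j) not in transitions
    )
    ratio = params.ts_tv if params.ts_tv is not None else ts_sum / tv_sum  # default kappa=1
    alpha_over_beta = ratio * tv_sum / ts_sum
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = alpha_over_beta if (i, j) in transitions else 1.0
            q[i, j] = rate * pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(q)))
    return q / scale, pi


def discrete_gamma_rates(shape: float, n_categories: int = 5) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma categories
    (mean-one gamma with the given shape), normalized to average 1."""
    a = shape
    edges = gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), a, scale=1.0 / a)
    upper_cdf = gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
    rates = n_categories * np.diff(upper_cdf)
    return rates / rates.mean()


@dataclass(frozen=True)
class SeqSimConfig:
    """Tree, substitution model, sequence length and seed for one run."""

    tree: TreeNode
    params: SubstitutionModelParams
    length: int = 1000
    n_categories: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for node in self.tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                raise ValueError("every branch needs a nonnegative length")


def simulate_alignment(config: SeqSimConfig) -> Alignment:
    """Evolve sequences down the tree by per-site continuous-time T92
    substitution; site rates follow the discrete-gamma categories of the
    model (or are uniform when the shape is unset)."""
    rng = np.random.default_rng(config.seed)
    q, pi = t92_rate_matrix(config.params)
    if config.params.gamma_shape is None:
        rates = np.ones(1)
    else:
        rates = discrete_gamma_rates(config.params.gamma_shape, config.n_categories)
    site_cat = rng.integers(0, len(rates), size=config.length)
    root_seq = rng.choice(4, size=config.length, p=pi)

    leaves: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            transition = [expm(q * child.length * r) for r in rates]
            child_seq = seq.copy()
            for cat, P in enumerate(transition):
                for state in range(4):
                    sites = np.flatnonzero((site_cat == cat) & (seq == state))
                    if sites.size:
                        child_seq[sites] = rng.choice(4, size=sites.size, p=P[state])
            if child.is_tip():
                leaves[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(config.tree, root_seq)
    ids = [t.name for t in config.tree.tips()]
    seqs = ["".join(_BASES[s] for s in leaves[i]) for i in ids]
    return Alignment(tuple(ids), tuple(seqs))
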