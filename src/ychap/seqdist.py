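"""Alignment summaries and pairwise evolutionary distances.

Distances are computed after complete deletion of gap-containing
columns.  Two substitution models are provided: Jukes-Cantor and the
Tamura 3-parameter model (T92), which corrects for GC-content bias
(parameter theta) and distinguishes transitions from transversions;
an optional gamma shape parameter models rate heterogeneity across
sites.  With theta = 0.5 and no gamma, T92 reduces to Kimura's
2-parameter distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix

__all__ = [
    "Alignment",
    "PairwiseCounts",
    "SubstitutionModelParams",
    "SRY_T92G",
    "SaturationError",
    "strip_gap_columns",
    "alignment_summary",
    "pairwise_counts",
    "jc_distance",
    "t92_distance",
    "distance_matrix",
    "gc_content",
    "write_phylip",
]

_ALPHABET = frozenset("ACGTN-")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Raised when observed divergence exceeds a model's correctable range."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide sequences over {A,C,G,T,-,N}."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"{sid}: illegal characters {sorted(bad)}")

    @classmethod
    def from_sequences(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = zip(*((i, s.upper()) for i, s in pairs))
        return cls(tuple(ids), tuple(seqs))

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def as_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            len(self.ids), self.length
        )

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment(tuple(ids), tuple(self.sequence(i) for i in ids))

    def select_columns(self, idx: Sequence[int]) -> "Alignment":
        arr = self.as_array()[:, list(idx)]
        return Alignment(self.ids, tuple(row.tobytes().decode() for row in arr))


def strip_gap_columns(aln: Alignment) -> Alignment:
    """Drop every column containing at least one gap (complete deletion)."""
    arr = aln.as_array()
    keep = ~(arr == b"-").any(axis=0)
    if not keep.any():
        raise ValueError("no columns remain after gap-column elimination")
    return aln.select_columns(np.flatnonzero(keep))


def alignment_summary(aln: Alignment, ingroup: Sequence[str] | None = None) -> dict:
    """Per-column site classification.

    Returns total length, the number of variable columns, and the number
    of parsimony-informative columns (>= 2 states each carried by >= 2
    sequences).  If ``ingroup`` ids are given, variable columns are
    additionally split into those fixed within the ingroup (the
    difference lies against the remaining sequences) and those variable
    within the ingroup.  N and gap characters are treated as missing.
    """
    if len(aln) < 2:
        raise ValueError("alignment summary requires >= 2 sequences")
    arr = aln.as_array()
    ingroup_rows = None
    if ingroup is not None:
        ingroup_rows = [aln.ids.index(i) for i in ingroup]

    variable = informative = fixed_in = variable_in = 0
    for col in arr.T:
        states = [c for c in col.tobytes().decode() if c in "ACGT"]
        uniq = set(states)
        if len(uniq) > 1:
            variable += 1
            if sum(1 for s in uniq if states.count(s) >= 2) >= 2:
                informative += 1
            if ingroup_rows is not None:
                in_states = {
                    c
                    for c in (col[i].decode() for i in ingroup_rows)
                    if c in "ACGT"
                }
                if len(in_states) <= 1:
                    fixed_in += 1
                else:
                    variable_in += 1
    out = {
        "length": aln.length,
        "variable": variable,
        "parsimony_informative": informative,
    }
    if ingroup_rows is not None:
        out["fixed_in_ingroup"] = fixed_in
        out["variable_in_ingroup"] = variable_in
    return out


@dataclass(frozen=True)
class PairwiseCounts:
    """Site counts for one sequence pair after pairwise deletion."""

    L: int  # compared (both-determined) sites
    P: float  # transition proportion
    Q: float  # transversion proportion

    @property
    def p(self) -> float:
        return self.P + self.Q


def pairwise_counts(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Transition/transversion difference proportions for one pair.

    Sites where either sequence is not a determined base (N or gap) are
    excluded for this pair only (pairwise deletion).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    L = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        L += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if L == 0:
        raise ValueError("no comparable sites")
    return PairwiseCounts(L=L, P=ts / L, Q=tv / L)


@dataclass(frozen=True)
class SubstitutionModelParams:
    """T92 model parameters: GC content theta, transition/transversion
    ratio, and optional gamma shape for among-site rate variation."""

    theta: float
    ts_tv: float | None = None
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")


#: Parameters estimated for the SRY-promoter alignment of Caprinae:
#: equilibrium GC content 2 x 0.1608, Ts/Tv ratio 1.6281, gamma shape 0.4762.
SRY_T92G = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281, gamma_shape=0.4762)


def gc_content(aln: Alignment) -> float:
    """G+C frequency over all determined bases of the alignment."""
    arr = aln.as_array()
    gc = int(((arr == b"G") | (arr == b"C")).sum())
    acgt = int(np.isin(arr, [b"A", b"C", b"G", b"T"]).sum())
    if acgt == 0:
        raise ValueError("no determined bases")
    return gc / acgt


def jc_distance(counts: PairwiseCounts) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p)."""
    p = counts.p
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75: Jukes-Cantor distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _corrected_log(x: float, gamma_shape: float | None) -> float:
    """-ln(x), or its gamma-rates analogue a (x^(-1/a) - 1)."""
    if x <= 0:
        raise SaturationError("divergence beyond the model's correctable range")
    if gamma_shape is None:
        return -np.log(x)
    a = gamma_shape
    return a * (x ** (-1.0 / a) - 1.0)


def t92_distance(counts: PairwiseCounts, params: SubstitutionModelParams) -> float:
    """Tamura 3-parameter distance, optionally gamma-corrected.

    With h = 2 theta (1 - theta):
    d = h * C(1 - P/h - Q) + (1 - h)/2 * C(1 - 2Q)
    where C(x) = -ln(x) or, under gamma shape a, a (x^(-1/a) - 1).
    """
    h = 2.0 * params.theta * (1.0 - params.theta)
    term1 = 1.0 - counts.P / h - counts.Q
    term2 = 1.0 - 2.0 * counts.Q
    return h * _corrected_log(term1, params.gamma_shape) + 0.5 * (1.0 - h) * _corrected_log(
        term2, params.gamma_shape
    )


_MODELS = ("jc", "t92", "t92g")


def distance_matrix(
    aln: Alignment,
    model: str = "jc",
    params: SubstitutionModelParams | None = None,
) -> DistanceMatrix:
    """Pairwise model distances on a gap-stripped copy of the alignment."""
    model = model.lower().replace("+", "")
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    if len(aln) < 2:
        raise ValueError("distance matrix requires >= 2 sequences")
    aln = strip_gap_columns(aln)
    if model != "jc":
        if params is None:
            params = SubstitutionModelParams(theta=gc_content(aln))
        if model == "t92":
            params = SubstitutionModelParams(params.theta, params.ts_tv, None)
        elif params.gamma_shape is None:
            raise ValueError("t92g requires a gamma shape parameter")
    n = len(aln)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = pairwise_counts(aln.seqs[i], aln.seqs[j])
            if model == "jc":
                d = jc_distance(counts)
            else:
                d = t92_distance(counts, params)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=aln.ids)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for sid in dm.ids:
            row = "  ".join(f"{x:.6f}" for x in dm[sid])
            fh.write(f"{sid:<12}{row}\n")
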