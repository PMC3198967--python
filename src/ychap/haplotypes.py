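"""Composite Y-chromosome haplotypes and their character encoding.

A chamois Y-chromosome haplotype is the combination of allelic states
carried on the non-recombining male-specific region: one SNP in the SRY
gene promoter (A/G), the pentanucleotide [TTTTG] repeat count of the
UMN2303 microsatellite, and the SRYM18 microsatellite, which is a
compound locus made of a trinucleotide [TTC] motif, an internal SNP
(A/T) and a mononucleotide [T] motif.  Because the segment is inherited
as a unit, the five characters form a single haplotype.

This module defines the haplotype and table containers, the character
scheme used to weight the five characters by mutability, and the
affine calibration between electrophoretic allele sizes (bp) and repeat
counts.  SRYM18 exhibits homoplasy: different (tri, mono) repeat
decompositions can yield the same PCR fragment size, which is why the
calibration is per structural variant and why ``size_to_repeats`` for
SRYM18 requires the sequenced trinucleotide count.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CompositeHaplotype",
    "Character",
    "CharacterScheme",
    "SizeCalibration",
    "HaplotypeTable",
    "load_haplotype_table",
    "load_table2",
    "character_matrix",
    "CANONICAL_SUBPOPS",
]

_SRY_STATES = frozenset("AG")
_STR_SNP_STATES = frozenset("AT")

#: The 12 sampled subpopulations, west to east, with their species.
CANONICAL_SUBPOPS: "pd.DataFrame" = pd.DataFrame(
    {
        "species": ["pyrenaica"] * 3 + ["rupicapra"] * 9,
        "rank": range(1, 13),
    },
    index=pd.Index(
        ["par", "pyr", "orn", "cat", "rupW", "rupC", "rupE", "tat", "cap", "bal", "asi", "cau"],
        name="subpop",
    ),
)


@dataclass(frozen=True)
class CompositeHaplotype:
    """One Y lineage state: SRY SNP + three STR repeat counts + STR SNP."""

    id: str
    sry_snp: str
    penta_repeats: int
    tri_repeats: int
    str_snp: str
    mono_repeats: int

    def __post_init__(self) -> None:
        if self.sry_snp not in _SRY_STATES:
            raise ValueError(f"{self.id}: SRY promoter SNP must be A or G, got {self.sry_snp!r}")
        if self.str_snp not in _STR_SNP_STATES:
            raise ValueError(f"{self.id}: SRYM18 SNP must be A or T, got {self.str_snp!r}")
        for name in ("penta_repeats", "tri_repeats", "mono_repeats"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{self.id}: {name} must be an integer, got {value!r}")
            if value < 1:
                raise ValueError(f"{self.id}: {name} must be >= 1, got {value}")

    @property
    def structure(self) -> str:
        """SRYM18 structural variant implied by the internal SNP."""
        return "TTC-A-T" if self.str_snp == "A" else "TTC-T"


@dataclass(frozen=True)
class Character:
    name: str
    kind: str  # "binary" or "ordered"
    weight: float

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordered"):
            raise ValueError(f"character kind must be 'binary' or 'ordered', got {self.kind!r}")
        if not self.weight > 0:
            raise ValueError(f"character weight must be positive, got {self.weight}")


# Attribute on CompositeHaplotype backing each character name.
_CHAR_ATTR = {
    "sry_snp": "sry_snp",
    "str_snp": "str_snp",
    "penta": "penta_repeats",
    "tri": "tri_repeats",
    "mono": "mono_repeats",
}

# Reference (ancestral, plesiomorphic) states for the binary characters:
# the western haplogroup carries A at both SNPs, shared with the outgroups.
_BINARY_REFERENCE = {"sry_snp": "A", "str_snp": "A"}


@dataclass(frozen=True)
class CharacterScheme:
    """Ordered characters with mutability weights.

    The default weights follow the mutability ordering of the motifs:
    the fast mononucleotide gets w=1, the trinucleotide w=2, the slow
    pentanucleotide w=3, and the two essentially unique SNPs w=4.
    """

    characters: tuple[Character, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.characters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate character names in scheme")
        unknown = set(names) - set(_CHAR_ATTR)
        if unknown:
            raise ValueError(f"unknown characters: {sorted(unknown)}")

    @classmethod
    def default(cls) -> "CharacterScheme":
        return cls(
            (
                Character("sry_snp", "binary", 4.0),
                Character("str_snp", "binary", 4.0),
                Character("penta", "ordered", 3.0),
                Character("tri", "ordered", 2.0),
                Character("mono", "ordered", 1.0),
            )
        )

    @classmethod
    def microsatellites_only(cls) -> "CharacterScheme":
        """The three repeat motifs without the SNP characters."""
        return cls(tuple(c for c in cls.default().characters if c.kind == "ordered"))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.characters)

    def states(self, hap: CompositeHaplotype) -> tuple:
        """The haplotype's state vector in scheme order."""
        return tuple(getattr(hap, _CHAR_ATTR[c.name]) for c in self.characters)


class SizeCalibration:
    """Affine maps between allele size (bp) and repeat counts.

    UMN2303: size = offset + 5 * penta_repeats.

    SRYM18:  size = offset(structure) + 3 * tri_repeats + mono_repeats,
    where the structure is [TTC]mA[T]n (western type, internal A counted
    inside the offset) or [TTC]m[T]n (eastern type).  The two structural
    offsets are fitted independently because the flanking lengths differ
    once the internal nucleotide is accounted for.
    """

    def __init__(
        self,
        umn2303_offset: int = 95,
        srym18_offsets: Mapping[str, int] | None = None,
    ) -> None:
        self.umn2303_offset = umn2303_offset
        self.srym18_offsets = dict(srym18_offsets or {"TTC-A-T": 87, "TTC-T": 87})

    # -- UMN2303 ------------------------------------------------------
    def penta_from_size(self, size: int) -> int:
        delta = size - self.umn2303_offset
        if delta <= 0 or delta % 5:
            raise ValueError(
                f"UMN2303 size {size} is not congruent with a [TTTTG]n array at offset "
                f"{self.umn2303_offset}"
            )
        return delta // 5

    def size_from_penta(self, repeats: int) -> int:
        return self.umn2303_offset + 5 * repeats

    # -- SRYM18 -------------------------------------------------------
    def mono_from_size(self, size: int, tri: int, structure: str) -> int:
        offset = self.srym18_offsets[structure]
        mono = size - offset - 3 * tri
        if mono < 1:
            raise ValueError(
                f"SRYM18 size {size} incompatible with [TTC]{tri} under structure {structure}"
            )
        return mono

    def srym18_size(self, tri: int, mono: int, structure: str) -> int:
        return self.srym18_offsets[structure] + 3 * tri + mono

    # -- generic ------------------------------------------------------
    def size_to_repeats(
        self, locus: str, size: int, structure: str | None = None, tri: int | None = None
    ) -> int:
        """Repeat count encoded by an allele size.

        For UMN2303 this is the pentanucleotide count.  For SRYM18,
        size alone is ambiguous (homoplasy), so the sequenced
        trinucleotide count must be supplied and the mononucleotide
        count is returned.
        """
        if locus == "UMN2303":
            return self.penta_from_size(size)
        if locus == "SRYM18":
            if structure is None or tri is None:
                raise ValueError("SRYM18 requires structure and tri (homoplasic locus)")
            return self.mono_from_size(size, tri, structure)
        raise KeyError(f"no calibration for locus {locus!r}")

    def repeats_to_size(
        self, locus: str, repeats: int, structure: str | None = None, tri: int | None = None
    ) -> int:
        if locus == "UMN2303":
            return self.size_from_penta(repeats)
        if locus == "SRYM18":
            if structure is None or tri is None:
                raise ValueError("SRYM18 requires structure and tri")
            return self.srym18_size(tri, repeats, structure)
        raise KeyError(f"no calibration for locus {locus!r}")


@dataclass
class HaplotypeTable:
    """Haplotype-by-subpopulation count matrix with a species partition."""

    haplotypes: list[CompositeHaplotype]
    counts: pd.DataFrame  # index: haplotype id, columns: subpops, ints
    subpop_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [h.id for h in self.haplotypes]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate haplotype ids: {dupes}")
        self.counts = self.counts.loc[ids].astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative haplotype counts")
        if self.counts.to_numpy().sum() == 0:
            raise ValueError("empty count matrix: no individuals")
        if self.subpop_meta is None:
            self.subpop_meta = _default_meta(list(self.counts.columns))
        missing = set(self.counts.columns) - set(self.subpop_meta.index)
        if missing:
            raise ValueError(f"subpopulations without metadata: {sorted(missing)}")

    # -- basic summaries ---------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [h.id for h in self.haplotypes]

    @property
    def n(self) -> int:
        """Total number of sampled individuals."""
        return int(self.counts.to_numpy().sum())

    @property
    def k(self) -> int:
        """Number of distinct haplotypes with nonzero count."""
        return int((self.counts.sum(axis=1) > 0).sum())

    @property
    def species(self) -> list[str]:
        return sorted(self.subpop_meta["species"].unique())

    def haplotype(self, hap_id: str) -> CompositeHaplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    # -- grouping -----------------------------------------------------
    def group_columns(self, group: str | Sequence[str]) -> list[str]:
        """Resolve a group selector to subpopulation columns.

        Accepts ``"all"``, a species label, a single subpopulation
        label, or an explicit sequence of subpopulation labels.
        """
        if isinstance(group, str):
            if group == "all":
                return list(self.counts.columns)
            if group in set(self.subpop_meta["species"]):
                cols = self.subpop_meta.index[self.subpop_meta["species"] == group]
                return [c for c in self.counts.columns if c in set(cols)]
            if group in self.counts.columns:
                return [group]
            raise KeyError(f"unknown group {group!r}")
        cols = list(group)
        unknown = set(cols) - set(self.counts.columns)
        if unknown:
            raise KeyError(f"unknown subpopulations {sorted(unknown)}")
        return cols

    def group_counts(self, group: str | Sequence[str] = "all") -> pd.Series:
        """Per-haplotype counts pooled over the selected subpopulations."""
        return self.counts[self.group_columns(group)].sum(axis=1)

    # -- io -----------------------------------------------------------
    def to_tsv(self, path, calibration: SizeCalibration | None = None) -> None:
        cal = calibration or SizeCalibration()
        cols = list(self.counts.columns)
        with open(path, "w") as fh:
            fh.write(
                "# id\tsry_snp\tumn2303_size\tsrym18_size\ttri\tstr_snp\tmono\t"
                + "\t".join(cols)
                + "\n"
            )
            for h in self.haplotypes:
                row = [
                    h.id,
                    h.sry_snp,
                    str(cal.size_from_penta(h.penta_repeats)),
                    str(cal.srym18_size(h.tri_repeats, h.mono_repeats, h.structure)),
                    str(h.tri_repeats),
                    h.str_snp,
                    str(h.mono_repeats),
                ] + [str(int(self.counts.at[h.id, c])) for c in cols]
                fh.write("\t".join(row) + "\n")


def _default_meta(subpops: list[str]) -> pd.DataFrame:
    """Canonical metadata when the columns are the 12 known subpopulations,
    else each subpopulation forms its own group in column order."""
    if set(subpops) <= set(CANONICAL_SUBPOPS.index):
        return CANONICAL_SUBPOPS.loc[[s for s in CANONICAL_SUBPOPS.index if s in subpops]].copy()
    return pd.DataFrame(
        {"species": subpops, "rank": range(1, len(subpops) + 1)},
        index=pd.Index(subpops, name="subpop"),
    )


_CELL_RE = re.compile(r"^\s*(\d+)\s*(?:\(\s*\d+\s*\))?\s*$")

_DEF_COLS = ["id", "sry_snp", "umn2303_size", "srym18_size", "tri", "str_snp", "mono"]


def _parse_count(cell: str) -> int:
    """Leading count of a table cell; parenthesized sub-counts ignored."""
    cell = cell.strip()
    if not cell:
        return 0
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"cannot parse count cell {cell!r}")
    return int(m.group(1))


def load_haplotype_table(
    path,
    calibration: SizeCalibration | None = None,
    subpop_meta: pd.DataFrame | None = None,
) -> HaplotypeTable:
    """Parse a tab-separated haplotype table.

    Expected columns: ``id sry_snp umn2303_size srym18_size tri str_snp
    mono`` followed by one count column per subpopulation.  Count cells
    may carry parenthesized sampling-site sub-counts, which are ignored.
    Repeat counts for UMN2303 are derived from allele size through the
    calibration; SRYM18 sizes are validated against the (tri, mono)
    decomposition.
    """
    cal = calibration or SizeCalibration()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].lstrip("#").strip().split("\t")
    header = [h.strip() for h in header]
    if header[: len(_DEF_COLS)] != _DEF_COLS:
        raise ValueError(f"header must start with {_DEF_COLS}, got {header[:7]}")
    subpops = header[len(_DEF_COLS) :]
    if not subpops:
        raise ValueError("no subpopulation columns")

    haplotypes: list[CompositeHaplotype] = []
    rows: dict[str, list[int]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"row has {len(fields)} fields, expected {len(header)}: {ln!r}")
        hap_id, sry, u_size, s_size, tri, str_snp, mono = fields[:7]
        if hap_id in rows:
            raise ValueError(f"duplicate haplotype ids: ['{hap_id}']")
        tri_i, mono_i = int(tri), int(mono)
        structure = "TTC-A-T" if str_snp == "A" else "TTC-T"
        penta = cal.penta_from_size(int(u_size))
        expected = cal.srym18_size(tri_i, mono_i, structure)
        if expected != int(s_size):
            raise ValueError(
                f"{hap_id}: SRYM18 size {s_size} inconsistent with tri={tri_i}, mono={mono_i} "
                f"(calibration gives {expected})"
            )
        haplotypes.append(
            CompositeHaplotype(
                id=hap_id,
                sry_snp=sry,
                penta_repeats=penta,
                tri_repeats=tri_i,
                str_snp=str_snp,
                mono_repeats=mono_i,
            )
        )
        rows[hap_id] = [_parse_count(c) for c in fields[7:]]

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=subpops)
    counts.index.name = "id"
    return HaplotypeTable(haplotypes, counts, subpop_meta)


def load_table2() -> HaplotypeTable:
    """The packaged 10-haplotype, 12-subpopulation, 87-male count table."""
    with resources.as_file(resources.files("ychap.data") / "table2.tsv") as p:
        return load_haplotype_table(p)


def character_matrix(table: HaplotypeTable, scheme: CharacterScheme | None = None) -> pd.DataFrame:
    """Haplotype-by-character state matrix.

    Binary characters are coded 0 for the ancestral (western/outgroup)
    state and 1 for the derived state; ordered characters carry raw
    repeat counts.
    """
    scheme = scheme or CharacterScheme.default()
    data = {}
    for ch in scheme.characters:
        col = []
        for h in table.haplotypes:
            state = getattr(h, _CHAR_ATTR[ch.name])
            if ch.kind == "binary":
                col.append(0 if state == _BINARY_REFERENCE[ch.name] else 1)
            else:
                col.append(int(state))
        data[ch.name] = col
    return pd.DataFrame(data, index=pd.Index(table.ids, name="id"))
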