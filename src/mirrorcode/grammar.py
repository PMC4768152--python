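"""CARC/CRAC residue-class grammars and exhaustive motif enumeration.

Both cholesterol-recognition motifs are linear triads of anchor residues
separated by short unconstrained spacers:

* CARC, read N->C:  basic (K/R) - X(1-5) - aromatic (F/Y/W) - X(1-5) - aliphatic (L/V)
* CRAC, read N->C:  aliphatic (L/V) - X(1-5) - aromatic (Y/F) - X(1-5) - basic (K/R)

The two consensus sequences are mirror images of one another, which is what
lets a single transmembrane helix present one motif to each membrane leaflet.
Spacer positions are entirely unconstrained: any character (including letters
that belong to an anchor class, or ambiguity codes) may sit between anchors.
Only the three anchor positions are class-checked.

Coordinates are 1-based inclusive throughout (UniProt convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "MotifKind",
    "ResidueClassTable",
    "MotifMatch",
    "classify_residue",
    "enumerate_matches",
    "select_maximal",
]

#: Anchor roles, in the order CARC reads them (CRAC reads them reversed).
ROLES = ("basic", "aromatic", "aliphatic")


class MotifKind(str, enum.Enum):
    """Motif direction: which anchor class comes first in N->C order."""

    CARC = "CARC"  # basic -> aromatic -> aliphatic
    CRAC = "CRAC"  # aliphatic -> aromatic -> basic

    @property
    def role_order(self) -> tuple[str, str, str]:
        if self is MotifKind.CARC:
            return ("basic", "aromatic", "aliphatic")
        return ("aliphatic", "aromatic", "basic")


@dataclass(frozen=True)
class ResidueClassTable:
    """Residue classes and spacer bounds for one pattern evaluation.

    Defaults follow the consensus definitions: basic {K,R}; aromatic {F,Y,W}
    for CARC but {Y,F} for CRAC (the original CRAC algorithm used Tyr only,
    available via ``strict_crac``); aliphatic {L,V}, optionally including Ile.
    """

    basic: frozenset[str] = frozenset("KR")
    aromatic_carc: frozenset[str] = frozenset("FYW")
    aromatic_crac: frozenset[str] = frozenset("YF")
    aliphatic: frozenset[str] = frozenset("LV")
    spacer_min: int = 1
    spacer_max: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.spacer_min <= self.spacer_max):
            raise ValueError(
                f"require 1 <= spacer_min <= spacer_max, got "
                f"[{self.spacer_min}, {self.spacer_max}]"
            )
        for arom in (self.aromatic_carc, self.aromatic_crac):
            overlapping = (self.basic & arom) | (self.basic & self.aliphatic) | (
                arom & self.aliphatic
            )
            if overlapping:
                raise ValueError(f"anchor classes overlap on {sorted(overlapping)}")

    @classmethod
    def configured(
        cls,
        *,
        allow_ile: bool = False,
        strict_crac: bool = False,
        spacer_min: int = 1,
        spacer_max: int = 5,
    ) -> "ResidueClassTable":
        """Build a table from the two documented relaxation switches.

        ``allow_ile`` admits Ile as an aliphatic anchor (branched aliphatics
        Leu/Val/Ile all pack well against the cholesterol methyl groups, but
        the consensus as usually written says L/V). ``strict_crac`` restricts
        the CRAC aromatic to Tyr only, the original literal algorithm.
        """
        return cls(
            aliphatic=frozenset("LVI") if allow_ile else frozenset("LV"),
            aromatic_crac=frozenset("Y") if strict_crac else frozenset("YF"),
            spacer_min=spacer_min,
            spacer_max=spacer_max,
        )

    def anchor_set(self, role: str, kind: MotifKind) -> frozenset[str]:
        if role == "basic":
            return self.basic
        if role == "aromatic":
            return self.aromatic_carc if kind is MotifKind.CARC else self.aromatic_crac
        if role == "aliphatic":
            return self.aliphatic
        raise ValueError(f"unknown anchor role: {role!r}")


DEFAULT_TABLE = ResidueClassTable()


@dataclass(frozen=True, order=True)
class MotifMatch:
    """One located motif: anchor triad plus derived span.

    ``start``/``end`` are the outermost anchors, 1-based inclusive.  The sort
    order (start, aromatic, end) is the deterministic report order.
    """

    start: int
    pos_aromatic: int
    end: int
    pos_basic: int = field(compare=False)
    pos_aliphatic: int = field(compare=False)
    kind: MotifKind = field(compare=False)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def anchors(self) -> tuple[int, int, int]:
        """Anchor positions in N->C order."""
        return (self.start, self.pos_aromatic, self.end)

    def overlaps(self, other: "MotifMatch") -> bool:
        return self.start <= other.end and other.start <= self.end

    @classmethod
    def from_anchors(
        cls, kind: MotifKind, first: int, aromatic: int, last: int
    ) -> "MotifMatch":
        if kind is MotifKind.CARC:
            basic, aliphatic = first, last
        else:
            aliphatic, basic = first, last
        return cls(
            start=first,
            pos_aromatic=aromatic,
            end=last,
            pos_basic=basic,
            pos_aliphatic=aliphatic,
            kind=kind,
        )


def classify_residue(
    code: str,
    role: str,
    table: ResidueClassTable = DEFAULT_TABLE,
    kind: MotifKind = MotifKind.CARC,
) -> bool:
    """True iff ``code`` can serve as the given anchor role for ``kind``.

    Note the asymmetry between kinds: Trp is an admissible CARC aromatic but
    not a CRAC one.
    """
    if role not in ROLES:
        raise ValueError(f"unknown anchor role: {role!r}")
    return code.upper() in table.anchor_set(role, kind)


def _clean(sequence: str) -> str:
    return "".join(sequence.split()).upper()


def enumerate_matches(
    sequence: str,
    kind: MotifKind,
    offset: int = 1,
    table: ResidueClassTable = DEFAULT_TABLE,
) -> list[MotifMatch]:
    """Enumerate ALL anchor triads satisfying the grammar (overlaps allowed).

    Every combination of three positions whose residues fit the kind's anchor
    classes in order, with both spacer gaps inside ``[spacer_min, spacer_max]``,
    is reported.  Coordinates are 1-based with the first residue of
    ``sequence`` at ``offset``.  Ordering is deterministic: by start, then
    aromatic position, then end.
    """
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    seq = _clean(sequence)
    n = len(seq)
    if n == 0:
        return []

    first_role, _, last_role = kind.role_order
    first_set = table.anchor_set(first_role, kind)
    arom_set = table.anchor_set("aromatic", kind)
    last_set = table.anchor_set(last_role, kind)
    lo, hi = table.spacer_min, table.spacer_max

    out: list[MotifMatch] = []
    for i in range(n):
        if seq[i] not in first_set:
            continue
        for j in range(i + lo + 1, min(i + hi + 2, n)):
            if seq[j] not in arom_set:
                continue
            for k in range(j + lo + 1, min(j + hi + 2, n)):
                if seq[k] not in last_set:
                    continue
                out.append(
                    MotifMatch.from_anchors(
                        kind, i + offset, j + offset, k + offset
                    )
                )
    out.sort()
    return out


def select_maximal(matches: Sequence[MotifMatch]) -> list[MotifMatch]:
    """Reduce overlapping matches to one largest-span representative each.

    Matches are clustered transitively by residue overlap; from every cluster
    the match with the greatest span survives, ties broken by smallest start,
    then smallest aromatic position.  This implements the reporting rule that
    when several overlapping motifs exist, the largest possible sequence is
    selected.
    """
    if not matches:
        return []
    kinds = {m.kind for m in matches}
    if len(kinds) > 1:
        raise ValueError(f"select_maximal requires a single motif kind, got {kinds}")

    ordered = sorted(matches)
    clusters: list[list[MotifMatch]] = [[ordered[0]]]
    reach = ordered[0].end
    for m in ordered[1:]:
        if m.start <= reach:  # shares >= 1 residue with the running cluster
            clusters[-1].append(m)
        else:
            clusters.append([m])
        reach = max(reach, m.end)

    return [
        min(cluster, key=lambda m: (-m.span, m.start, m.pos_aromatic))
        for cluster in clusters
    ]
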