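"""Membrane topology: TM orientation, boundary extension, leaflet assignment.

The motif grammars are vectorial, so which membrane leaflet a motif serves is
decided by protein topology.  For a protein whose N-terminus is extracellular
(type I single-pass proteins; TM 1/3/5/7 of a GPCR) the odd-numbered TM
segments enter the membrane from the outside, so their N-terminal half sits in
the outer (exofacial) leaflet; even-numbered segments are reversed, and the
whole pattern flips for a cytoplasmic N-terminus.

Database TM boundaries routinely stop short of the interfacial Lys/Arg
residues (which snorkel toward the polar headgroup region), so segments are
extended outward to the outermost basic residue found within a small window
before scanning.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .grammar import MotifKind, MotifMatch

__all__ = [
    "Leaflet",
    "NTermLocation",
    "TMSegment",
    "OrientedTM",
    "TMStatus",
    "LocatedMotif",
    "TMClassification",
    "orient_tm_segments",
    "extend_tm",
    "assign_leaflet",
    "classify_tm",
]


class Leaflet(str, enum.Enum):
    OUTER = "outer"
    INNER = "inner"

    @property
    def opposite(self) -> "Leaflet":
        return Leaflet.INNER if self is Leaflet.OUTER else Leaflet.OUTER


class NTermLocation(str, enum.Enum):
    EXTRACELLULAR = "extracellular"
    CYTOPLASMIC = "cytoplasmic"


@dataclass(frozen=True)
class TMSegment:
    """One annotated membrane-spanning segment, 1-based inclusive."""

    index: int  # ordinal along the sequence, 1-based
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"TM index must be >= 1, got {self.index}")
        if not (1 <= self.start < self.end):
            raise ValueError(
                f"TM{self.index}: require 1 <= start < end, got {self.start}-{self.end}"
            )


@dataclass(frozen=True)
class OrientedTM:
    """A TM segment with extended boundaries and membrane orientation.

    ``n_end_faces`` names the leaflet adjacent to the segment's N-terminal
    end.  ``midpoint`` splits the extended segment into the two leaflet
    halves: positions <= midpoint belong to the N-terminal half.
    """

    segment: TMSegment
    extended_start: int
    extended_end: int
    n_end_faces: Leaflet

    def __post_init__(self) -> None:
        if self.extended_start > self.segment.start or self.extended_end < self.segment.end:
            raise ValueError("extended boundaries must contain the annotated segment")

    @property
    def index(self) -> int:
        return self.segment.index

    @property
    def midpoint(self) -> int:
        return (self.extended_start + self.extended_end) // 2

    def contains(self, position: int) -> bool:
        return self.extended_start <= position <= self.extended_end

    def leaflet_of(self, position: int) -> Leaflet:
        """Leaflet of the TM half containing ``position``."""
        if not self.contains(position):
            raise ValueError(
                f"position {position} outside extended TM{self.index} "
                f"[{self.extended_start}, {self.extended_end}]"
            )
        in_n_half = position <= self.midpoint
        return self.n_end_faces if in_n_half else self.n_end_faces.opposite


def _validate_segments(segments: Sequence[TMSegment]) -> None:
    for prev, cur in zip(segments, segments[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"TM segments overlap or are unsorted: "
                f"TM{prev.index} {prev.start}-{prev.end} vs TM{cur.index} {cur.start}-{cur.end}"
            )


def orient_tm_segments(
    n_term_location: NTermLocation, segments: Sequence[TMSegment]
) -> list[OrientedTM]:
    """Assign each TM the leaflet its N-terminal end faces.

    Orientation alternates with segment parity: with an extracellular
    N-terminus, odd-indexed segments run outside-to-inside (N end faces the
    outer leaflet) and even-indexed ones the reverse; a cytoplasmic N-terminus
    flips the whole assignment.  Boundaries are left unextended here
    (extended == annotated); see :func:`extend_tm`.
    """
    segments = sorted(segments, key=lambda s: s.start)
    _validate_segments(segments)
    odd_faces = (
        Leaflet.OUTER
        if n_term_location is NTermLocation.EXTRACELLULAR
        else Leaflet.INNER
    )
    oriented = []
    for seg in segments:
        faces = odd_faces if seg.index % 2 == 1 else odd_faces.opposite
        oriented.append(
            OrientedTM(
                segment=seg,
                extended_start=seg.start,
                extended_end=seg.end,
                n_end_faces=faces,
            )
        )
    return oriented


def extend_tm(
    sequence: str,
    tm: TMSegment,
    window: int,
    *,
    basic: frozenset[str] = frozenset("KR"),
    previous_end: Optional[int] = None,
    next_start: Optional[int] = None,
) -> tuple[int, int]:
    """Extend TM boundaries outward to interfacial basic residues.

    Looks up to ``window`` residues upstream of ``start`` (and downstream of
    ``end``) for Lys/Arg; the boundary moves to the outermost basic residue
    found, else stays put.  The extension never runs past sequence bounds nor
    into a neighbouring annotated TM (``previous_end`` / ``next_start``,
    clipped one residue short).
    Returns ``(extended_start, extended_end)``.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    n = len(sequence)
    if tm.end > n:
        raise ValueError(f"TM{tm.index} {tm.start}-{tm.end} outside sequence of length {n}")

    lo_limit = 1 if previous_end is None else previous_end + 1
    hi_limit = n if next_start is None else next_start - 1

    ext_start = tm.start
    for pos in range(max(tm.start - window, lo_limit), tm.start):
        if sequence[pos - 1] in basic:
            ext_start = pos
            break  # outermost (farthest upstream) basic wins

    ext_end = tm.end
    for pos in range(min(tm.end + window, hi_limit), tm.end, -1):
        if sequence[pos - 1] in basic:
            ext_end = pos
            break
    return ext_start, ext_end


def assign_leaflet(match: MotifMatch, tm: OrientedTM) -> Leaflet:
    """Leaflet served by a motif: the half holding its basic anchor.

    The basic anchor (not the motif midpoint) decides, because the Lys/Arg
    end of the motif is the part that must reach the aqueous interface while
    the aliphatic end buries into the bilayer core.
    """
    if not (tm.contains(match.start) and tm.contains(match.end)):
        raise ValueError(
            f"motif {match.start}-{match.end} outside extended TM{tm.index} "
            f"[{tm.extended_start}, {tm.extended_end}]"
        )
    return tm.leaflet_of(match.pos_basic)


class TMStatus(str, enum.Enum):
    DUAL_MIRROR = "dual_mirror"
    CARC_ONLY = "carc_only"
    CRAC_ONLY = "crac_only"
    NONE = "none"


@dataclass(frozen=True)
class LocatedMotif:
    """A motif match with its leaflet label and maximal-representative flag."""

    match: MotifMatch
    leaflet: Leaflet
    maximal: bool = True

    @property
    def kind(self) -> MotifKind:
        return self.match.kind


@dataclass(frozen=True)
class TMClassification:
    tm_index: int
    status: TMStatus
    motifs: tuple[LocatedMotif, ...]
    # both kinds present but in the same leaflet: not a mirror pair
    same_leaflet_pair: bool = False
    # one residue anchoring two overlapping motifs of different kinds
    shared_anchor: bool = False


def classify_tm(
    carc_motifs: Sequence[LocatedMotif],
    crac_motifs: Sequence[LocatedMotif],
    tm: OrientedTM,
) -> TMClassification:
    """Classify a TM from its leaflet-labelled motifs.

    ``dual_mirror`` requires at least one CARC and one CRAC in *opposite*
    leaflets of the segment — the geometry that lets two tail-to-tail
    cholesterol molecules bind, one per leaflet.  A CARC/CRAC pair sharing a
    leaflet is not a mirror pair and is flagged separately.
    """
    for lm in list(carc_motifs) + list(crac_motifs):
        if not tm.contains(lm.match.pos_basic):
            raise ValueError(
                f"motif anchor {lm.match.pos_basic} outside extended TM{tm.index}"
            )
    carc_leaflets = {lm.leaflet for lm in carc_motifs}
    crac_leaflets = {lm.leaflet for lm in crac_motifs}

    same_leaflet_pair = False
    if carc_motifs and crac_motifs:
        if any(l.opposite in crac_leaflets for l in carc_leaflets):
            status = TMStatus.DUAL_MIRROR
        else:
            status = TMStatus.NONE
            same_leaflet_pair = True
    elif carc_motifs:
        status = TMStatus.CARC_ONLY
    elif crac_motifs:
        status = TMStatus.CRAC_ONLY
    else:
        status = TMStatus.NONE

    carc_anchor_positions = {
        p for lm in carc_motifs for p in lm.match.anchors
    }
    shared = any(
        p in carc_anchor_positions for lm in crac_motifs for p in lm.match.anchors
    )

    motifs = tuple(
        sorted(list(carc_motifs) + list(crac_motifs), key=lambda lm: lm.match)
    )
    return TMClassification(
        tm_index=tm.index,
        status=status,
        motifs=motifs,
        same_leaflet_pair=same_leaflet_pair,
        shared_anchor=shared,
    )
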