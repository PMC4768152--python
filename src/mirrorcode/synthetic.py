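"""Synthetic membrane proteins with planted motifs, and shuffle nulls.

The generator builds alternating loop/TM architectures whose background
alphabet contains no motif anchor letters at all, so the only triads a scan
can find are the ones planted.  This makes plant-and-recover tests exact:
every planted motif must come back with its kind, leaflet and anchor triad,
and nothing else may appear.

By default the background excludes every anchor class (K,R,F,Y,W and L,V,I):
leaving aliphatics in the background would let a stray Leu/Val extend a
planted motif's span, and the maximal-span representative would then differ
from the planted triad.  A "realistic" background with a hydrophobic
residue-frequency table is available for qualitative work, without the
exactness guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grammar import MotifKind, MotifMatch, ResidueClassTable, enumerate_matches
from .scan import ProteinRecord
from .topology import Leaflet, NTermLocation, TMSegment, orient_tm_segments

__all__ = [
    "PlantSpec",
    "PlantedMotif",
    "ConstructionError",
    "generate_synthetic_protein",
    "shuffle_null",
]

#: anchor-free hydrophobic-ish TM background (no K,R,F,Y,W,L,V,I)
TM_BACKGROUND = "ACGMST"
#: anchor-free polar loop background
LOOP_BACKGROUND = "DENQSTGP"
#: hydrophobic frequency table for the "realistic" (non-exact) background
REALISTIC_TM = dict(A=0.12, C=0.02, G=0.08, I=0.10, L=0.16, M=0.04, F=0.08,
                    S=0.06, T=0.06, V=0.12, W=0.02, Y=0.04, P=0.02, N=0.02,
                    Q=0.02, H=0.02, K=0.01, R=0.01)


class ConstructionError(ValueError):
    """A planted motif cannot be placed as requested."""


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant: where, what kind, which leaflet, which residues."""

    tm_index: int
    kind: MotifKind
    leaflet: Leaflet
    s1: int = 2  # spacer between first and central anchor
    s2: int = 2  # spacer between central and last anchor
    basic: str = "K"
    aromatic: str = "F"
    aliphatic: str = "L"

    def __post_init__(self) -> None:
        table = ResidueClassTable.configured(allow_ile=True)
        if self.basic not in table.basic:
            raise ValueError(f"{self.basic!r} is not a basic anchor residue")
        if self.aromatic not in (
            table.aromatic_carc if self.kind is MotifKind.CARC else table.aromatic_crac
        ):
            raise ValueError(f"{self.aromatic!r} is not a {self.kind.value} aromatic anchor")
        if self.aliphatic not in table.aliphatic:
            raise ValueError(f"{self.aliphatic!r} is not an aliphatic anchor residue")
        if not (1 <= self.s1 <= 5 and 1 <= self.s2 <= 5):
            raise ValueError("spacer lengths must lie in [1, 5]")

    @property
    def length(self) -> int:
        return 3 + self.s1 + self.s2

    def residues(self, rng: np.random.Generator) -> str:
        """Motif string in N->C order with anchor-free spacer residues."""
        sp = lambda n: "".join(rng.choice(list(TM_BACKGROUND), size=n))
        if self.kind is MotifKind.CARC:
            first, last = self.basic, self.aliphatic
        else:
            first, last = self.aliphatic, self.basic
        return first + sp(self.s1) + self.aromatic + sp(self.s2) + last


@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted motif, in final protein coordinates."""

    tm_index: int
    kind: MotifKind
    leaflet: Leaflet
    pos_basic: int
    pos_aromatic: int
    pos_aliphatic: int

    @property
    def anchors(self) -> tuple[int, int, int]:
        return tuple(sorted((self.pos_basic, self.pos_aromatic, self.pos_aliphatic)))


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _draw_realistic(rng: np.random.Generator, n: int) -> str:
    letters = list(REALISTIC_TM)
    probs = np.array(list(REALISTIC_TM.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def generate_synthetic_protein(
    n_tm: int,
    plants: Sequence[PlantSpec] = (),
    seed: int = 0,
    *,
    topology: NTermLocation = NTermLocation.EXTRACELLULAR,
    realistic_background: bool = False,
    protein_id: Optional[str] = None,
) -> tuple[ProteinRecord, list[PlantedMotif]]:
    """Build a synthetic membrane protein with motifs planted at chosen leaflets.

    Architecture: N-terminal loop (8-15 residues), then ``n_tm`` TM segments
    of 20-26 residues separated by loops of 8-15 residues, then a C-terminal
    loop.  Each plant is written into the half of its TM that faces the
    requested leaflet (resolved through the protein topology), with the basic
    anchor inside that half.  Deterministic under ``seed``.

    Returns the record plus the ground-truth anchor coordinates of every
    planted motif.

    Raises :class:`ConstructionError` if a plant cannot fit in its TM half, or
    if two plants in one TM would sit closer than ``spacer_max + 1`` residues
    (which could create a chimeric cross-kind triad out-spanning a planted one).
    """
    if n_tm < 0:
        raise ValueError("n_tm must be >= 0")
    for p in plants:
        if not (1 <= p.tm_index <= n_tm):
            raise ConstructionError(f"plant references TM{p.tm_index} of {n_tm}")

    rng = np.random.default_rng(seed)
    tm_lengths = rng.integers(20, 27, size=n_tm)
    loop_lengths = rng.integers(8, 16, size=n_tm + 1)

    # lay out segment coordinates
    segments: list[TMSegment] = []
    pos = 1 + int(loop_lengths[0])
    for i in range(n_tm):
        start = pos
        end = start + int(tm_lengths[i]) - 1
        segments.append(TMSegment(index=i + 1, start=start, end=end))
        pos = end + 1 + int(loop_lengths[i + 1])
    total_len = pos - 1 if n_tm else int(loop_lengths[0])

    oriented = {o.index: o for o in orient_tm_segments(topology, segments)}

    # background sequence
    seq = list(_draw(rng, LOOP_BACKGROUND, total_len))
    for seg in segments:
        tm_seq = (
            _draw_realistic(rng, seg.end - seg.start + 1)
            if realistic_background
            else _draw(rng, TM_BACKGROUND, seg.end - seg.start + 1)
        )
        seq[seg.start - 1 : seg.end] = list(tm_seq)

    # plant motifs
    placements: dict[int, list[tuple[int, int]]] = {}
    truth: list[PlantedMotif] = []
    for plant in plants:
        otm = oriented[plant.tm_index]
        seg = otm.segment
        mid = (seg.start + seg.end) // 2
        n_half = plant.leaflet == otm.n_end_faces  # basic anchor goes N-half?
        length = plant.length

        if plant.kind is MotifKind.CARC:  # basic anchor is the FIRST residue
            start = seg.start if n_half else mid + 1
        else:  # CRAC: basic anchor is the LAST residue
            start = (mid - length + 1) if n_half else (seg.end - length + 1)
        end = start + length - 1
        if start < seg.start or end > seg.end:
            raise ConstructionError(
                f"plant {plant.kind.value} (length {length}) does not fit in the "
                f"{'N' if n_half else 'C'}-terminal half of TM{seg.index} "
                f"({seg.start}-{seg.end})"
            )
        basic_anchor = start if plant.kind is MotifKind.CARC else end
        if (basic_anchor <= mid) != n_half:
            raise ConstructionError(
                f"plant {plant.kind.value} basic anchor {basic_anchor} cannot land in "
                f"the requested half of TM{seg.index}"
            )

        for other_start, other_end in placements.get(plant.tm_index, []):
            gap = max(start, other_start) - min(end, other_end) - 1
            if gap < 6:  # spacer_max + 1
                raise ConstructionError(
                    f"plants in TM{seg.index} are {max(gap, 0)} residues apart; "
                    f"need >= 6 to rule out chimeric cross-kind triads"
                )
        placements.setdefault(plant.tm_index, []).append((start, end))

        motif = plant.residues(rng)
        seq[start - 1 : end] = list(motif)
        if plant.kind is MotifKind.CARC:
            pb, pa, pl = start, start + 1 + plant.s1, end
        else:
            pl, pa, pb = start, start + 1 + plant.s1, end
        truth.append(
            PlantedMotif(
                tm_index=plant.tm_index,
                kind=plant.kind,
                leaflet=plant.leaflet,
                pos_basic=pb,
                pos_aromatic=pa,
                pos_aliphatic=pl,
            )
        )

    record = ProteinRecord(
        id=protein_id or f"SYN_{seed}",
        sequence="".join(seq),
        topology=topology,
        tm_segments=tuple(segments),
    )
    return record, truth


def shuffle_null(
    sequence: str,
    kind: MotifKind,
    n_shuffles: int,
    seed: int = 0,
    table: Optional[ResidueClassTable] = None,
) -> float:
    """Fraction of composition-preserving shuffles containing >= 1 motif.

    An empirical null for how easily a sequence's residue composition alone
    produces a motif of the given kind.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    table = table or ResidueClassTable()
    rng = np.random.default_rng(seed)
    letters = np.array(list("".join(sequence.split()).upper()))
    hits = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        if enumerate_matches(shuffled, kind, table=table):
            hits += 1
    return hits / n_shuffles
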