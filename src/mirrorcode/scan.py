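"""End-to-end protein scanning: orient, extend, detect, assign, classify."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .grammar import (
    MotifKind,
    MotifMatch,
    ResidueClassTable,
    enumerate_matches,
    select_maximal,
)
from .topology import (
    Leaflet,
    LocatedMotif,
    NTermLocation,
    OrientedTM,
    TMClassification,
    TMSegment,
    TMStatus,
    assign_leaflet,
    classify_tm,
    extend_tm,
    orient_tm_segments,
)

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "ProteinRecord", "ScanReport", "scan_protein", "scan_peptide"]

#: the 20 standard one-letter residue codes
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ScanConfig:
    """Scan-wide switches; the defaults reproduce the consensus algorithms.

    ``window`` is the per-side TM boundary extension (residues) searched for
    interfacial Lys/Arg.  The default of 2 mirrors how far database TM
    boundaries typically stop short of the snorkeling basic residue; larger
    windows start harvesting loop arginines that sit well outside the
    membrane interface and inflate the motif count.
    """

    allow_ile: bool = False
    strict_crac: bool = False
    spacer_min: int = 1
    spacer_max: int = 5
    window: int = 2
    maximal_only: bool = True

    @property
    def table(self) -> ResidueClassTable:
        return ResidueClassTable.configured(
            allow_ile=self.allow_ile,
            strict_crac=self.strict_crac,
            spacer_min=self.spacer_min,
            spacer_max=self.spacer_max,
        )


DEFAULT_CONFIG = ScanConfig()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein to scan: sequence, topology, TM annotation."""

    id: str
    sequence: str
    topology: NTermLocation
    tm_segments: tuple[TMSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", "".join(self.sequence.split()).upper())
        object.__setattr__(
            self, "tm_segments", tuple(sorted(self.tm_segments, key=lambda s: s.start))
        )
        n = len(self.sequence)
        for seg in self.tm_segments:
            if seg.end > n:
                raise ValueError(
                    f"{self.id}: TM{seg.index} {seg.start}-{seg.end} exceeds "
                    f"sequence length {n}"
                )


@dataclass(frozen=True)
class ScanReport:
    """Per-protein scan result: per-TM classifications plus summary counts."""

    protein_id: str
    tms: tuple[OrientedTM, ...]
    classifications: tuple[TMClassification, ...]

    @property
    def summary(self) -> dict[str, int]:
        counts = {s: 0 for s in TMStatus}
        for c in self.classifications:
            counts[c.status] += 1
        return {
            "n_dual": counts[TMStatus.DUAL_MIRROR],
            "n_carc_only": counts[TMStatus.CARC_ONLY],
            "n_crac_only": counts[TMStatus.CRAC_ONLY],
            "n_none": counts[TMStatus.NONE],
        }

    def status_of(self, tm_index: int) -> TMStatus:
        for c in self.classifications:
            if c.tm_index == tm_index:
                return c.status
        raise KeyError(f"no TM with index {tm_index} in report for {self.protein_id}")

    def motifs_of(self, tm_index: int) -> tuple[LocatedMotif, ...]:
        for c in self.classifications:
            if c.tm_index == tm_index:
                return c.motifs
        raise KeyError(f"no TM with index {tm_index} in report for {self.protein_id}")

    def motif_rows(self) -> list[dict]:
        """Flat motif table, deterministically ordered."""
        rows = []
        for c in self.classifications:
            for lm in c.motifs:
                m = lm.match
                rows.append(
                    {
                        "protein_id": self.protein_id,
                        "tm_index": c.tm_index,
                        "kind": m.kind.value,
                        "start": m.start,
                        "end": m.end,
                        "pos_basic": m.pos_basic,
                        "pos_aromatic": m.pos_aromatic,
                        "pos_aliphatic": m.pos_aliphatic,
                        "leaflet": lm.leaflet.value,
                        "maximal": lm.maximal,
                    }
                )
        rows.sort(key=lambda r: (r["tm_index"], r["start"], r["kind"], r["end"]))
        return rows


def _located(
    matches: Sequence[MotifMatch],
    maximal: Sequence[MotifMatch],
    tm: OrientedTM,
    maximal_only: bool,
) -> list[LocatedMotif]:
    maximal_set = set(maximal)
    chosen = maximal if maximal_only else matches
    return [
        LocatedMotif(match=m, leaflet=assign_leaflet(m, tm), maximal=m in maximal_set)
        for m in chosen
    ]


def scan_tm(
    sequence: str, tm: OrientedTM, config: ScanConfig = DEFAULT_CONFIG
) -> TMClassification:
    """Detect both motif kinds inside one extended TM and classify it."""
    sub = sequence[tm.extended_start - 1 : tm.extended_end]
    table = config.table
    located: dict[MotifKind, list[LocatedMotif]] = {}
    for kind in MotifKind:
        matches = enumerate_matches(sub, kind, offset=tm.extended_start, table=table)
        maximal = select_maximal(matches)
        for m in matches:
            if m not in maximal:
                logger.debug(
                    "%s candidate %s not maximal in its overlap cluster", kind.value, m
                )
        located[kind] = _located(matches, maximal, tm, config.maximal_only)
    return classify_tm(located[MotifKind.CARC], located[MotifKind.CRAC], tm)


def scan_protein(record: ProteinRecord, config: ScanConfig = DEFAULT_CONFIG) -> ScanReport:
    """Scan every TM of a protein.

    Pipeline per TM: orient from topology -> extend boundaries to interfacial
    basic residues (never crossing a neighbouring TM) -> enumerate CARC and
    CRAC triads in the extended segment -> reduce to maximal-span
    representatives per overlap cluster -> assign each motif's leaflet from
    its basic anchor -> classify the TM.
    """
    oriented = orient_tm_segments(record.topology, record.tm_segments)
    extended: list[OrientedTM] = []
    for i, otm in enumerate(oriented):
        prev_end = oriented[i - 1].segment.end if i > 0 else None
        next_start = oriented[i + 1].segment.start if i + 1 < len(oriented) else None
        es, ee = extend_tm(
            record.sequence,
            otm.segment,
            config.window,
            previous_end=prev_end,
            next_start=next_start,
        )
        extended.append(
            OrientedTM(
                segment=otm.segment,
                extended_start=es,
                extended_end=ee,
                n_end_faces=otm.n_end_faces,
            )
        )

    classifications = tuple(scan_tm(record.sequence, tm, config) for tm in extended)
    report = ScanReport(
        protein_id=record.id, tms=tuple(extended), classifications=classifications
    )
    logger.info(
        "%s: %d TMs scanned; %s", record.id, len(extended), report.summary
    )
    return report


def scan_peptide(
    sequence: str,
    offset: int = 1,
    kinds: Sequence[MotifKind] = (MotifKind.CARC, MotifKind.CRAC),
    config: ScanConfig = DEFAULT_CONFIG,
) -> dict[MotifKind, dict[str, list[MotifMatch]]]:
    """Scan a raw peptide without topology (no leaflet labels).

    Returns, per requested kind, both the exhaustive match list and the
    maximal-span representatives.
    """
    table = config.table
    out: dict[MotifKind, dict[str, list[MotifMatch]]] = {}
    for kind in kinds:
        matches = enumerate_matches(sequence, kind, offset=offset, table=table)
        out[kind] = {"all": matches, "maximal": select_maximal(matches)}
    return out
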