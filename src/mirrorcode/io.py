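"""File formats: FASTA in, TM-annotation tables in, TSV/BED/JSON reports out.

Coordinates are 1-based inclusive everywhere inside the package and in the
TSV/JSON outputs; BED output converts to the 0-based half-open convention.
Writers are byte-stable: identical report and config give identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO

from .grammar import MotifKind, MotifMatch
from .scan import ProteinRecord, ScanReport
from .topology import (
    Leaflet,
    LocatedMotif,
    NTermLocation,
    OrientedTM,
    TMClassification,
    TMSegment,
    TMStatus,
)

__all__ = [
    "FormatError",
    "read_fasta",
    "read_tm_annotations",
    "build_records",
    "write_report",
    "report_to_json",
    "report_from_json",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into (id, uppercased sequence) pairs.

    Gaps and whitespace are stripped from sequences.  An empty file or text
    before the first header is rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace("-", "").replace(".", "")
        records.append((rec.id, "".join(seq.split()).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


_TOPOLOGY_VALUES = {t.value: t for t in NTermLocation}


def read_tm_annotations(
    path: PathLike,
) -> dict[str, tuple[NTermLocation, list[TMSegment]]]:
    """Read a TM table: TSV with protein_id, tm_index, start, end, topology.

    ``topology`` (the N-terminus location, ``extracellular`` or
    ``cytoplasmic``) must be consistent across a protein's rows.  Rows may be
    unsorted; output segments are sorted and validated (1-based inclusive,
    non-overlapping).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty TM annotation file") from exc
    required = {"protein_id", "tm_index", "start", "end", "topology"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    out: dict[str, tuple[NTermLocation, list[TMSegment]]] = {}
    for pid, grp in df.groupby("protein_id", sort=True):
        topo_values = set(grp["topology"].astype(str))
        if len(topo_values) != 1:
            raise FormatError(f"{path}: {pid}: inconsistent topology values {topo_values}")
        topo_str = topo_values.pop()
        if topo_str not in _TOPOLOGY_VALUES:
            raise FormatError(
                f"{path}: {pid}: unknown topology {topo_str!r} "
                f"(expected one of {sorted(_TOPOLOGY_VALUES)})"
            )
        segments = []
        for row in grp.itertuples():
            try:
                segments.append(
                    TMSegment(index=int(row.tm_index), start=int(row.start), end=int(row.end))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {row.Index + 2}: {exc}") from exc
        segments.sort(key=lambda s: s.start)
        for prev, cur in zip(segments, segments[1:]):
            if cur.start <= prev.end:
                raise FormatError(
                    f"{path}: {pid}: TM{prev.index} and TM{cur.index} overlap"
                )
        out[str(pid)] = (_TOPOLOGY_VALUES[topo_str], segments)
    return out


def build_records(
    fasta_path: PathLike, tm_path: PathLike
) -> list[ProteinRecord]:
    """Join a FASTA file with its TM annotation table into scan-ready records.

    Proteins lacking TM annotations are rejected: leaflet logic is undefined
    without topology (use peptide scanning for bare sequences).
    """
    annotations = read_tm_annotations(tm_path)
    records = []
    for pid, seq in read_fasta(fasta_path):
        if pid not in annotations:
            raise FormatError(
                f"{pid}: no TM annotation; provide one or scan as a peptide"
            )
        topo, segments = annotations[pid]
        records.append(
            ProteinRecord(id=pid, sequence=seq, topology=topo, tm_segments=tuple(segments))
        )
    return records


# ---------------------------------------------------------------------------
# report writers

_TSV_COLUMNS = [
    "protein_id",
    "tm_index",
    "kind",
    "start",
    "end",
    "pos_basic",
    "pos_aromatic",
    "pos_aliphatic",
    "leaflet",
    "maximal",
]


def _tsv_text(report: ScanReport) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for row in report.motif_rows():
        lines.append("\t".join(str(row[c]) for c in _TSV_COLUMNS))
    return "\n".join(lines) + "\n"


def _bed_text(report: ScanReport) -> str:
    """BED6: 0-based half-open intervals, name '<KIND>:<leaflet>'."""
    lines = []
    for row in report.motif_rows():
        lines.append(
            "\t".join(
                [
                    row["protein_id"],
                    str(row["start"] - 1),
                    str(row["end"]),
                    f"{row['kind']}:{row['leaflet']}",
                    str(row["end"] - row["start"] + 1),
                    "+",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def report_to_json(report: ScanReport) -> str:
    payload = {
        "protein_id": report.protein_id,
        "summary": report.summary,
        "tms": [
            {
                "tm_index": tm.index,
                "start": tm.segment.start,
                "end": tm.segment.end,
                "extended_start": tm.extended_start,
                "extended_end": tm.extended_end,
                "n_end_faces": tm.n_end_faces.value,
            }
            for tm in report.tms
        ],
        "classifications": [
            {
                "tm_index": c.tm_index,
                "status": c.status.value,
                "same_leaflet_pair": c.same_leaflet_pair,
                "shared_anchor": c.shared_anchor,
                "motifs": [
                    {
                        "kind": lm.match.kind.value,
                        "start": lm.match.start,
                        "end": lm.match.end,
                        "pos_basic": lm.match.pos_basic,
                        "pos_aromatic": lm.match.pos_aromatic,
                        "pos_aliphatic": lm.match.pos_aliphatic,
                        "leaflet": lm.leaflet.value,
                        "maximal": lm.maximal,
                    }
                    for lm in c.motifs
                ],
            }
            for c in report.classifications
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def report_from_json(text: str) -> ScanReport:
    """Rebuild a ScanReport from its JSON serialization (lossless)."""
    payload = json.loads(text)
    tms = tuple(
        OrientedTM(
            segment=TMSegment(index=t["tm_index"], start=t["start"], end=t["end"]),
            extended_start=t["extended_start"],
            extended_end=t["extended_end"],
            n_end_faces=Leaflet(t["n_end_faces"]),
        )
        for t in payload["tms"]
    )
    classifications = tuple(
        TMClassification(
            tm_index=c["tm_index"],
            status=TMStatus(c["status"]),
            same_leaflet_pair=c["same_leaflet_pair"],
            shared_anchor=c["shared_anchor"],
            motifs=tuple(
                LocatedMotif(
                    match=MotifMatch(
                        start=m["start"],
                        pos_aromatic=m["pos_aromatic"],
                        end=m["end"],
                        pos_basic=m["pos_basic"],
                        pos_aliphatic=m["pos_aliphatic"],
                        kind=MotifKind(m["kind"]),
                    ),
                    leaflet=Leaflet(m["leaflet"]),
                    maximal=m["maximal"],
                )
                for m in c["motifs"]
            ),
        )
        for c in payload["classifications"]
    )
    return ScanReport(
        protein_id=payload["protein_id"], tms=tms, classifications=classifications
    )


def write_report(report: ScanReport, path: PathLike, format: str = "tsv") -> Path:
    """Write a scan report as ``tsv``, ``bed`` or ``json``."""
    path = Path(path)
    if format == "tsv":
        text = _tsv_text(report)
    elif format == "bed":
        text = _bed_text(report)
    elif format == "json":
        text = report_to_json(report)
    else:
        raise ValueError(f"unsupported report format {format!r} (tsv|bed|json)")
    path.write_text(text)
    return path
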