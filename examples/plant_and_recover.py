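"""Build a synthetic membrane protein with planted motifs and recover them.

The generator writes an anchor-free background (no K/R/F/Y/W/L/V/I outside
the plants), so the scan must find exactly the planted triads — kind,
leaflet and anchor coordinates — and nothing else.
"""

from mirrorcode import (
    Leaflet,
    MotifKind,
    PlantSpec,
    generate_synthetic_protein,
    scan_protein,
)

plants = (
    PlantSpec(tm_index=3, kind=MotifKind.CARC, leaflet=Leaflet.OUTER, s1=1, s2=2),
    PlantSpec(tm_index=3, kind=MotifKind.CRAC, leaflet=Leaflet.INNER, s1=2, s2=1),
    PlantSpec(tm_index=5, kind=MotifKind.CRAC, leaflet=Leaflet.OUTER, s1=3, s2=2),
)
record, truth = generate_synthetic_protein(7, plants, seed=2016)

print(f"{record.id}: {len(record.sequence)} residues, {len(record.tm_segments)} TMs")
for t in truth:
    print(f"  planted {t.kind.value} in TM{t.tm_index} ({t.leaflet.value}), anchors {t.anchors}")

report = scan_protein(record)
print("recovered:")
for c in report.classifications:
    for lm in c.motifs:
        print(
            f"  TM{c.tm_index}: {lm.kind.value} anchors {lm.match.anchors} ({lm.leaflet.value})"
        )
print("TM3 status:", report.status_of(3).value)  # dual_mirror: one motif per leaflet
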