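"""Scan the human CB1 cannabinoid receptor for the CARC/CRAC mirror code.

Runs the full pipeline on the bundled receptor (seven TM helices,
extracellular N-terminus): extend each TM to its interfacial Lys/Arg,
enumerate both motif grammars, keep the largest-span representative per
overlap cluster, assign leaflets, classify.  A "dual_mirror" TM carries a
CARC in one leaflet and a CRAC in the other — the geometry that can bind
two tail-to-tail cholesterol molecules at once.
"""

from mirrorcode import scan_protein
from mirrorcode.reference import cb1_record

report = scan_protein(cb1_record())

print(f"protein {report.protein_id}: {len(report.tms)} TM domains")
for c in report.classifications:
    motifs = ", ".join(
        f"{lm.kind.value} {lm.match.start}-{lm.match.end} ({lm.leaflet.value})"
        for lm in c.motifs
    )
    print(f"  TM{c.tm_index}: {c.status.value:12s} {motifs}")
print("summary:", report.summary)
# TM3 and TM7 are dual-mirror; TM4 has only a CARC and TM5 only a CRAC
# (both serving the inner leaflet); TM1/TM2/TM6 carry no motif at all.
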