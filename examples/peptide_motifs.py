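"""Motif queries on published peptides, including the grammar's edge cases.

Shows: the acetylcholine-receptor gamma-TM4 CARC motifs (human and Torpedo,
the latter using Trp inside its spacer), the TSPO TM5 region that carries
both motifs, and the serotonin 5-HT7 TM7 CRAC peptide whose reported motif
starts at an Ile — admissible only with the allow-Ile switch, and even then
not the largest valid span.
"""

from mirrorcode import MotifKind, ScanConfig, scan_peptide
from mirrorcode.reference import (
    ACHR_HUMAN_GAMMA_TM4,
    ACHR_TORPEDO_GAMMA_TM4,
    HT7_CRAC_PEPTIDE,
    TSPO_TM5_REGION,
)

CARC, CRAC = MotifKind.CARC, MotifKind.CRAC


def show(label, seq, offset, kind, config=ScanConfig()):
    res = scan_peptide(seq, offset=offset, kinds=(kind,), config=config)[kind]
    for m in res["maximal"]:
        print(
            f"{label}: {kind.value} {m.start}-{m.end} "
            f"(basic {m.pos_basic}, aromatic {m.pos_aromatic}, aliphatic {m.pos_aliphatic})"
        )


show("AChR human gamma-TM4", *ACHR_HUMAN_GAMMA_TM4, CARC)
show("AChR Torpedo gamma-TM4", *ACHR_TORPEDO_GAMMA_TM4, CARC)
show("TSPO TM5 region", *TSPO_TM5_REGION, CARC)
show("TSPO TM5 region", *TSPO_TM5_REGION, CRAC)

# The 5-HT7 CRAC peptide: with the default L/V aliphatic anchors the maximal
# motif is Leu-anchored (span 12); allowing Ile reveals the Ile-anchored
# triads as well, but they remain inside the same overlap cluster.
seq, off = HT7_CRAC_PEPTIDE
show("5-HT7 CRAC peptide (default)", seq, off, CRAC)
res = scan_peptide(seq, offset=off, kinds=(CRAC,), config=ScanConfig(allow_ile=True))
print(
    "5-HT7 CRAC peptide (allow Ile), all triads:",
    [m.anchors for m in res[CRAC]["all"]],
)
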