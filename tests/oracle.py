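"""Independent brute-force motif oracle for cross-checking the scanner.

Deliberately naive and separate from the package: test every O(n^3)
combination of three positions against the written-out consensus, with no
shared code beyond the residue alphabet.
"""

from itertools import combinations

BASIC = set("KR")
AROMATIC_CARC = set("FYW")
AROMATIC_CRAC = set("YF")
ALIPHATIC = set("LV")


def brute_force_triads(seq, kind, spacer_min=1, spacer_max=5,
                       aromatic_crac=AROMATIC_CRAC, aliphatic=ALIPHATIC):
    """All (i, j, k) 0-based position triples satisfying the consensus."""
    seq = seq.upper()
    if kind == "CARC":
        first, arom, last = BASIC, AROMATIC_CARC, aliphatic
    elif kind == "CRAC":
        first, arom, last = aliphatic, aromatic_crac, BASIC
    else:
        raise ValueError(kind)
    out = []
    for i, j, k in combinations(range(len(seq)), 3):
        if seq[i] not in first or seq[j] not in arom or seq[k] not in last:
            continue
        if not (spacer_min <= j - i - 1 <= spacer_max):
            continue
        if not (spacer_min <= k - j - 1 <= spacer_max):
            continue
        out.append((i, j, k))
    return out
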