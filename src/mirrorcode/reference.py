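"""Bundled validation cases: published peptides and the CB1 receptor.

These are the worked examples against which the scanner is validated:

* human AChR gamma-subunit TM4 region peptide (CARC at 455-462);
* *Torpedo* AChR gamma-TM4 peptide (CARC at 449-456, with a Trp variant);
* human CB1 receptor (UniProt P21554) with its seven annotated TM segments;
* TSPO TM5 region peptide, residues 135-156 (per the solution structure of
  the PK11195-bound translocator protein), carrying a CARC anchored at
  Arg-135 and the classical CRAC at 149-156;
* human serotonin 5-HT7 receptor TM7-derived CARC and CRAC peptides.

The CB1 record is a local copy: its length (472) and the motif-bearing
regions 186-196, 204-214, 232-239 and 291-300 were cross-checked against
independently published coordinates before bundling.  The TSPO entry is the
TM5 region only, used with a numbering offset.
"""

from __future__ import annotations

from importlib import resources

from .io import build_records
from .scan import ProteinRecord

__all__ = [
    "cb1_record",
    "ACHR_HUMAN_GAMMA_TM4",
    "ACHR_TORPEDO_GAMMA_TM4",
    "TSPO_TM5_REGION",
    "HT7_CARC_PEPTIDE",
    "HT7_CRAC_PEPTIDE",
]

#: human AChR gamma TM4 CARC-bearing peptide, first residue = 455
ACHR_HUMAN_GAMMA_TM4 = ("RVCFLAML", 455)
#: Torpedo AChR gamma TM4 CARC-bearing peptide, first residue = 449
ACHR_TORPEDO_GAMMA_TM4 = ("KACFWIAL", 449)
#: TSPO TM5 region, first residue = 135 (CARC from Arg-135; CRAC 149-156)
TSPO_TM5_REGION = ("RLLYPYLAWLAFATVLNYYVWR", 135)
#: 5-HT7 receptor TM7-derived peptides (synthetic constructs, offset 1)
HT7_CARC_PEPTIDE = ("RTFLWLGYANSL", 1)
HT7_CRAC_PEPTIDE = ("SLINPFIYAFFNRDLR", 1)


def _data_path(name: str):
    return resources.files("mirrorcode.data").joinpath(name)


def cb1_record() -> ProteinRecord:
    """The human CB1 cannabinoid receptor with its seven TM segments.

    TM boundaries (1-based inclusive): 117-142, 155-175, 188-212, 233-255,
    274-299, 345-365, 378-399; extracellular N-terminus.
    """
    with resources.as_file(_data_path("cb1_P21554.fasta")) as fasta:
        with resources.as_file(_data_path("cb1_tm.tsv")) as tm:
            (record,) = build_records(fasta, tm)
    return record
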