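"""Deuterium quadrupolar splittings of a methyl-labelled TM peptide.

A CD3-labelled alanine side chain has a 167 kHz static quadrupolar coupling.
Fast spinning about the C-CD3 bond scales it by |P2(cos 70.53 deg)| = 1/3,
giving the ~41.75 kHz powder splitting expected for an otherwise rigid
peptide; whole-helix rotation about the membrane normal with the tensor near
the magic angle averages the pattern away entirely.
"""

from mirrorcode import (
    STATIC_CHI_KHZ,
    TETRAHEDRAL_ANGLE_DEG,
    MotionalMode,
    QuadSpec,
    effective_splitting,
)

rigid = effective_splitting(QuadSpec())
methyl = effective_splitting(
    QuadSpec(modes=(MotionalMode(TETRAHEDRAL_ANGLE_DEG),))
)
wobble = effective_splitting(
    QuadSpec(modes=(MotionalMode(TETRAHEDRAL_ANGLE_DEG), MotionalMode(30.0)))
)

print(f"static coupling:            {STATIC_CHI_KHZ:.1f} kHz")
print(f"rigid-limit splitting:      {rigid:.2f} kHz")
print(f"+ methyl rotation (70.53deg): {methyl:.2f} kHz")
print(f"+ 30deg axial wobble:        {wobble:.2f} kHz")
# each additional fast motion can only narrow the Pake pattern
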