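# Methods

## Motif grammars

A motif is an anchor triad, not a substring pattern: three positions whose
residues fall in the required classes, with both inter-anchor gaps in
`[spacer_min, spacer_max]` (defaults 1 and 5). Spacer positions are
completely unconstrained — anchor-class letters and ambiguity codes may sit
between anchors (the CB1 TM3 CARC has both an F and a K inside its spacers).
Enumeration is exhaustive and reports every satisfying triad, ordered by
(start, aromatic position, end); this costs O(n·s²) with s = `spacer_max`
and is instantaneous at protein scale.

Residue classes, and why they are configurable:

| role | CARC | CRAC | notes |
|---|---|---|---|
| basic | K, R | K, R | fixed |
| aromatic | F, Y, W | Y, F | CH–π stacking works for any aromatic; Trp is only documented for CARC. `strict_crac` restricts CRAC to the original Tyr-only rule — note the CB1 TM3 CRAC contains no Tyr, so Y/F must be the default to find it. |
| aliphatic | L, V | L, V | `allow_ile` adds Ile (branched aliphatics all accommodate the cholesterol methyl groups). Off by default because the consensus as usually written says L/V; the 5-HT7 TM7 CRAC peptide is the case where it matters. |

Case is normalised on input; characters outside the 20 standard residues can
never be anchors but are legal spacers.

### Maximal-span selection

When several triads overlap (share ≥1 residue, transitively), the reported
representative is the one with the greatest span; ties break by smallest
start, then smallest aromatic position. The tie-break is ours — the
selection rule in the literature says only that the largest sequence is
selected — and is needed for byte-stable reports. All triads remain
available in all-matches mode; the `maximal` flag marks representatives.

Two consequences worth knowing. In the 5-HT7 CRAC peptide
`SLINPFIYAFFNRDLR`, the Ile-anchored motif usually quoted (positions 7–16
with `allow_ile`) is *not* the largest valid span — a Leu-anchored triad
spans 2–13 — so the quoted motif appears only in all-matches mode. In CB1
TM5 the largest CRAC triad is L288–Y294–K300 (span 13), which out-spans the
usually quoted V291–Y296/Y294–K300; both are in the same overlap cluster and
the classification is unaffected.

## Topology and leaflets

TM orientation alternates with segment parity: with an extracellular
N-terminus, odd-indexed segments have their N-terminal end in the outer
leaflet (type I single-pass proteins; TM 1/3/5/7 of a GPCR), even-indexed
segments the reverse; a cytoplasmic N-terminus flips everything.

Database TM boundaries often exclude the interfacial basic residues, which
snorkel toward the headgroups. Each segment is therefore extended outward to
the outermost Lys/Arg within `window` residues per side, clipped at sequence
bounds and one residue short of a neighbouring TM. **Default window = 2.**
The documented extensions in the motif literature are all ≤2 residues (CB1
TM3 186/214 vs annotated 188/212; TM5's Lys one residue past the annotated
end; TM7's Lys two residues before the start), and wider windows start
harvesting loop basics that are not at the membrane interface: at window 5
the CB1 worked example itself breaks (a loop arginine fabricates a CARC in
TM2 and a loop lysine a CRAC in TM4). The window is configurable for
proteins whose annotations are sloppier.

A motif's leaflet is the leaflet of the TM *half* (split at the integer
midpoint of the extended segment; positions ≤ midpoint are the N-half)
containing its **basic anchor** — not the motif midpoint — because the
Lys/Arg end is the part that must reach the aqueous interface. A TM is
`dual_mirror` iff it has ≥1 CARC and ≥1 CRAC in opposite leaflets. Both
kinds in the *same* leaflet is not a mirror pair: the TM is classified
`none` with a `same_leaflet_pair` flag (related to, but distinct from, the
distant CARC/CRAC pairs described in ABC transporters). A residue anchoring
motifs of both kinds is allowed and sets `shared_anchor`.

Proteins without TM annotations are rejected by the pipeline (leaflet logic
is undefined without topology); `scan_peptide` / `mirrorcode peptide` scan
bare sequences and report positions only.

## Bundled validation cases

The CB1 receptor record (472 aa, seven TMs, extracellular N-terminus) is a
local copy whose motif-bearing regions were cross-checked against
independently published coordinates (186–196, 204–214, 232–239, 291–300)
before bundling. TSPO is carried as its TM5 region only (residues 135–156,
used with a numbering offset): every anchor in that region is pinned by the
published analysis (CARC from Arg-135 with Tyr-138; CRAC 149–156 ending at
Arg-156). The quoted TSPO CARC extent "135–146" does not satisfy the 1–5
spacer rule (no aliphatic anchor within 5 of an aromatic reaches 146); the
scanner reports what the grammar yields, 135–144.

## Synthetic proteins and nulls

`generate_synthetic_protein` emulates a polytopic membrane protein's
architecture — loops of 8–15 residues alternating with TM segments of 20–26
— not its chemistry: the background alphabet contains **no anchor letters at
all** (K/R/F/Y/W and L/V/I are excluded; TMs draw from `ACGMST`, loops from
`DENQSTGP`). Excluding the aliphatics too matters: a stray background
Leu/Val within 5 of a planted aromatic would extend the motif's span and the
maximal-span representative would no longer be the planted triad. With the
anchor-free background, plant-and-recover is exact (kind, leaflet, anchor
coordinates) with zero false positives, which is what the recovery tests
assert. A `realistic_background` mode draws TMs from a hydrophobic frequency
table (Leu/Val/Phe-rich) for qualitative use; it carries no exactness
guarantee. Passing tests on synthetic proteins therefore validate the
scanning logic, not the scanner's specificity on natural sequences, whose
composition produces motifs at appreciable background rates (see
`shuffle_null`, the composition-preserving permutation null).

Motifs are planted flush against the end of the requested TM half so the
basic anchor lands in the right half; two plants in one TM must keep ≥6
residues between them (`spacer_max`+1), otherwise a chimeric triad mixing
anchors of the two plants could out-span a planted motif — violations raise
a construction error rather than silently producing an unrecoverable plant.
All randomness flows from one `numpy` generator seeded by the caller.

## Monolayer analysis

Adsorption kinetics are fitted as Δπ(t) = Δπ_max·(1 − e^(−kt)) by
Levenberg–Marquardt least squares; the initial insertion velocity is
v0 = k·Δπ_max. The mono-exponential form is our choice of the simplest
saturating model; if the fit fails the initial velocity falls back to the
first finite difference, flagged `converged=False`. Fewer than 4 points is
an error; an all-zero trace returns (0, 0, 0).

The critical insertion pressure is obtained by ordinary least squares of
Δπ_max on π₀ and extrapolation to the x-intercept, π_c = −a/b — the standard
monolayer-practice reading of "the film pressure at which insertion stops".
A non-negative slope means no extrapolable π_c and raises an error. Two
exact points define the line; ≥3 are recommended. π_c is invariant under
rescaling all Δπ_max by c > 0 (both a and b scale by c). Recovery tests use
Gaussian noise with σ = 0.25 mN·m⁻¹, the stated accuracy of the film-balance
instrument class, and check unbiasedness of the mean estimate over 1000
replicates within two standard errors. The published experimental π_c values
(42.5 / 32.5 / 28 / 42 mN·m⁻¹) are used only as synthetic scenario
parameters — the underlying raw isotherms are not public.

## Quadrupolar averaging

Each fast motional mode scales the static coupling by the second-Legendre
order factor P₂(cosβ) = ½(3cos²β − 1); independent modes multiply. The
powder (Pake) splitting is reported with the horn-to-horn convention
Δν = ¾·χ_eff (the convention is ours; reported experimental splittings do
not state one). Methyl rotation uses β = arccos(1/3) ≈ 70.53°, giving
|P₂| = 1/3 and 41.75 kHz from the 167 kHz static aliphatic C–D coupling.
The ~38 kHz measured for rigid methyl-labelled peptides reflects additional
small-amplitude librations, which are not quantified here and carry no
computational target. Splittings are non-negative and monotonically
non-increasing as modes are appended (every |P₂| ≤ 1), and mode order is
irrelevant.

## Problem sizes and determinism

The validation suites run at: 10,000 sampled sequences (length ≤15, 10-letter
alphabet) for oracle agreement against an independent O(n³) triple
enumeration; 200 random single-plant synthetic proteins for exact recovery;
1000 noise replicates for π_c unbiasedness. These sizes give exact
(agreement/recovery are all-or-nothing) or tightly concentrated statistics
in seconds. Report writers are byte-stable for fixed input and config; TSV
and JSON use 1-based inclusive coordinates, BED 0-based half-open.

## Known limitations

* No motif "strength" scoring or interaction energetics; the grammar is
  binary by construction.
* No de novo TM prediction — annotations must be supplied.
* Leaflet assignment is topological (half-helix membership), not a membrane
  insertion-depth model; strongly tilted helices may defeat it.
* Natural-sequence specificity is outside the exactness guarantee
  (see synthetic-background note above).
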