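# Methods

This note records the models, constants and design choices behind
`selenopep`, in the spirit of a statistics package documenting its
likelihoods: what is computed, under which assumptions, and where the
genuinely open decisions were made.

## Charge model and isoelectric point

Net charge is the classical Henderson–Hasselbalch sum over independent
ionizable groups: each basic group (N-terminus, Arg, Lys, His) contributes
`+1/(1+10^(pH−pKa))`, each acidic group (C-terminus, Asp, Glu, Cys, Tyr and
the Sec selenol) contributes `−1/(1+10^(pKa−pH))`. Group independence (no
electrostatic coupling, no conformational burial) is the standard desk
approximation; it is exact for the model and adequate for short, soluble
peptides. Because every term is non-increasing in pH and the two termini
are always present, the curve is strictly decreasing, so the isoelectric
point is the unique root on pH ∈ [0, 14]; it is found by bisection to
|Z| < 1e−6 (≤ 200 iterations) and reported to two decimals. Displayed
charges round half-away-from-zero; exact floats are kept internally.

### pKa set

No single published pKa set is canonical. The shipped defaults are the
Solomon textbook values — N-terminus 9.6, C-terminus 2.4, D 3.9, E 4.3,
H 6.0, C 8.3, Y 10.1, K 10.5, R 12.5 — with the literature Sec selenol pKa
of 5.2 (ionized form −1). Among the common alternatives evaluated during
calibration (Lehninger, EMBOSS, Sillero, Grimsley, Rodwell, DTASelect,
Thurlkill, IPC-peptide), this set is the one that reproduces the full
published property table of the five packaged designs: all ten rounded net
charges (pH 7 and pH 5.5) exactly, and all five pI values within ±0.10.
The selenol pKa being ~3 units below the thiol's is the chemically
important feature: at skin pH (5.5) Sec is already about two-thirds
ionized while Cys is neutral, which is why adding Sec residues lowers the
acidic-pH net charge of a design. Constants are data (`data/residues.tsv`),
so any other set can be loaded or patched via `override_entries`.

## Masses

Average residue masses (free amino acid minus one water, standard atomic
weights; water 18.0153 Da). The Sec entry is the one *calibrated* value:
the atomic composition of the Sec residue (C3H5NOSe) gives 150.05 Da, but
the published molecular weights of the five packaged designs imply
per-peptide Sec residue masses between 150.24 and 150.59 Da — mutually
inconsistent with any single value, which points to rounding/transcription
noise in the published table rather than a recoverable constant. The
shipped default, 150.42 Da, is the minimax fit: it keeps all five packaged
molecular weights within 0.53 Da (the composition value would leave
residuals up to 1.63 Da). Both values are documented in the data file;
users who want strict composition masses can override the entry.
Monoisotopic masses and isotope envelopes are out of scope.

## Hydrophobicity

The Wimley–White whole-residue octanol scale (water → n-octanol transfer
free energy, charged form for His), with the sign convention *larger =
more polar-soluble*, matching how the upstream property tool reports it.
Two additions make the packaged designs reproduce their published values
*exactly* (to the cent, all five):

* a constant terminus contribution of **+7.90 kcal/mol per peptide**
  (the charged chain ends prefer water by a fixed, composition-independent
  amount), stored as table metadata;
* a Sec value of **+3.20 kcal/mol**, inferred from the published sums
  (the per-U increment is identical across all five designs, which is what
  justifies reading it as the tool's native Sec parameter rather than a
  Cys alias; the Cys value, −0.02, would miss every Sec-containing sum by
  3.2 kcal/mol per U).

## Helical wheel and hydrophobic moment

Residues in a 1-based inclusive window are placed at 100°/residue (ideal
α-helix; configurable). The hydrophobic moment is the vector sum of
per-residue hydrophobicities at the wheel angles; since the shipped scale
is hydrophilicity-positive, values are negated so the arrow points to the
apolar face, as conventionally drawn. Magnitude and direction are
reported with the window. The wheel is a 2-D idealization: it ignores
helix distortion, fraying and any non-helical structure.

## Design rules

The rule set encodes the published design criteria with two
operationalizations that the source leaves qualitative:

* **"Mid-final chain"**: Sec allowed only at 1-based positions
  `> ceil(L/3)` (fraction configurable). For edit-based candidates, `L` is
  the *template* length — insertion slots are judged on the chain the
  design started from; for bare sequences it is the candidate's own
  length.
* **Net-charge window**: the published table prints a strict
  "+1 < Z < +4", yet two of the published designs sit exactly on +1 and
  +4. Bounds are therefore read as inclusive, at pH 7 (the design pH;
  pH 5.5 belongs to the selection filter).

The validator returns one verdict per rule and never errors on a
violation. Notably, the published designs themselves do not all pass:
the 43-mer exceeds the length bound and three designs carry a Sec at
position 3–4. These are surfaced as failed checks with positions — the
engine validates the published set, it does not retrofit rules to it.
Generation enumerates Cys→Sec substitutions and Sec insertions
(lexicographic by (position, residue)), optionally composes cationic
insertions, filters through the validator, deduplicates by sequence and
applies a seeded shuffle before truncating to the budget; with an
exhaustive budget the output equals brute-force enumeration of the same
edit moves. Multiple insertions are drawn from distinct template gaps.

## Selection

Thresholds: hydrophobicity strictly greater than +40 kcal/mol; rounded net
charge at pH 5.5 in (0, +4]; helix fraction ≥ 0.5. Helicity is a
user-supplied annotation (TSV) because it originates from structure
predictors outside this package; a candidate without an annotation fails
the criterion as "not evaluable" rather than silently. An optional
hydrophobic-moment threshold exists but is off by default — the published
outcome (a unique survivor) is reproducible without it. Ranking is by
(hydrophobicity, hydrophobic moment) descending with peptide-id
tie-break, making selection a pure, order-invariant function.

## Cloning conventions

Coordinates are 1-based, inclusive, top strand. NotI is modeled as
recognition `GCGGCCGC` cut at GC^GGCCGC, leaving 4-nt 5′ overhangs
(`GGCC`); the geometry is data (`RestrictionEnzyme`), so other 5′-overhang
cutters can be added, and the packaged definition is cross-checked against
Biopython's enzyme catalogue in the tests. A digestion fragment's
`sequence` is the top-strand span between consecutive top-strand cuts —
this makes fragment lengths exactly conserve the parent length through
digest/ligate round trips; the protruding bottom strand at the right end
is carried separately. Ligation joins fragments **in the order given** and
refuses incompatible junctions; resolution of ambiguous multi-way
ligations is deliberately not attempted — the caller specifies the order.
Back-translation maps U to TGA always; the default stop is TAA and TGA is
excluded from the stop row of the packaged E. coli usage table, since the
opal codon is reassigned in a Sec-expression host. Sec-aware translation
reads in-frame TGA as U except in the final codon position. The SECIS
element itself (an mRNA hairpin) is not folded or scored; CDS parts carry
an annotation slot and the only structural constraint checked is the
positional one (Sec codons 3′-proximal, via the design-rule zone).

## Synthetic data

Template generation draws residue classes from a target composition
(default: cationic-heavy amphipathic profile, 30% cationic / 35%
hydrophobic) then residues uniformly within class, with a forced Cys count
so the substitution strategy is always exercisable; DNA part generation
draws uniform ACGT with rejection sampling against (or controlled
implantation of) NotI sites. Generators are pure functions of
(spec, seed) over numpy's seeded PCG64. What they do *not* emulate:
real promoter/RBS/CDS sequence statistics, codon structure in non-CDS
parts, peptide secondary-structure propensity, or homology between
templates. Passing the synthetic suites therefore demonstrates the
*algebra* (conservation laws, round trips, rule agreement, determinism) on
realistic sizes, not biological plausibility of any particular sequence.
The construct-arithmetic suite builds the published two-insert
architecture (prefix-only on insert 1, suffix-only on insert 2) from
synthetic stand-in parts whose lengths are chosen to match the published
part anatomy (e.g. a 2,652 bp polymerase CDS, a 96 nt lead CDS), because
the original part sequences are not redistributable inside this package;
all lengths and fragment counts are then derived, not asserted inputs.

## Problem sizes and runtime

The default suites use: 1,000 random peptides for charge monotonicity and
pI-root checks, 200 pairs for mass additivity, 1,000 random circles with
1–3 implanted sites for digestion/ligation conservation, 100 random
Sec-containing peptides for the back-translation round trip, and
two full pipeline runs for determinism. The whole test suite completes in
well under a minute on a single CPU; these sizes were chosen as the point
where the property suites' failure probability under a seeded generator is
effectively determined by the code, not the sample.

## Known limitations

* Charge/pI ignore group coupling and activity corrections; predictions at
  extreme pH are model artifacts.
* The calibrated Sec mass is an inference from published sums, not a
  physical constant; composition purists should override it (150.05).
* Helicity is annotation-driven; the package deliberately contains no
  structure predictor.
* Ligation handles 5′-overhang chemistry only (no blunt, 3′-overhang or
  partial-fill joins).
* Codon optimization is usage-weighted or argmax per codon; no CAI
  windows, GC constraints or secondary-structure avoidance.
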