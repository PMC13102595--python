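# selenopep

Design, physicochemical triage and in-silico cloning of **selenopeptides** —
short therapeutic peptides carrying the 21st amino acid, selenocysteine
(Sec, one-letter code **U**). Sec is a cysteine analogue with selenium in
place of sulfur; its low selenol pKa and redox activity make Sec-containing
peptides attractive antioxidant / anti-tumoral candidates, e.g. for topical
treatment of UV-driven skin damage in nucleotide-excision-repair–deficient
patients (xeroderma pigmentosum). The package is aimed at peptide designers
and synthetic biologists who want the whole desk pipeline — from template
editing to an expression construct — as reproducible, testable code.

## What it computes

**Design engine** (`selenopep.design`). Machine-readable design rules
(length 12–35, 1–4 Sec confined to the C-terminal two-thirds of the chain —
keeping the UGA codons near the SECIS element — net charge +1…+4 at pH 7,
insertions restricted to R/K/H) with candidate enumeration by Cys→Sec
substitution, Sec insertion and cationic insertion, plus a rule-by-rule
validator and a `GGGGS`-linker repeat-construct builder.

**Sec-aware physicochemistry** (`selenopep.properties`). For a peptide with
ionizable groups *i* (both termini, D/E/C/Y side chains, and the Sec
selenol, pKa 5.2, ionized form −1):

```
Z(pH) = Σ_basic  1/(1+10^(pH−pKa_i))  −  Σ_acidic 1/(1+10^(pKa_i−pH))
```

the Henderson–Hasselbalch net charge; pI is the unique root of `Z` on
[0, 14] (bisection to |Z| < 1e−6). Average molecular weight is the residue
mass sum plus one water. Hydrophobicity is the summed whole-residue
water→octanol transfer free energy (larger = more polar-soluble) including
a fixed terminus contribution. Amphipathicity comes from the helical wheel
(100°/residue) and the hydrophobic-moment vector sum.

**Lead selection** (`selenopep.selection`). The published triage filter:
hydrophobicity > +40 kcal/mol, positive rounded net charge ≤ +4 at pH 5.5
(median skin pH), and an α-helix annotation covering ≥ half the chain
(helicity is user-supplied — it comes from structure predictors, not from
this package). Survivors are ranked by hydrophobicity, then hydrophobic
moment.

**BioBrick cloning** (`selenopep.cloning`). Affixing the BioBrick
prefix/suffix (each carrying one NotI site), cassette assembly with a
role-order linter, virtual NotI digestion (GC^GGCCGC, 4-nt 5′ overhangs)
with cohesive-end algebra, sticky-end ligation and circularization,
Sec-aware back-translation (U → TGA, stop = TAA, E. coli codon usage) and
sec-aware translation, GenBank/FASTA serialization via Biopython.

**Synthetic data** (`selenopep.synthetic`). Seeded generators for peptide
templates with controlled residue-class composition and for DNA part sets
with controlled NotI-site placement, plus the packaged bundle of the ten
published template/design sequences and their printed property table.

## Worked example

```
$ selenopep run --seed 1 --out demo-out
# Selenopeptide pipeline summary

seed: 1
candidates: 5

| peptide | length | MW (Da) | pI | hydrophobicity | rules |
|---|---|---|---|---|---|
| Selera-1 | 43 | 4601.19 | 8.89 | +58.65 | fails: length, sec_zone |
| Selera-2 | 31 | 3680.92 | 8.26 | +45.71 | fails: sec_zone |
| Selera-3 | 16 | 2223.07 | 10.63 | +30.56 | all pass |
| Selera-4 | 15 | 2122.33 | 10.14 | +23.14 | fails: sec_zone |
| Selera-5 | 15 | 1893.85 | 9.75 | +19.92 | all pass |

lead: **Selera-2** (1 survivor(s))
```

The table is the recomputed property surface for the five packaged designs
(weights in Da, pI in pH units, hydrophobicity in kcal/mol,
polar-soluble-positive). The `rules` column is the design validator doing
its job on the *published* sequences: it flags that the largest design
exceeds the 35-residue bound and that three designs carry a Sec ahead of
the C-terminal zone (e.g. position 4 of the lead) — known discrepancies of
the published set that the validator surfaces rather than hides. Selection
then applies the hydrophobicity/charge/helicity filter, and exactly one
candidate survives: Selera-2.

Back-translating a design gives a SECIS-ready CDS with in-frame opal
codons at every Sec:

```
$ selenopep clone backtranslate --peptide QNKKRFHYFRKKUNQU
>peptide
CAGAACAAAAAACGCTTTCATTATTTTCGCAAAAAATGAAACCAGTGATAA
```

Library use:

```python
from selenopep import load_default_table, parse_peptide, property_report
table = load_default_table()
pep = parse_peptide("MADUSERLHHSAHKKGUWAACTNFSRCTRKU", table, id="Selera-2")
rep = property_report(pep, table)         # ph_list defaults to (7.0, 5.5)
rep.rounded_charge_by_ph[5.5]             # +4
round(rep.hydrophobicity, 2)              # 45.71
```

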