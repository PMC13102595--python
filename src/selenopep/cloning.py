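"""In-silico BioBrick assembly for selenoprotein expression constructs.

Models the construction of a Sec-expression plasmid: affixing the BioBrick
prefix/suffix to inserts, concatenating parts into cassettes, virtual
restriction digestion with cohesive-end bookkeeping, sticky-end ligation
(linear or circular), Sec-aware back-translation (U -> TGA, the opal codon
recoded by the SECIS machinery) with codon-usage optimization for the
expression host, and GenBank/FASTA serialization via Biopython.

Conventions: sequences are top-strand, 1-based inclusive coordinates. A
digestion fragment's ``sequence`` is the top-strand segment between
consecutive top-strand cut positions, so fragment lengths always conserve
the parent length; 5' overhangs are recorded at both ends (the 3'-end
overhang is the protruding bottom strand read 5'->3').
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .properties import PeptideSequence

DNA_ALPHABET = set("ACGT")
PART_ROLES = {
    "prefix", "suffix", "promoter", "rbs", "cds", "terminator",
    "backbone", "other",
}

#: BioBrick affix strings (normalized; any typographic artifacts stripped).
BIOBRICK_PREFIX = "GAATTCGCGGCCGCTTCTAG"  # 20 bp, contains one NotI site
BIOBRICK_SUFFIX = "TACTAGTAGCGGCCGCTGCAG"  # 21 bp, contains one NotI site


class CloningError(ValueError):
    """Raised for invalid cloning operations (topology, overhangs, order)."""


def _clean_dna(sequence: str) -> str:
    """Uppercase and strip all non-IUPAC characters (whitespace, zero-width)."""
    seq = "".join(ch for ch in sequence.upper() if ch in DNA_ALPHABET or ch.isalpha())
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise CloningError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DNAPart:
    """An annotated DNA part (promoter, RBS, CDS, terminator, backbone...)."""

    id: str
    role: str
    sequence: str
    topology: str = "linear"
    secis_note: Optional[str] = None  # SECIS annotation slot for CDS parts

    def __post_init__(self) -> None:
        if self.role not in PART_ROLES:
            raise CloningError(f"{self.id}: unknown role {self.role!r}")
        if self.topology not in ("linear", "circular"):
            raise CloningError(f"{self.id}: bad topology {self.topology!r}")
        object.__setattr__(self, "sequence", _clean_dna(self.sequence))
        if not self.sequence:
            raise CloningError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme leaving 5' overhangs (cut offsets on top/bottom).

    ``cut_offset_top``/``cut_offset_bottom`` count bases from the 5' end of
    the recognition site on the top strand; for NotI (GC^GGCCGC) they are 2
    and 6, leaving 4-nt 5' overhangs (GGCC).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset_top <= len(self.recognition)):
            raise CloningError(f"{self.name}: top cut offset out of range")
        if not (0 <= self.cut_offset_bottom <= len(self.recognition)):
            raise CloningError(f"{self.name}: bottom cut offset out of range")
        if self.cut_offset_bottom < self.cut_offset_top:
            raise CloningError(f"{self.name}: only 5'-overhang cutters supported")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    @property
    def overhang_length(self) -> int:
        return self.cut_offset_bottom - self.cut_offset_top

    def sites(self, sequence: str, topology: str = "linear") -> list[int]:
        """1-based start positions of recognition sites on the top strand.

        For circular molecules, sites spanning the origin are found as well.
        """
        seq = sequence
        n = len(sequence)
        if topology == "circular":
            seq = sequence + sequence[: len(self.recognition) - 1]
        found, start = [], 0
        while True:
            idx = seq.find(self.recognition, start)
            if idx == -1 or idx >= n:
                break
            found.append(idx + 1)
            start = idx + 1
        return found


NOT_I = RestrictionEnzyme(
    name="NotI", recognition="GCGGCCGC", cut_offset_top=2, cut_offset_bottom=6
)


def load_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load enzyme definitions from TSV (name, recognition, cut offsets)."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        ):
            enz = RestrictionEnzyme(
                name=row["name"],
                recognition=_clean_dna(row["recognition"]),
                cut_offset_top=int(row["cut_offset_top"]),
                cut_offset_bottom=int(row["cut_offset_bottom"]),
            )
            out[enz.name] = enz
    return out


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment with cohesive ends.

    ``five_prime_overhang`` is the single-stranded 5' start of ``sequence``
    (top strand). ``three_prime_overhang`` is the protruding bottom strand at
    the right end, read 5'->3'; its bases are *not* part of ``sequence`` (the
    complementary bases belong to the neighboring fragment), which is what
    makes fragment lengths additive under digestion and ligation.
    """

    sequence: str
    five_prime_overhang: str = ""
    three_prime_overhang: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_dna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Construct:
    """An ordered assembly of parts, linear or circular."""

    id: str
    parts: tuple[DNAPart, ...]
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise CloningError(f"{self.id}: bad topology {self.topology!r}")
        if not self.parts:
            raise CloningError(f"{self.id}: empty construct")

    @property
    def sequence(self) -> str:
        return "".join(p.sequence for p in self.parts)

    def __len__(self) -> int:
        return len(self.sequence)

    def canonical_rotation(self) -> str:
        """Lexicographically minimal rotation (circular identity)."""
        seq = self.sequence
        if self.topology != "circular":
            return seq
        doubled = seq + seq
        return min(doubled[i : i + len(seq)] for i in range(len(seq)))

    def same_molecule(self, other: "Construct") -> bool:
        if self.topology != other.topology:
            return False
        return self.canonical_rotation() == other.canonical_rotation()


# ---------------------------------------------------------------------------
# Assembly operations
# ---------------------------------------------------------------------------

def add_affixes(
    insert: DNAPart,
    prefix: str = BIOBRICK_PREFIX,
    suffix: str = BIOBRICK_SUFFIX,
    which: str = "both",
) -> DNAPart:
    """Prepend/append the BioBrick affix strings verbatim to a linear part."""
    if insert.topology != "linear":
        raise CloningError(f"{insert.id}: cannot affix a circular part")
    if which not in ("prefix_only", "suffix_only", "both"):
        raise CloningError(f"unknown affix mode {which!r}")
    seq = insert.sequence
    if which in ("prefix_only", "both"):
        seq = _clean_dna(prefix) + seq
    if which in ("suffix_only", "both"):
        seq = seq + _clean_dna(suffix)
    return replace(insert, id=f"{insert.id}+affix", sequence=seq)


_ROLE_ORDER = {"promoter": 0, "rbs": 1, "cds": 2, "terminator": 3}


def assemble_insert(
    parts: Sequence[DNAPart],
    expected_roles: Optional[Sequence[str]] = None,
    id: str = "insert",
    strict: bool = False,
) -> DNAPart:
    """Concatenate linear parts into one insert, linting the role order.

    The linter checks that promoter precedes RBS precedes CDS precedes
    terminator among the functional parts; violations are warnings unless
    ``strict`` is set, in which case the offending pair is named.
    """
    if not parts:
        raise CloningError("no parts to assemble")
    for p in parts:
        if p.topology != "linear":
            raise CloningError(f"{p.id}: circular part in assembly")
    if expected_roles is not None:
        got = [p.role for p in parts]
        if list(expected_roles) != got:
            raise CloningError(f"role order {got} != expected {list(expected_roles)}")
    warnings = []
    ranked = [(p, _ROLE_ORDER[p.role]) for p in parts if p.role in _ROLE_ORDER]
    for (a, ra), (b, rb) in zip(ranked, ranked[1:]):
        if rb < ra:
            msg = f"role order violation: {a.id} ({a.role}) before {b.id} ({b.role})"
            if strict:
                raise CloningError(msg)
            warnings.append(msg)
    seq = "".join(p.sequence for p in parts)
    part = DNAPart(id=id, role="other", sequence=seq)
    if warnings:
        # surfaced, not fatal: attach to the SECIS/annotation note slot
        part = replace(part, secis_note="; ".join(warnings))
    return part


def concatenate(a: DNAPart, b: DNAPart, id: Optional[str] = None) -> DNAPart:
    """Plain end-to-end join of two linear parts; length additive."""
    if a.topology != "linear" or b.topology != "linear":
        raise CloningError("concatenate requires linear parts")
    return DNAPart(
        id=id or f"{a.id}+{b.id}", role="other", sequence=a.sequence + b.sequence
    )


def virtual_digest(
    molecule: DNAPart | Construct, enzyme: RestrictionEnzyme = NOT_I
) -> list[Fragment]:
    """Digest a molecule, returning fragments with cohesive-end bookkeeping.

    A linear molecule with k sites yields k+1 fragments; a circular one
    yields k fragments (or the molecule itself, as a single fragment, when
    no site is present). Fragment sequence lengths conserve the input
    length. Cut positions are reported on the top strand, 1-based.
    """
    seq = molecule.sequence
    topology = molecule.topology
    name = molecule.id
    sites = enzyme.sites(seq, topology)
    ov = enzyme.overhang_length
    if not sites:
        return [Fragment(sequence=seq, source=f"{name}:uncut")]
    cuts = [s - 1 + enzyme.cut_offset_top for s in sites]  # 0-based top cuts
    overhang_at = {
        c: seq[c : c + ov] if c + ov <= len(seq) else (seq + seq)[c : c + ov]
        for c in cuts
    }
    frags = []
    if topology == "linear":
        bounds = [0] + cuts + [len(seq)]
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            frags.append(
                Fragment(
                    sequence=seq[lo:hi],
                    five_prime_overhang=overhang_at.get(lo, ""),
                    three_prime_overhang=(
                        revcomp(overhang_at[hi]) if hi in overhang_at else ""
                    ),
                    source=f"{name}:{lo + 1}-{hi}",
                )
            )
    else:
        doubled = seq + seq
        for i, lo in enumerate(cuts):
            hi = cuts[(i + 1) % len(cuts)]
            span = doubled[lo : hi if hi > lo else hi + len(seq)]
            frags.append(
                Fragment(
                    sequence=span,
                    five_prime_overhang=overhang_at[lo],
                    three_prime_overhang=revcomp(overhang_at[hi]),
                    source=f"{name}:{lo + 1}-{hi if hi > lo else hi + len(seq)}",
                )
            )
    return frags


def _ends_compatible(left: Fragment, right: Fragment) -> bool:
    """True when left's right end can anneal to right's left end."""
    return left.three_prime_overhang == revcomp(right.five_prime_overhang)


def ligate(
    fragments: Sequence[Fragment],
    require_circular: bool = False,
    id: str = "ligation",
) -> Construct:
    """Join fragments end-to-end in the given order at complementary overhangs.

    Every junction must pair a 5' overhang with its complementary protruding
    bottom strand (blunt-into-sticky is refused, naming the junction). With
    ``require_circular`` the last fragment must also close onto the first.
    The output length is the sum of fragment lengths, each junction's
    overhang counted once (it is stored on only one side).
    """
    if not fragments:
        raise CloningError("nothing to ligate")
    for i, (a, b) in enumerate(zip(fragments, fragments[1:])):
        if not _ends_compatible(a, b):
            raise CloningError(
                f"incompatible overhangs at junction {i + 1}: "
                f"{a.three_prime_overhang or 'blunt'} / "
                f"{b.five_prime_overhang or 'blunt'}"
            )
    topology = "linear"
    if require_circular:
        last, first = fragments[-1], fragments[0]
        if not _ends_compatible(last, first):
            raise CloningError(
                "cannot circularize: terminal overhangs "
                f"{last.three_prime_overhang or 'blunt'} / "
                f"{first.five_prime_overhang or 'blunt'} do not pair"
            )
        topology = "circular"
    parts = tuple(
        DNAPart(id=f.source or f"frag-{i + 1}", role="other", sequence=f.sequence)
        for i, f in enumerate(fragments)
    )
    return Construct(id=id, parts=parts, topology=topology)


def digest_and_ligate(
    backbone: DNAPart | Construct,
    cassette: DNAPart | Construct,
    enzyme: RestrictionEnzyme = NOT_I,
    id: str = "plasmid",
) -> Construct:
    """Standard BioBrick cloning step: digest both molecules, keep the
    backbone body and the cassette core, and close them into a circle.

    The cassette must carry exactly two sites (one in each affix) and the
    backbone exactly two sites flanking its cloning region (for a circular
    backbone, the larger fragment is kept as the vector body; the excised
    stuffer is discarded).
    """
    cass_frags = virtual_digest(cassette, enzyme)
    if len(cass_frags) != 3:
        raise CloningError(
            f"expected 2 {enzyme.name} sites in the cassette affixes, digest "
            f"gave {len(cass_frags)} fragments"
        )
    core = cass_frags[1]
    bb_frags = virtual_digest(backbone, enzyme)
    if backbone.topology == "circular":
        if len(bb_frags) < 1:
            raise CloningError("backbone digest yielded nothing")
        body = max(bb_frags, key=len)
    else:
        raise CloningError("backbone must be circular")
    if not body.five_prime_overhang:
        raise CloningError(f"backbone has no {enzyme.name} site")
    return ligate([body, core], require_circular=True, id=id)


# ---------------------------------------------------------------------------
# Sec-aware coding-sequence handling
# ---------------------------------------------------------------------------

#: Opal codon reassigned to Sec by the SECIS machinery.
SEC_CODON = "TGA"

_STANDARD_FORWARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


@dataclass(frozen=True)
class CodonTable:
    """Per-amino-acid codon weights with the Sec recoding rule (U -> TGA)."""

    weights: dict[str, dict[str, float]]
    stop_codon: str = "TAA"

    def __post_init__(self) -> None:
        for aa, codons in self.weights.items():
            total = sum(codons.values())
            if abs(total - 1.0) > 1e-6:
                raise CloningError(
                    f"codon weights for {aa!r} sum to {total}, expected 1"
                )
        u = self.weights.get("U", {})
        if set(u) != {SEC_CODON}:
            raise CloningError("U must map only to TGA")
        if self.stop_codon == SEC_CODON:
            raise CloningError("TGA is reserved for Sec in this system")

    def argmax(self, aa: str) -> str:
        codons = self.weights[aa]
        return max(sorted(codons), key=lambda c: codons[c])

    def sample(self, aa: str, rng: random.Random) -> str:
        codons = sorted(self.weights[aa])
        probs = [self.weights[aa][c] for c in codons]
        return rng.choices(codons, weights=probs, k=1)[0]


def load_codon_table(path: str | Path, stop_codon: str = "TAA") -> CodonTable:
    """Load codon usage from TSV (amino_acid, codon, fraction) and renormalize."""
    raw: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        ):
            raw.setdefault(row["amino_acid"], {})[row["codon"]] = float(
                row["fraction"]
            )
    for aa, codons in raw.items():
        total = sum(codons.values())
        raw[aa] = {c: f / total for c, f in codons.items()}
    return CodonTable(weights=raw, stop_codon=stop_codon)


def default_codon_table() -> CodonTable:
    """Packaged E. coli K-12 usage table with U recoded to TGA."""
    with resources.as_file(
        resources.files("selenopep.data").joinpath("codon_usage_ecoli.tsv")
    ) as path:
        return load_codon_table(path)


def back_translate(
    peptide: PeptideSequence,
    codon_table: Optional[CodonTable] = None,
    mode: str = "argmax",
    seed: int = 0,
) -> str:
    """Map a peptide to a CDS under the usage table; U always becomes TGA.

    ``argmax`` picks the most-used codon per residue (deterministic);
    ``seeded_weighted`` samples codons by usage fraction, reproducibly per
    seed. One stop codon is appended, so the CDS length is 3*(n+1).
    """
    codon_table = codon_table or default_codon_table()
    if mode not in ("argmax", "seeded_weighted"):
        raise CloningError(f"unknown back-translation mode {mode!r}")
    rng = random.Random(seed)
    codons = []
    for tok in peptide.tokens:
        if tok not in codon_table.weights:
            raise CloningError(f"no codon defined for residue token {tok!r}")
        if mode == "argmax":
            codons.append(codon_table.argmax(tok))
        else:
            codons.append(codon_table.sample(tok, rng))
    codons.append(codon_table.stop_codon)
    return "".join(codons)


def translate(cds: str, sec_aware: bool = True, id: str = "") -> PeptideSequence:
    """Translate a CDS; with ``sec_aware``, in-frame TGA reads as Sec.

    Without ``sec_aware``, TGA terminates translation like any stop codon. A
    trailing stop codon is consumed silently.
    """
    cds = _clean_dna(cds)
    if len(cds) % 3 != 0:
        raise CloningError(f"CDS length {len(cds)} not a multiple of 3")
    tokens: list[str] = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _STANDARD_FORWARD[codon]
        if codon == SEC_CODON and sec_aware and i < n_codons - 1:
            tokens.append("U")
            continue
        if aa == "*":
            break
        tokens.append(aa)
    return PeptideSequence(id=id, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ROLE_TO_FEATURE = {
    "promoter": "promoter",
    "rbs": "RBS",
    "cds": "CDS",
    "terminator": "terminator",
    "backbone": "misc_feature",
    "prefix": "misc_feature",
    "suffix": "misc_feature",
    "other": "misc_feature",
}
_FEATURE_TO_ROLE = {v: k for k, v in reversed(_ROLE_TO_FEATURE.items())}


def construct_to_seqrecord(construct: Construct) -> SeqRecord:
    record = SeqRecord(
        Seq(construct.sequence),
        id=construct.id[:16] or "construct",
        name=(construct.id or "construct")[:16].replace(" ", "_"),
        description=construct.id,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = construct.topology
    offset = 0
    for part in construct.parts:
        record.features.append(
            SeqFeature(
                FeatureLocation(offset, offset + len(part)),
                type=_ROLE_TO_FEATURE[part.role],
                qualifiers={"label": [part.id], "role": [part.role]},
            )
        )
        offset += len(part)
    return record


def serialize_construct(
    construct: Construct, path: str | Path, format: str = "genbank"
) -> None:
    """Write a construct as GenBank (one feature per part) or FASTA."""
    if format not in ("genbank", "fasta"):
        raise CloningError(f"unknown format {format!r}")
    SeqIO.write([construct_to_seqrecord(construct)], str(path), format)


def read_construct(path: str | Path, format: str = "genbank") -> Construct:
    """Read back a serialized construct, reconstructing parts and topology."""
    record = next(SeqIO.parse(str(path), format))
    seq = str(record.seq).upper()
    topology = record.annotations.get("topology", "linear")
    parts = []
    for feat in sorted(record.features, key=lambda f: int(f.location.start)):
        role = feat.qualifiers.get("role", [_FEATURE_TO_ROLE.get(feat.type, "other")])[0]
        parts.append(
            DNAPart(
                id=feat.qualifiers.get("label", ["part"])[0],
                role=role,
                sequence=seq[int(feat.location.start) : int(feat.location.end)],
            )
        )
    if not parts:
        parts = [DNAPart(id=record.id, role="other", sequence=seq)]
    return Construct(id=record.description or record.id, parts=tuple(parts), topology=topology)
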