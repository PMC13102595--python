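"""Synthetic inputs: peptide templates, DNA part sets, and the Selera bundle.

Everything the pipeline consumes can be generated here with no download:
short cationic/amphipathic peptide templates with controllable length and
residue-class composition, and DNA part sets with controlled presence or
absence of NotI sites. All generators are pure functions of (spec, seed).

:func:`selera_fixture` returns the published template and designed
selenopeptide sequences (with their printed property table) plus the
BioBrick affix strings, as ready-to-use records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cloning import NOT_I, BIOBRICK_PREFIX, BIOBRICK_SUFFIX, DNAPart
from .residues import ResidueTable, load_default_table

_DNA = np.array(list("ACGT"))


class SyntheticSpecError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class TemplateSpec:
    """Specification for a batch of synthetic peptide templates.

    ``class_composition`` gives target fractions per residue class
    (cationic/anionic/polar/hydrophobic/special); residues are drawn per
    class then uniformly within class. ``include_cysteines`` forces a
    per-record Cys count drawn uniformly from the given range, so the
    Cys→Sec substitution strategy of the design engine is always testable.
    """

    n: int = 10
    length_range: tuple[int, int] = (12, 35)
    class_composition: dict[str, float] = field(
        default_factory=lambda: {
            # cationic-leaning amphipathic profile typical of the templates
            "cationic": 0.30,
            "anionic": 0.05,
            "polar": 0.20,
            "hydrophobic": 0.35,
            "special": 0.10,
        }
    )
    include_cysteines: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticSpecError("n must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise SyntheticSpecError(f"invalid length_range {self.length_range}")
        clo, chi = self.include_cysteines
        if not (0 <= clo <= chi):
            raise SyntheticSpecError(
                f"invalid include_cysteines {self.include_cysteines}"
            )
        if chi > lo:
            raise SyntheticSpecError(
                "cysteine count may exceed the shortest template length"
            )
        total = sum(self.class_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticSpecError(
                f"class_composition fractions sum to {total}, expected 1"
            )


def gen_peptide_templates(
    spec: TemplateSpec, table: Optional[ResidueTable] = None
) -> list[tuple[str, str]]:
    """Generate ``spec.n`` templates as (id, sequence) records.

    Lengths are uniform in ``length_range``; residues are drawn per
    ``class_composition`` then uniformly within class (Sec and Cys excluded
    from the draw; Cys placement is governed by ``include_cysteines``).
    Deterministic given the spec seed.
    """
    table = table or load_default_table()
    by_class: dict[str, list[str]] = {}
    for rec in table.records.values():
        if len(rec.code) == 1 and rec.code not in ("U", "C"):
            by_class.setdefault(rec.residue_class, []).append(rec.code)
    for cls in spec.class_composition:
        if cls not in by_class:
            raise SyntheticSpecError(f"no residues available for class {cls!r}")
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_composition)
    probs = np.array([spec.class_composition[c] for c in classes])
    records = []
    for i in range(spec.n):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        n_cys = int(
            rng.integers(spec.include_cysteines[0], spec.include_cysteines[1] + 1)
        )
        drawn_classes = rng.choice(classes, size=length, p=probs)
        seq = [
            str(rng.choice(sorted(by_class[cls]))) for cls in drawn_classes
        ]
        if n_cys:
            cys_pos = rng.choice(length, size=n_cys, replace=False)
            for p in cys_pos:
                seq[int(p)] = "C"
        records.append((f"template-{i + 1:03d}", "".join(seq)))
    return records


@dataclass(frozen=True)
class PartSetSpec:
    """Specification for a synthetic DNA part set.

    ``roles`` lists (role, min_len, max_len) triples. ``notI_policy``:
    ``forbid`` rejects any part containing the NotI site (rejection
    sampling), ``implant`` places sites at ``implant_positions`` (1-based,
    per part id), ``require_in_affixes_only`` forbids sites in all parts and
    relies on the BioBrick affixes to supply them.
    """

    roles: tuple[tuple[str, int, int], ...] = (
        ("promoter", 35, 60),
        ("rbs", 12, 20),
        ("cds", 60, 300),
        ("terminator", 40, 80),
        ("backbone", 1800, 2500),
    )
    notI_policy: str = "forbid"
    implant_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        for role, lo, hi in self.roles:
            if not (1 <= lo <= hi):
                raise SyntheticSpecError(f"invalid length range for {role!r}")
        if self.notI_policy not in ("forbid", "implant", "require_in_affixes_only"):
            raise SyntheticSpecError(f"unknown notI_policy {self.notI_policy!r}")


def gen_dna_parts(spec: PartSetSpec) -> list[DNAPart]:
    """Generate one part per role entry, honoring the NotI-site policy."""
    rng = np.random.default_rng(spec.seed)
    site = NOT_I.recognition
    parts = []
    counts: dict[str, int] = {}
    for role, lo, hi in spec.roles:
        counts[role] = counts.get(role, 0) + 1
        part_id = f"{role}-{counts[role]}"
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(spec.max_retries + 1):
            seq = "".join(rng.choice(_DNA, size=length))
            if spec.notI_policy == "implant":
                for pos in spec.implant_positions.get(part_id, ()):
                    if not (1 <= pos <= length - len(site) + 1):
                        raise SyntheticSpecError(
                            f"{part_id}: implant position {pos} out of range"
                        )
                    seq = seq[: pos - 1] + site + seq[pos - 1 + len(site):]
                # implanting may not create extra sites elsewhere
                if seq.count(site) == len(spec.implant_positions.get(part_id, ())):
                    break
            elif site not in seq:
                break
            if attempt == spec.max_retries:
                raise SyntheticSpecError(
                    f"{part_id}: rejection sampling exceeded "
                    f"{spec.max_retries} retries"
                )
        parts.append(DNAPart(id=part_id, role=role, sequence=seq))
    return parts


# ---------------------------------------------------------------------------
# Published sequences (template peptides, designed selenopeptides, affixes)
# ---------------------------------------------------------------------------

#: Template peptides, in publication order.
TEMPLATE_SEQUENCES: dict[str, str] = {
    "YR-10": "YGKPVAVPAR",
    "Rb4": "MADSERLSAPGCWAACTNFSRTRK",
    "LW2": "QNKRFYFRKNQ",
    "LTX-315": "KKWWKKW-dip-K",
    "OS-LL11": "LLPPWLCPRNK",
}

#: Designed selenopeptides (Sec = U), in publication order.
SELERA_SEQUENCES: dict[str, str] = {
    "Selera-1": "YGUKHHVCAVRGGGGSYGUKHHVCAVRGGGGSYGUKHHVUAVR",
    "Selera-2": "MADUSERLHHSAHKKGUWAACTNFSRCTRKU",
    "Selera-3": "QNKKRFHYFRKKUNQU",
    "Selera-4": "QRAUKKILWWKKUWU",
    "Selera-5": "LLPPWKKLCPRUNUK",
}

#: Published property table for the five designs (for cross-checks and as
#: selection-stage input): MW (Da), rounded net charge at pH 7 and pH 5.5,
#: pI, hydrophobicity (kcal/mol).
PUBLISHED_PROPERTIES: dict[str, dict[str, float]] = {
    "Selera-1": {"mw": 4600.79, "q7": 3, "q55": 8, "pi": 8.81, "hyd": 58.65},
    "Selera-2": {"mw": 3680.39, "q7": 1, "q55": 4, "pi": 8.24, "hyd": 45.71},
    "Selera-3": {"mw": 2222.95, "q7": 4, "q55": 5, "pi": 10.64, "hyd": 30.56},
    "Selera-4": {"mw": 2122.85, "q7": 2, "q55": 3, "pi": 10.12, "hyd": 23.14},
    "Selera-5": {"mw": 1893.84, "q7": 2, "q55": 3, "pi": 9.83, "hyd": 19.92},
}

#: Helix annotations used by the published lead filter: the four designs
#: retaining helical structure in the predicted models, with the fraction of
#: the chain annotated helical (nominal values; Selera-5 showed no secondary
#: structure and is deliberately absent).
HELIX_ANNOTATIONS: dict[str, float] = {
    "Selera-1": 0.7,
    "Selera-2": 0.8,
    "Selera-3": 0.7,
    "Selera-4": 0.6,
}


@dataclass(frozen=True)
class SeleraFixture:
    templates: dict[str, str]
    designs: dict[str, str]
    published_properties: dict[str, dict[str, float]]
    helix_annotations: dict[str, float]
    prefix: str
    suffix: str

    @property
    def peptides(self) -> dict[str, str]:
        return {**self.templates, **self.designs}


def selera_fixture() -> SeleraFixture:
    """Return the published peptide bundle and BioBrick affix strings."""
    return SeleraFixture(
        templates=dict(TEMPLATE_SEQUENCES),
        designs=dict(SELERA_SEQUENCES),
        published_properties={
            k: dict(v) for k, v in PUBLISHED_PROPERTIES.items()
        },
        helix_annotations=dict(HELIX_ANNOTATIONS),
        prefix=BIOBRICK_PREFIX,
        suffix=BIOBRICK_SUFFIX,
    )


def records_to_fasta(records: Sequence[tuple[str, str]]) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq in records)
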