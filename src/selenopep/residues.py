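"""Per-residue physical constants for Sec-aware peptide physicochemistry.

The residue table bundles everything the property calculators need: average
residue masses, side-chain pKa values with the sign of the ionized form,
whole-residue hydrophobicity (octanol-scale transfer free energies, larger =
more polar-soluble), and a coarse residue-class label used for helical-wheel
plots and template generation. Constants are data, not code: the packaged
defaults live in ``data/residues.tsv`` and any value can be overridden or
extended (e.g. to register non-single-letter tokens such as the "dip" residue
of LTX-315) without touching the calculators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

CANONICAL_CODES = set("ACDEFGHIKLMNPQRSTVWY")
#: Selenocysteine one-letter code.
SEC = "U"
RESIDUE_CLASSES = {"cationic", "anionic", "polar", "hydrophobic", "special"}


class ResidueTableError(ValueError):
    """Raised for malformed residue data (missing/duplicate codes, bad values)."""


@dataclass(frozen=True)
class ResidueRecord:
    """Physical constants for one residue token.

    ``avg_mass`` is the residue mass in Da (free amino acid minus one water).
    ``side_chain_pka`` and ``charge_when_ionized`` (+1 or -1) are present
    together or not at all. ``hydrophobicity`` is in kcal/mol with the
    polar-soluble-positive sign convention.
    """

    code: str
    name: str
    avg_mass: float
    side_chain_pka: Optional[float] = None
    charge_when_ionized: Optional[int] = None
    hydrophobicity: float = 0.0
    residue_class: str = "special"

    def __post_init__(self) -> None:
        if not self.code:
            raise ResidueTableError("residue code must be non-empty")
        if self.avg_mass <= 0:
            raise ResidueTableError(
                f"{self.code}: avg_mass must be positive, got {self.avg_mass}"
            )
        if (self.side_chain_pka is None) != (self.charge_when_ionized is None):
            raise ResidueTableError(
                f"{self.code}: side_chain_pka and charge_when_ionized must be "
                "present together"
            )
        if self.charge_when_ionized not in (None, 1, -1):
            raise ResidueTableError(
                f"{self.code}: charge_when_ionized must be +1 or -1"
            )
        if self.residue_class not in RESIDUE_CLASSES:
            raise ResidueTableError(
                f"{self.code}: unknown residue_class {self.residue_class!r}"
            )
        if self.residue_class == "cationic" and self.charge_when_ionized != 1:
            raise ResidueTableError(f"{self.code}: cationic residues must be +1")
        if self.residue_class == "anionic" and self.charge_when_ionized != -1:
            raise ResidueTableError(f"{self.code}: anionic residues must be -1")

    @property
    def is_basic(self) -> bool:
        return self.charge_when_ionized == 1

    @property
    def is_acidic(self) -> bool:
        return self.charge_when_ionized == -1


@dataclass(frozen=True)
class ResidueTable:
    """A complete residue constant set plus terminus parameters.

    ``terminus_hydrophobicity`` is the per-peptide contribution of the two
    chain termini to the summed hydrophobicity (kcal/mol); the octanol scale
    is a whole-residue scale and the charged ends of a free peptide prefer
    water by a fixed amount independent of composition.
    """

    records: Mapping[str, ResidueRecord]
    n_term_pka: float
    c_term_pka: float
    water_mass: float
    terminus_hydrophobicity: float = 0.0

    def __post_init__(self) -> None:
        missing = (CANONICAL_CODES | {SEC}) - set(self.records)
        if missing:
            raise ResidueTableError(
                f"residue table incomplete, missing {sorted(missing)}"
            )
        for code, rec in self.records.items():
            if code != rec.code:
                raise ResidueTableError(
                    f"key {code!r} does not match record code {rec.code!r}"
                )

    def __getitem__(self, code: str) -> ResidueRecord:
        try:
            return self.records[code]
        except KeyError:
            raise KeyError(f"unknown residue token {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.records

    @property
    def codes(self) -> set[str]:
        return set(self.records)

    def ionizable_side_chains(self) -> Iterable[ResidueRecord]:
        return (r for r in self.records.values() if r.side_chain_pka is not None)


def _parse_float(field: str) -> Optional[float]:
    field = field.strip()
    return float(field) if field else None


def _parse_charge(field: str) -> Optional[int]:
    field = field.strip()
    if not field:
        return None
    return int(field.replace("+", ""))


def load_table(path: str | Path) -> ResidueTable:
    """Load a residue table from delimited text (TSV).

    The format is one row per residue (``code  name  avg_mass  side_chain_pka
    charge_when_ionized  hydrophobicity  residue_class``, empty field =
    absent) with ``#meta key value`` lines for the terminus pKa values, water
    mass and terminus hydrophobicity.
    """
    meta: dict[str, float] = {}
    records: dict[str, ResidueRecord] = {}
    with open(path, newline="") as fh:
        rows = []
        for raw in fh:
            if raw.startswith("#meta"):
                _, key, value = raw.strip().split("\t")
                meta[key] = float(value)
                continue
            if raw.startswith("#") or not raw.strip():
                continue
            rows.append(raw)
        reader = csv.DictReader(rows, delimiter="\t")
        for row in reader:
            code = row["code"].strip()
            if code in records:
                raise ResidueTableError(f"duplicate residue code {code!r}")
            records[code] = ResidueRecord(
                code=code,
                name=row["name"].strip(),
                avg_mass=float(row["avg_mass"]),
                side_chain_pka=_parse_float(row["side_chain_pka"]),
                charge_when_ionized=_parse_charge(row["charge_when_ionized"]),
                hydrophobicity=float(row["hydrophobicity"]),
                residue_class=row["residue_class"].strip(),
            )
    try:
        return ResidueTable(
            records=records,
            n_term_pka=meta["n_term_pka"],
            c_term_pka=meta["c_term_pka"],
            water_mass=meta["water_mass"],
            terminus_hydrophobicity=meta.get("terminus_hydrophobicity", 0.0),
        )
    except KeyError as exc:  # missing #meta line
        raise ResidueTableError(f"missing table metadata: {exc}") from exc


def load_default_table() -> ResidueTable:
    """Return the packaged default table (20 canonical residues plus Sec)."""
    with resources.as_file(
        resources.files("selenopep.data").joinpath("residues.tsv")
    ) as path:
        return load_table(path)


def override_entries(
    table: ResidueTable, overrides: Mapping[str, Mapping[str, object]]
) -> ResidueTable:
    """Return a new table with per-field overrides applied to named codes.

    ``overrides`` maps residue code to a partial field dict, e.g.
    ``{"U": {"side_chain_pka": 5.43}}``. Untouched records are shared;
    record invariants are re-checked on construction.
    """
    records = dict(table.records)
    for code, fields in overrides.items():
        if code not in records:
            raise ResidueTableError(
                f"override targets unknown code {code!r}; use "
                "register_noncanonical to add new tokens"
            )
        records[code] = replace(records[code], **fields)
    return replace(table, records=records)


def register_noncanonical(
    table: ResidueTable, token: str, record: ResidueRecord
) -> ResidueTable:
    """Return a new table with an extra residue token (e.g. ``dip``).

    Peptides containing the token become parseable and computable with the
    user-supplied constants. Collisions with existing codes are refused.
    """
    if token in table.records:
        raise ResidueTableError(f"token {token!r} already registered")
    if record.code != token:
        record = replace(record, code=token)
    records = dict(table.records)
    records[token] = record
    return replace(table, records=records)
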