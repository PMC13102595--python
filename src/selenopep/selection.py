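"""Lead selection: the physicochemical filter that singles out one design.

The published filter keeps candidates that are soluble in polar solvents
(summed hydrophobicity strictly greater than +40 kcal/mol on the
polar-soluble-positive scale), carry a positive rounded net charge of at
most +4 at pH 5.5 (the median pH of human skin, the intended topical
environment), and are annotated as α-helical over most of their length.
Helix content comes from external structure prediction and is therefore a
user-supplied annotation, not something this package computes. Survivors
are ranked by hydrophobicity, then hydrophobic moment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .properties import PropertyReport, round_charge


class SelectionError(ValueError):
    """Raised for malformed selection inputs (e.g. duplicate peptide ids)."""


@dataclass(frozen=True)
class SelectionCriteria:
    min_hydrophobicity: float = 40.0  # kcal/mol, strict >
    charge_ph: float = 5.5
    charge_max: int = 4  # inclusive, on the rounded charge
    charge_min_exclusive: int = 0  # strict >, "positive net charge"
    min_helix_fraction: float = 0.5  # "most of its extension"
    min_hydrophobic_moment: Optional[float] = None  # optional, default off

    def __post_init__(self) -> None:
        if self.charge_min_exclusive >= self.charge_max:
            raise SelectionError("charge_min_exclusive must be < charge_max")


def default_criteria() -> SelectionCriteria:
    return SelectionCriteria()


@dataclass(frozen=True)
class HelixAnnotation:
    peptide_id: str
    helix_fraction: Optional[float]  # None = annotation absent
    source: str = ""

    def __post_init__(self) -> None:
        if self.helix_fraction is not None and not (
            0.0 <= self.helix_fraction <= 1.0
        ):
            raise SelectionError(
                f"{self.peptide_id}: helix_fraction must be in [0, 1]"
            )


def load_annotations(path: str | Path) -> list[HelixAnnotation]:
    """Read helix annotations from TSV (peptide_id, helix_fraction, source)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        ):
            frac = row.get("helix_fraction", "").strip()
            out.append(
                HelixAnnotation(
                    peptide_id=row["peptide_id"].strip(),
                    helix_fraction=float(frac) if frac else None,
                    source=row.get("source", "").strip(),
                )
            )
    return out


@dataclass(frozen=True)
class CriterionCheck:
    criterion: str
    passed: bool
    evaluable: bool = True
    detail: str = ""


@dataclass(frozen=True)
class CandidateVerdict:
    peptide_id: str
    checks: tuple[CriterionCheck, ...]
    hydrophobicity: float
    hydrophobic_moment: float

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, criterion: str) -> CriterionCheck:
        for c in self.checks:
            if c.criterion == criterion:
                return c
        raise KeyError(criterion)


def evaluate_candidates(
    reports: Sequence[PropertyReport],
    annotations: Iterable[HelixAnnotation] = (),
    criteria: Optional[SelectionCriteria] = None,
) -> list[CandidateVerdict]:
    """Apply the selection criteria to each property report.

    A missing helix annotation makes the helix criterion not-evaluable,
    which counts as a failure (the published filter requires demonstrated
    helicity) but is flagged as such. Pure function of its inputs.
    """
    criteria = criteria or default_criteria()
    ids = [r.peptide_id for r in reports]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SelectionError(f"duplicate peptide ids {dupes}")
    ann_map: dict[str, HelixAnnotation] = {}
    for ann in annotations:
        if ann.peptide_id in ann_map:
            raise SelectionError(f"duplicate annotation for {ann.peptide_id}")
        ann_map[ann.peptide_id] = ann

    verdicts = []
    for report in reports:
        checks = []
        hyd = report.hydrophobicity
        checks.append(
            CriterionCheck(
                "hydrophobicity",
                hyd > criteria.min_hydrophobicity,
                detail=f"{hyd:+.2f} kcal/mol, require > "
                f"{criteria.min_hydrophobicity:+.0f}",
            )
        )
        if criteria.charge_ph in report.net_charge_by_ph:
            q = report.net_charge_by_ph[criteria.charge_ph]
            qi = round_charge(q)
            checks.append(
                CriterionCheck(
                    "net_charge",
                    criteria.charge_min_exclusive < qi <= criteria.charge_max,
                    detail=f"{q:+.2f} (rounds to {qi:+d}) at pH "
                    f"{criteria.charge_ph:g}, require "
                    f"({criteria.charge_min_exclusive:+d}, "
                    f"{criteria.charge_max:+d}]",
                )
            )
        else:
            checks.append(
                CriterionCheck(
                    "net_charge", False, evaluable=False,
                    detail=f"no charge computed at pH {criteria.charge_ph:g}",
                )
            )
        ann = ann_map.get(report.peptide_id)
        if ann is None or ann.helix_fraction is None:
            checks.append(
                CriterionCheck(
                    "helix", False, evaluable=False,
                    detail="helix annotation absent",
                )
            )
        else:
            checks.append(
                CriterionCheck(
                    "helix",
                    ann.helix_fraction >= criteria.min_helix_fraction,
                    detail=f"helix fraction {ann.helix_fraction:.2f}, require "
                    f">= {criteria.min_helix_fraction:.2f}",
                )
            )
        if criteria.min_hydrophobic_moment is not None:
            mu = report.hydrophobic_moment.magnitude
            checks.append(
                CriterionCheck(
                    "hydrophobic_moment",
                    mu >= criteria.min_hydrophobic_moment,
                    detail=f"{mu:.2f} kcal/mol, require >= "
                    f"{criteria.min_hydrophobic_moment:.2f}",
                )
            )
        verdicts.append(
            CandidateVerdict(
                peptide_id=report.peptide_id,
                checks=tuple(checks),
                hydrophobicity=hyd,
                hydrophobic_moment=report.hydrophobic_moment.magnitude,
            )
        )
    return verdicts


@dataclass(frozen=True)
class SelectionResult:
    #: all-pass candidates, best first
    survivors: tuple[CandidateVerdict, ...]
    #: criterion -> number of candidates failing it
    failure_counts: dict[str, int]

    @property
    def lead(self) -> Optional[CandidateVerdict]:
        return self.survivors[0] if self.survivors else None


def select_lead(verdicts: Sequence[CandidateVerdict]) -> SelectionResult:
    """Rank all-pass candidates by (hydrophobicity, hydrophobic moment) desc.

    Ties beyond both keys break on peptide id, so the ranking is a pure,
    order-invariant function of the verdict set.
    """
    survivors = sorted(
        (v for v in verdicts if v.passed),
        key=lambda v: (-v.hydrophobicity, -v.hydrophobic_moment, v.peptide_id),
    )
    failures: dict[str, int] = {}
    for v in verdicts:
        for c in v.checks:
            if not c.passed:
                failures[c.criterion] = failures.get(c.criterion, 0) + 1
    return SelectionResult(survivors=tuple(survivors), failure_counts=failures)


def verdicts_to_tsv(verdicts: Sequence[CandidateVerdict]) -> str:
    if not verdicts:
        return ""
    crits = [c.criterion for c in verdicts[0].checks]
    lines = ["\t".join(["peptide_id", *crits, "overall"])]
    for v in verdicts:
        cells = [v.peptide_id]
        for c in v.checks:
            cells.append(
                "pass" if c.passed else ("n/e" if not c.evaluable else "fail")
            )
        cells.append("pass" if v.passed else "fail")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
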