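"""Sec-aware peptide physicochemistry.

Implements the five standard descriptors used to triage candidate
selenopeptides — average molecular weight, Henderson–Hasselbalch net charge
at arbitrary pH, isoelectric point, summed whole-residue hydrophobicity —
plus the helical-wheel layout and hydrophobic moment used to judge
amphipathicity of a putative α-helical segment.

Net charge model: every basic group (N-terminus, cationic side chains)
contributes ``+1 / (1 + 10^(pH - pKa))`` and every acidic group (C-terminus,
anionic side chains, plus the ionizable polar ones: Cys thiol, Tyr hydroxyl
and the Sec selenol) contributes ``-1 / (1 + 10^(pKa - pH))``. The sum is
strictly decreasing in pH, so the isoelectric point is its unique root on
[0, 14] and is found by bisection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .residues import ResidueTable

DEFAULT_WHEEL_ANGLE = 100.0  # degrees per residue, ideal alpha-helix
DEFAULT_PH_LIST = (7.0, 5.5)


class PeptideParseError(ValueError):
    """Raised when a raw sequence string contains unresolvable tokens."""


@dataclass(frozen=True)
class PeptideSequence:
    """A tokenized amino-acid chain; tokens may be multi-character."""

    id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise PeptideParseError(f"{self.id or 'peptide'}: empty sequence")

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        # multi-character tokens are re-emitted hyphen-delimited
        out = []
        for tok in self.tokens:
            out.append(tok if len(tok) == 1 else f"-{tok}-")
        return "".join(out).replace("--", "-")

    def count(self, token: str) -> int:
        return sum(1 for t in self.tokens if t == token)

    def positions(self, token: str) -> tuple[int, ...]:
        """1-based positions of ``token``."""
        return tuple(i + 1 for i, t in enumerate(self.tokens) if t == token)


def parse_peptide(text: str, table: ResidueTable, id: str = "") -> PeptideSequence:
    """Tokenize a raw sequence against the active residue table.

    Single letters are matched case-insensitively; declared multi-character
    tokens are recognized when hyphen-delimited (``KKWWKKW-dip-K``).
    Whitespace is ignored. Unresolvable characters raise
    :class:`PeptideParseError` naming the 1-based position.
    """
    cleaned = "".join(text.split())
    if not cleaned:
        raise PeptideParseError(f"{id or 'peptide'}: empty sequence")
    multi = {c.lower(): c for c in table.codes if len(c) > 1}
    single = {c.upper(): c for c in table.codes if len(c) == 1}
    tokens: list[str] = []
    pos = 0
    for segment in cleaned.split("-"):
        if not segment:
            continue
        if segment.lower() in multi:
            tokens.append(multi[segment.lower()])
            pos += len(segment)
            continue
        for ch in segment:
            pos += 1
            if ch.upper() not in single:
                raise PeptideParseError(
                    f"{id or 'peptide'}: unresolvable residue {ch!r} at "
                    f"position {pos}"
                )
            tokens.append(single[ch.upper()])
    return PeptideSequence(id=id, tokens=tuple(tokens))


def molecular_weight(peptide: PeptideSequence, table: ResidueTable) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    return sum(table[t].avg_mass for t in peptide.tokens) + table.water_mass


def _group_charges(
    peptide: PeptideSequence, table: ResidueTable
) -> list[tuple[float, int]]:
    """(pKa, sign) for every ionizable group including both termini."""
    groups = [(table.n_term_pka, +1), (table.c_term_pka, -1)]
    for tok in peptide.tokens:
        rec = table[tok]
        if rec.side_chain_pka is not None:
            groups.append((rec.side_chain_pka, rec.charge_when_ionized))
    return groups


def net_charge(peptide: PeptideSequence, pH: float, table: ResidueTable) -> float:
    """Henderson–Hasselbalch net charge (exact float) at a given pH."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    total = 0.0
    for pka, sign in _group_charges(peptide, table):
        if sign > 0:
            total += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return total


def round_charge(value: float) -> int:
    """Round half away from zero, the convention used for display charges."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def isoelectric_point(
    peptide: PeptideSequence, table: ResidueTable, tol: float = 1e-6
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge curve is strictly decreasing (termini guarantee one basic and
    one acidic group), so the root is unique. Converges to |charge| < tol.
    """
    lo, hi = 0.0, 14.0
    if net_charge(peptide, lo, table) < 0:
        return lo
    if net_charge(peptide, hi, table) > 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(peptide, mid, table)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def total_hydrophobicity(peptide: PeptideSequence, table: ResidueTable) -> float:
    """Summed whole-residue hydrophobicity plus the terminus contribution.

    Sign convention: larger = more hydrophilic / polar-soluble (water→octanol
    transfer free energy).
    """
    return (
        sum(table[t].hydrophobicity for t in peptide.tokens)
        + table.terminus_hydrophobicity
    )


@dataclass(frozen=True)
class WheelPosition:
    position: int  # 1-based position in the full chain
    token: str
    angle: float  # degrees, mod 360
    residue_class: str


def _check_window(
    peptide: PeptideSequence, window: Optional[tuple[int, int]]
) -> tuple[int, int]:
    if window is None:
        return 1, len(peptide)
    start, end = window
    if not (1 <= start <= end <= len(peptide)):
        raise ValueError(
            f"window {window} out of bounds for {len(peptide)}-mer "
            "(1-based inclusive)"
        )
    return start, end


def helical_wheel_layout(
    peptide: PeptideSequence,
    table: ResidueTable,
    window: Optional[tuple[int, int]] = None,
    rotation_angle: float = DEFAULT_WHEEL_ANGLE,
) -> list[WheelPosition]:
    """Place windowed residues on an ideal helical wheel.

    Residue *i* (0-indexed within the 1-based inclusive window) sits at
    ``i * rotation_angle mod 360`` degrees and carries its residue-class
    label for plotting.
    """
    start, end = _check_window(peptide, window)
    layout = []
    for i, pos in enumerate(range(start, end + 1)):
        tok = peptide.tokens[pos - 1]
        layout.append(
            WheelPosition(
                position=pos,
                token=tok,
                angle=(i * rotation_angle) % 360.0,
                residue_class=table[tok].residue_class,
            )
        )
    return layout


@dataclass(frozen=True)
class HydrophobicMoment:
    magnitude: float  # kcal/mol
    direction: float  # degrees on the wheel, points to the hydrophobic face
    window: tuple[int, int]


def hydrophobic_moment(
    peptide: PeptideSequence,
    table: ResidueTable,
    window: Optional[tuple[int, int]] = None,
    rotation_angle: float = DEFAULT_WHEEL_ANGLE,
) -> HydrophobicMoment:
    """Vector sum of per-residue hydrophobicities on the helical wheel.

    The shipped scale is hydrophilicity-positive, so values are negated
    before summing: the resulting arrow points toward the apolar face, as
    conventionally drawn on helical-wheel diagrams.
    """
    start, end = _check_window(peptide, window)
    x = y = 0.0
    for i, pos in enumerate(range(start, end + 1)):
        h = -table[peptide.tokens[pos - 1]].hydrophobicity
        theta = math.radians((i * rotation_angle) % 360.0)
        x += h * math.cos(theta)
        y += h * math.sin(theta)
    direction = math.degrees(math.atan2(y, x)) % 360.0
    if direction >= 360.0:  # guard the -0.0 wrap
        direction = 0.0
    return HydrophobicMoment(
        magnitude=math.hypot(x, y),
        direction=direction,
        window=(start, end),
    )


@dataclass(frozen=True)
class PropertyReport:
    """One property-table row for a peptide (plus the amphipathicity vector)."""

    peptide_id: str
    length: int
    molecular_weight: float
    net_charge_by_ph: dict[float, float]
    rounded_charge_by_ph: dict[float, int]
    isoelectric_point: float
    hydrophobicity: float
    hydrophobic_moment: HydrophobicMoment

    def to_dict(self) -> dict:
        d = {
            "peptide_id": self.peptide_id,
            "length": self.length,
            "molecular_weight": round(self.molecular_weight, 2),
            "isoelectric_point": round(self.isoelectric_point, 2),
            "hydrophobicity": round(self.hydrophobicity, 2),
            "hydrophobic_moment": round(self.hydrophobic_moment.magnitude, 2),
            "moment_direction": round(self.hydrophobic_moment.direction, 1),
            "moment_window": list(self.hydrophobic_moment.window),
        }
        for ph, q in self.net_charge_by_ph.items():
            d[f"net_charge_pH{ph:g}"] = self.rounded_charge_by_ph[ph]
            d[f"net_charge_pH{ph:g}_exact"] = round(q, 4)
        return d


def property_report(
    peptide: PeptideSequence,
    table: ResidueTable,
    ph_list: Sequence[float] = DEFAULT_PH_LIST,
    moment_window: Optional[tuple[int, int]] = None,
    rotation_angle: float = DEFAULT_WHEEL_ANGLE,
) -> PropertyReport:
    """Aggregate all descriptors into one report row. Deterministic."""
    charges = {ph: net_charge(peptide, ph, table) for ph in ph_list}
    return PropertyReport(
        peptide_id=peptide.id,
        length=len(peptide),
        molecular_weight=molecular_weight(peptide, table),
        net_charge_by_ph=charges,
        rounded_charge_by_ph={ph: round_charge(q) for ph, q in charges.items()},
        isoelectric_point=isoelectric_point(peptide, table),
        hydrophobicity=total_hydrophobicity(peptide, table),
        hydrophobic_moment=hydrophobic_moment(
            peptide, table, moment_window, rotation_angle
        ),
    )


def reports_to_tsv(reports: Iterable[PropertyReport]) -> str:
    """Render reports as TSV, one row per peptide."""
    reports = list(reports)
    if not reports:
        return ""
    rows = [r.to_dict() for r in reports]
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"


def reports_to_json(reports: Iterable[PropertyReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)


def plot_helical_wheel(
    peptide: PeptideSequence,
    table: ResidueTable,
    window: Optional[tuple[int, int]] = None,
    rotation_angle: float = DEFAULT_WHEEL_ANGLE,
    path: Optional[str] = None,
):
    """Cosmetic helical-wheel plot with the hydrophobic-moment arrow.

    Requires matplotlib; returns the figure. Untested bit-exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "cationic": "#1f77b4",
        "anionic": "#d62728",
        "polar": "#2ca02c",
        "hydrophobic": "#7f7f7f",
        "special": "#ff7f0e",
    }
    layout = helical_wheel_layout(peptide, table, window, rotation_angle)
    moment = hydrophobic_moment(peptide, table, window, rotation_angle)
    fig, ax = plt.subplots(figsize=(5, 5))
    for wp in layout:
        theta = math.radians(wp.angle)
        x, y = math.cos(theta), math.sin(theta)
        ax.scatter([x], [y], s=600, color=colors[wp.residue_class], zorder=2)
        ax.annotate(
            f"{wp.token}{wp.position}", (x, y), ha="center", va="center",
            color="white", fontsize=8, zorder=3,
        )
    if moment.magnitude > 0:
        theta = math.radians(moment.direction)
        ax.annotate(
            "", xy=(0.6 * math.cos(theta), 0.6 * math.sin(theta)),
            xytext=(0, 0), arrowprops=dict(arrowstyle="->", lw=2),
        )
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{peptide.id} wheel {moment.window[0]}–{moment.window[1]}")
    if path:
        fig.savefig(path)
    return fig
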