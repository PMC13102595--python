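"""End-to-end pipeline: design validation -> properties -> selection -> cloning.

Wires the stages together around file-based inputs (FASTA templates, YAML
rules/criteria, TSV residue table and helix annotations) and emits a
reproducible report bundle: property tables (TSV + JSON), rule verdicts,
the ranked survivor list, optional construct artifacts, and a run log
recording the seed, package version and input checksums. Reruns with the
same config and seed are byte-identical apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .cloning import (
    DNAPart, add_affixes, assemble_insert, back_translate,
    default_codon_table, digest_and_ligate, serialize_construct,
)
from .design import DesignRuleSet, default_rules, validate_design
from .properties import (
    PeptideSequence, parse_peptide, property_report, reports_to_json,
    reports_to_tsv,
)
from .residues import ResidueTable, load_default_table, load_table
from .selection import (
    HelixAnnotation, SelectionCriteria, default_criteria, evaluate_candidates,
    load_annotations, select_lead, verdicts_to_tsv,
)
from .synthetic import PartSetSpec, gen_dna_parts, selera_fixture


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass(frozen=True)
class PipelineConfig:
    templates: Optional[Path] = None  # FASTA; None = packaged Selera bundle
    rules: Optional[Path] = None  # YAML DesignRuleSet overrides
    criteria: Optional[Path] = None  # YAML SelectionCriteria overrides
    residue_table: Optional[Path] = None  # TSV; None = packaged default
    annotations: Optional[Path] = None  # TSV helix annotations
    out_dir: Path = Path("selenopep-out")
    seed: int = 0
    run_cloning: bool = False
    strict: bool = False

    def resolve_paths(self) -> None:
        for name in ("templates", "rules", "criteria", "residue_table",
                     "annotations"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} path {p} does not exist")


def read_fasta_peptides(path: Path, table: ResidueTable) -> list[PeptideSequence]:
    """Parse a peptide FASTA (plain text, U accepted) against the table."""
    peptides = []
    rid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if rid is not None:
                    peptides.append(parse_peptide("".join(chunks), table, id=rid))
                rid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if rid is not None:
        peptides.append(parse_peptide("".join(chunks), table, id=rid))
    return peptides


def _load_rules(path: Optional[Path]) -> DesignRuleSet:
    if path is None:
        return default_rules()
    data = yaml.safe_load(Path(path).read_text()) or {}
    base = default_rules()
    kwargs = {}
    for fname in ("length_range", "sec_count_range", "net_charge_range"):
        if fname in data:
            kwargs[fname] = tuple(data[fname])
    for fname in ("sec_zone_fraction", "charge_ph", "linker"):
        if fname in data:
            kwargs[fname] = data[fname]
    if "allowed_cationic" in data:
        kwargs["allowed_cationic"] = frozenset(data["allowed_cationic"])
    return DesignRuleSet(**{**base.__dict__, **kwargs})


def _load_criteria(path: Optional[Path]) -> SelectionCriteria:
    if path is None:
        return default_criteria()
    data = yaml.safe_load(Path(path).read_text()) or {}
    base = default_criteria()
    return SelectionCriteria(**{**base.__dict__, **data})


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    seed: int
    peptides: list[PeptideSequence]
    verdicts: list
    reports: list
    selection: object
    construct_lengths: dict[str, int] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    config.resolve_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    table = (
        load_table(config.residue_table)
        if config.residue_table
        else load_default_table()
    )
    rules = _load_rules(config.rules)
    criteria = _load_criteria(config.criteria)
    if config.templates:
        peptides = read_fasta_peptides(Path(config.templates), table)
        annotations: list[HelixAnnotation] = (
            load_annotations(config.annotations) if config.annotations else []
        )
    else:
        fixture = selera_fixture()
        peptides = [
            parse_peptide(seq, table, id=name)
            for name, seq in fixture.designs.items()
        ]
        annotations = [
            HelixAnnotation(pid, frac, source="packaged")
            for pid, frac in fixture.helix_annotations.items()
        ]
    if not peptides:
        raise PipelineError("design stage: no input peptides")

    # --- design validation ------------------------------------------------
    verdicts = [validate_design(p, rules, table) for p in peptides]
    with open(out / "design_verdicts.tsv", "w") as fh:
        rules_order = [c.rule for c in verdicts[0].checks]
        fh.write("\t".join(["peptide_id", *rules_order, "overall"]) + "\n")
        for v in verdicts:
            cells = [v.peptide_id]
            cells += ["pass" if c.passed else "fail" for c in v.checks]
            cells.append("pass" if v.passed else "fail")
            fh.write("\t".join(cells) + "\n")

    # --- properties -------------------------------------------------------
    ph_list = sorted({7.0, 5.5, rules.charge_ph, criteria.charge_ph})
    reports = [property_report(p, table, ph_list=ph_list) for p in peptides]
    (out / "properties.tsv").write_text(reports_to_tsv(reports))
    (out / "properties.json").write_text(reports_to_json(reports))

    # --- selection --------------------------------------------------------
    sel_verdicts = evaluate_candidates(reports, annotations, criteria)
    selection = select_lead(sel_verdicts)
    (out / "selection.tsv").write_text(verdicts_to_tsv(sel_verdicts))

    # --- cloning (optional) -----------------------------------------------
    construct_lengths: dict[str, int] = {}
    if config.run_cloning:
        lead = selection.lead
        if lead is None:
            raise PipelineError("cloning stage: no lead selected")
        lead_pep = next(p for p in peptides if p.id == lead.peptide_id)
        codon_table = default_codon_table()
        cds = back_translate(lead_pep, codon_table, mode="argmax")
        parts = gen_dna_parts(
            PartSetSpec(
                roles=(
                    ("promoter", 35, 60), ("rbs", 12, 20),
                    ("terminator", 40, 80), ("backbone", 1800, 2500),
                ),
                notI_policy="forbid",
                seed=config.seed,
            )
        )
        by_role = {p.role: p for p in parts}
        cds_part = DNAPart(
            id=f"{lead_pep.id}-cds", role="cds", sequence=cds,
            secis_note="SECIS assumed within the CDS 3' region",
        )
        insert = assemble_insert(
            [by_role["promoter"], by_role["rbs"], cds_part, by_role["terminator"]],
            id="expression-insert", strict=config.strict,
        )
        cassette = add_affixes(insert)
        backbone_raw = by_role["backbone"]
        from .cloning import Construct
        backbone = Construct(
            id="backbone",
            parts=(
                DNAPart(id="bb-core", role="backbone",
                        sequence=backbone_raw.sequence),
                DNAPart(id="bb-site", role="other", sequence="GCGGCCGC"),
            ),
            topology="circular",
        )
        plasmid = digest_and_ligate(backbone, cassette, id="expression-plasmid")
        serialize_construct(plasmid, out / "plasmid.gb", "genbank")
        serialize_construct(plasmid, out / "plasmid.fasta", "fasta")
        construct_lengths = {
            "cds": len(cds), "insert": len(insert),
            "cassette": len(cassette), "plasmid": len(plasmid),
        }

    # --- run log ----------------------------------------------------------
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            name: (_sha256(p) if (p := getattr(config, name)) else "packaged")
            for name in ("templates", "rules", "criteria", "residue_table",
                         "annotations")
        },
        "n_peptides": len(peptides),
        "n_survivors": len(selection.survivors),
        "lead": selection.lead.peptide_id if selection.lead else None,
        "construct_lengths": construct_lengths,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))

    bundle = ReportBundle(
        out_dir=out, seed=config.seed, peptides=peptides, verdicts=verdicts,
        reports=reports, selection=selection,
        construct_lengths=construct_lengths,
        files=sorted(f.name for f in out.iterdir()),
    )
    (out / "summary.md").write_text(render_report(bundle))
    return bundle


def render_report(bundle: ReportBundle) -> str:
    """One-page human-readable summary of a report bundle."""
    lines = ["# Selenopeptide pipeline summary", ""]
    lines.append(f"seed: {bundle.seed}")
    lines.append(f"candidates: {len(bundle.peptides)}")
    if not bundle.peptides:
        lines.append("no candidates")
        return "\n".join(lines) + "\n"
    lines.append("")
    lines.append("| peptide | length | MW (Da) | pI | hydrophobicity | rules |")
    lines.append("|---|---|---|---|---|---|")
    verdict_by_id = {v.peptide_id: v for v in bundle.verdicts}
    for r in bundle.reports:
        v = verdict_by_id.get(r.peptide_id)
        rule_str = (
            "all pass" if v and v.passed
            else ("fails: " + ", ".join(v.failed_rules) if v else "-")
        )
        lines.append(
            f"| {r.peptide_id} | {r.length} | {r.molecular_weight:.2f} | "
            f"{r.isoelectric_point:.2f} | {r.hydrophobicity:+.2f} | {rule_str} |"
        )
    lines.append("")
    sel = bundle.selection
    if sel.survivors:
        lines.append(
            "lead: **" + sel.survivors[0].peptide_id + "** "
            f"({len(sel.survivors)} survivor(s))"
        )
    else:
        lines.append("no candidates survived selection")
        if sel.failure_counts:
            lines.append(
                "failures per criterion: "
                + ", ".join(f"{k}={v}" for k, v in sorted(sel.failure_counts.items()))
            )
    if bundle.construct_lengths:
        lines.append("")
        lines.append(
            "construct lengths (bp): "
            + ", ".join(f"{k}={v}" for k, v in bundle.construct_lengths.items())
        )
    return "\n".join(lines) + "\n"
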