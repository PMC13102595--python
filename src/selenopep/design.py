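"""Rule-based generation and validation of selenopeptide candidates.

The design rules encode the published criteria for grafting selenocysteine
and cationic residues onto antioxidant/anti-tumoral peptide templates:
chain length 12–35, one to four Sec residues confined to the mid/C-terminal
region (operationalized as the final two-thirds of the chain — Sec codons
near the 3' end keep them close to the SECIS element), a net-charge window
of +1 to +4 at the design pH, and insertions restricted to the cationic set
{R, K, H}. The engine generalizes the hand-crafted published designs: it
can validate any candidate rule-by-rule and enumerate valid variants of a
template, but is not meant to re-derive the published sequences uniquely.

Edit model: a candidate carries an ordered edit log (substitutions and
insertions, 1-based positions evaluated against the sequence state at
application time, emitted in ascending final position so replay is
unambiguous). Replaying the log on the template must reproduce the
candidate exactly.
"""

from __future__ import annotations

import itertools
import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .properties import PeptideSequence, net_charge, round_charge
from .residues import SEC, ResidueTable


class DesignError(ValueError):
    """Raised when a requested design move is infeasible; names the rule."""


@dataclass(frozen=True)
class DesignRuleSet:
    length_range: tuple[int, int] = (12, 35)
    sec_count_range: tuple[int, int] = (1, 4)
    #: fraction of the chain (from the N-terminus) where Sec is disallowed
    sec_zone_fraction: float = 1.0 / 3.0
    #: inclusive net-charge window, applied at charge_ph
    net_charge_range: tuple[int, int] = (1, 4)
    charge_ph: float = 7.0
    allowed_cationic: frozenset[str] = frozenset({"R", "K", "H"})
    linker: str = "GGGGS"

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1]:
            raise DesignError("length_range min > max")
        if self.sec_count_range[0] > self.sec_count_range[1]:
            raise DesignError("sec_count_range min > max")
        if not 0.0 <= self.sec_zone_fraction < 1.0:
            raise DesignError("sec_zone_fraction must be in [0, 1)")
        if self.net_charge_range[0] > self.net_charge_range[1]:
            raise DesignError("net_charge_range min > max")

    def zone_start(self, length: int) -> int:
        """First 1-based position at which Sec is allowed for a given length."""
        return math.ceil(length * self.sec_zone_fraction) + 1


def default_rules() -> DesignRuleSet:
    """The published rule set with the net-charge bounds read inclusively."""
    return DesignRuleSet()


@dataclass(frozen=True)
class Edit:
    kind: str  # "substitute" | "insert"
    position: int  # 1-based; for inserts, the residue's final position
    residue: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitute", "insert"):
            raise DesignError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise DesignError("edit position must be >= 1")


def apply_edits(
    template_tokens: Sequence[str], edits: Sequence[Edit]
) -> tuple[str, ...]:
    """Replay an edit log on template tokens.

    Edits are applied in order; each position refers to the sequence state
    at the time of application (insert = place the residue *at* that
    position, shifting the tail right; position len+1 appends).
    """
    tokens = list(template_tokens)
    for e in edits:
        if e.kind == "substitute":
            if e.position > len(tokens):
                raise DesignError(f"substitution at {e.position} beyond chain end")
            tokens[e.position - 1] = e.residue
        else:
            if e.position > len(tokens) + 1:
                raise DesignError(f"insertion at {e.position} beyond chain end+1")
            tokens.insert(e.position - 1, e.residue)
    return tuple(tokens)


@dataclass(frozen=True)
class CandidateVariant:
    peptide: PeptideSequence
    template_id: str
    edit_log: tuple[Edit, ...]
    template_tokens: tuple[str, ...] = ()

    def replay_matches(self) -> bool:
        if not self.template_tokens:
            return True
        return apply_edits(self.template_tokens, self.edit_log) == self.peptide.tokens


def _edit_id(template_id: str, edits: Sequence[Edit]) -> str:
    tag = ".".join(f"{e.kind[0]}{e.position}{e.residue}" for e in edits)
    return f"{template_id}~{tag}" if tag else template_id


def _make_variant(
    template: PeptideSequence, edits: Sequence[Edit]
) -> CandidateVariant:
    edits = tuple(edits)
    tokens = apply_edits(template.tokens, edits)
    return CandidateVariant(
        peptide=PeptideSequence(id=_edit_id(template.id, edits), tokens=tokens),
        template_id=template.id,
        edit_log=edits,
        template_tokens=template.tokens,
    )


def insert_selenocysteines(
    template: PeptideSequence,
    count: int,
    rules: DesignRuleSet,
    strategy: str = "substitute_cysteine",
    seed: int = 0,
    max_variants: int = 10000,
) -> list[CandidateVariant]:
    """Enumerate variants carrying exactly ``count`` Sec residues in-zone.

    Strategies: ``substitute_cysteine`` replaces existing in-zone Cys tokens
    (the published Cys→Sec pattern); ``insert_at_positions`` enumerates
    in-zone insertion slots; ``random_in_zone`` draws a seeded random mix of
    both moves. The allowed zone starts at ``rules.zone_start(len(template))``
    — mid/C-terminal positions of the *template* the design starts from.
    Output is lexicographic by (position, residue); deterministic given seed.
    """
    lo, hi = rules.sec_count_range
    if not lo <= count <= hi:
        raise DesignError(
            f"sec_count rule: requested {count} Sec outside [{lo}, {hi}]"
        )
    zone = rules.zone_start(len(template))
    variants: list[CandidateVariant] = []
    if strategy == "substitute_cysteine":
        in_zone_cys = [p for p in template.positions("C") if p >= zone]
        if len(in_zone_cys) < count:
            raise DesignError(
                f"sec_zone rule: only {len(in_zone_cys)} in-zone Cys available "
                f"for {count} substitutions (zone starts at {zone})"
            )
        for combo in itertools.combinations(in_zone_cys, count):
            variants.append(
                _make_variant(
                    template,
                    [Edit("substitute", p, SEC) for p in combo],
                )
            )
            if len(variants) >= max_variants:
                break
    elif strategy == "insert_at_positions":
        # gap g inserts before template position g+1; after inserting at
        # ascending gaps g_1 < ... < g_k the i-th Sec lands at g_i + i,
        # so in-zone requires g >= zone - 1 for every gap
        gaps = range(zone - 1, len(template) + 1)
        for combo in itertools.combinations(gaps, count):
            edits = [
                Edit("insert", g + i + 1, SEC) for i, g in enumerate(combo)
            ]
            variants.append(_make_variant(template, edits))
            if len(variants) >= max_variants:
                break
    elif strategy == "random_in_zone":
        rng = random.Random(seed)
        seen = set()
        for _ in range(max(20, 4 * count) * 10):
            if len(variants) >= min(max_variants, 20):
                break
            edits = []
            tokens = list(template.tokens)
            for i in range(count):
                if rng.random() < 0.5 and any(
                    t == "C" and p + 1 >= zone for p, t in enumerate(tokens)
                ):
                    cpos = [
                        p + 1 for p, t in enumerate(tokens)
                        if t == "C" and p + 1 >= zone
                    ]
                    pos = rng.choice(cpos)
                    edits.append(Edit("substitute", pos, SEC))
                    tokens[pos - 1] = SEC
                else:
                    pos = rng.randint(zone, len(tokens) + 1)
                    edits.append(Edit("insert", pos, SEC))
                    tokens.insert(pos - 1, SEC)
            key = tuple(tokens)
            if key not in seen:
                seen.add(key)
                variants.append(_make_variant(template, edits))
    else:
        raise DesignError(f"unknown strategy {strategy!r}")
    if not variants:
        raise DesignError(
            f"sec insertion produced no variants for strategy {strategy!r}"
        )
    variants.sort(key=lambda v: [(e.position, e.residue) for e in v.edit_log])
    return variants


def insert_cationic_residues(
    template: PeptideSequence,
    count: int,
    rules: DesignRuleSet,
    seed: int = 0,
    residues: Optional[Sequence[str]] = None,
    max_variants: int = 10000,
) -> list[CandidateVariant]:
    """Enumerate variants with ``count`` cationic residues inserted.

    Inserted residues are drawn only from ``rules.allowed_cationic``;
    anything else is rejected. The resulting length must respect the length
    rule. Lexicographic by (position, residue); deterministic given seed.
    """
    pool = sorted(residues if residues is not None else rules.allowed_cationic)
    bad = [r for r in pool if r not in rules.allowed_cationic]
    if bad:
        raise DesignError(
            f"cationic_insertions rule: {bad} not in allowed set "
            f"{sorted(rules.allowed_cationic)}"
        )
    if len(template) + count > rules.length_range[1]:
        raise DesignError(
            f"length rule: {len(template)} + {count} insertions exceeds "
            f"maximum {rules.length_range[1]}"
        )
    variants = []
    positions = range(1, len(template) + 2)
    for combo in itertools.combinations(positions, count):
        for picks in itertools.product(pool, repeat=count):
            edits = [
                Edit("insert", p + i, r)
                for i, (p, r) in enumerate(zip(combo, picks))
            ]
            variants.append(_make_variant(template, edits))
            if len(variants) >= max_variants:
                break
        if len(variants) >= max_variants:
            break
    variants.sort(key=lambda v: [(e.position, e.residue) for e in v.edit_log])
    return variants


def build_repeat_construct(
    core: PeptideSequence, n_repeats: int, linker: str = "GGGGS"
) -> PeptideSequence:
    """Join ``n_repeats`` copies of the core with (n-1) linkers.

    Length is n*|core| + (n-1)*|linker| — the fusion-linker architecture of
    the published triple-domain design.
    """
    if n_repeats < 1:
        raise DesignError("n_repeats must be >= 1")
    linker_tokens = tuple(linker)
    tokens: tuple[str, ...] = ()
    for i in range(n_repeats):
        if i:
            tokens += linker_tokens
        tokens += core.tokens
    return PeptideSequence(id=f"{core.id}x{n_repeats}", tokens=tokens)


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class DesignVerdict:
    peptide_id: str
    checks: tuple[RuleCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, rule: str) -> RuleCheck:
        for c in self.checks:
            if c.rule == rule:
                return c
        raise KeyError(rule)

    @property
    def failed_rules(self) -> tuple[str, ...]:
        return tuple(c.rule for c in self.checks if not c.passed)


def validate_design(
    candidate: CandidateVariant | PeptideSequence,
    rules: DesignRuleSet,
    table: ResidueTable,
) -> DesignVerdict:
    """Check a candidate rule-by-rule; violations are verdicts, not errors.

    The Sec-zone check uses the template length when the candidate carries
    one (insertions are measured against the chain the design started from)
    and the candidate's own length for bare sequences. Discrepancies in
    published designs — such as an N-terminal Sec — are reported with their
    positions, never silently passed.
    """
    if isinstance(candidate, PeptideSequence):
        candidate = CandidateVariant(
            peptide=candidate, template_id="", edit_log=()
        )
    pep = candidate.peptide
    checks = []

    n = len(pep)
    lo, hi = rules.length_range
    checks.append(
        RuleCheck("length", lo <= n <= hi, f"{n} residues, window [{lo}, {hi}]")
    )

    sec_positions = pep.positions(SEC)
    lo, hi = rules.sec_count_range
    checks.append(
        RuleCheck(
            "sec_count",
            lo <= len(sec_positions) <= hi,
            f"{len(sec_positions)} Sec at {sec_positions}, window [{lo}, {hi}]",
        )
    )

    ref_len = len(candidate.template_tokens) or n
    zone = rules.zone_start(ref_len)
    out_of_zone = tuple(p for p in sec_positions if p < zone)
    checks.append(
        RuleCheck(
            "sec_zone",
            not out_of_zone,
            f"zone starts at {zone}; out-of-zone Sec at {out_of_zone}"
            if out_of_zone
            else f"all Sec at or beyond position {zone}",
        )
    )

    q = net_charge(pep, rules.charge_ph, table)
    qi = round_charge(q)
    lo, hi = rules.net_charge_range
    checks.append(
        RuleCheck(
            "net_charge",
            lo <= qi <= hi,
            f"{q:+.2f} (rounds to {qi:+d}) at pH {rules.charge_ph:g}, "
            f"window [{lo:+d}, {hi:+d}] inclusive",
        )
    )

    bad_inserts = tuple(
        (e.position, e.residue)
        for e in candidate.edit_log
        if e.kind == "insert"
        and e.residue not in rules.allowed_cationic
        and e.residue != SEC
    )
    checks.append(
        RuleCheck(
            "cationic_insertions",
            not bad_inserts,
            f"non-cationic insertions {bad_inserts}"
            if bad_inserts
            else "all insertions from the cationic set or Sec",
        )
    )
    return DesignVerdict(peptide_id=pep.id, checks=tuple(checks))


@dataclass(frozen=True)
class GenerationResult:
    candidates: tuple[CandidateVariant, ...]
    #: rule -> number of enumerated variants that failed it
    failure_counts: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def generate_variants(
    template: PeptideSequence,
    rules: DesignRuleSet,
    table: ResidueTable,
    budget: int = 50,
    seed: int = 0,
    sec_counts: Optional[Sequence[int]] = None,
    cationic_counts: Sequence[int] = (0, 1),
    max_enumeration: int = 20000,
) -> GenerationResult:
    """Enumerate, validate and sample candidate variants of a template.

    Composition: Sec edits (both substitution and insertion strategies, for
    every count in ``sec_counts``, default the full allowed range) optionally
    followed by cationic insertions. Candidates failing any rule are
    dropped and tallied; survivors are deduplicated by sequence, ordered
    lexicographically by edit log, seeded-shuffled, and truncated to
    ``budget``. Deterministic given (inputs, seed).
    """
    if budget < 1:
        raise DesignError("budget must be >= 1")
    if sec_counts is None:
        sec_counts = range(rules.sec_count_range[0], rules.sec_count_range[1] + 1)

    sec_variants: list[CandidateVariant] = []
    for count in sec_counts:
        for strategy in ("substitute_cysteine", "insert_at_positions"):
            try:
                sec_variants.extend(
                    insert_selenocysteines(
                        template, count, rules, strategy, seed,
                        max_variants=max_enumeration,
                    )
                )
            except DesignError:
                continue
        if len(sec_variants) >= max_enumeration:
            break

    pool: list[CandidateVariant] = []
    for var in sec_variants:
        for c_count in cationic_counts:
            if c_count == 0:
                pool.append(var)
                continue
            try:
                augmented = insert_cationic_residues(
                    var.peptide, c_count, rules, seed,
                    max_variants=max(1, (max_enumeration - len(pool))
                                     // max(1, len(sec_variants))),
                )
            except DesignError:
                continue
            for aug in augmented:
                pool.append(
                    CandidateVariant(
                        peptide=aug.peptide,
                        template_id=template.id,
                        edit_log=var.edit_log + aug.edit_log,
                        template_tokens=template.tokens,
                    )
                )
        if len(pool) >= max_enumeration:
            break

    failures: Counter[str] = Counter()
    seen: set[tuple[str, ...]] = set()
    valid: list[CandidateVariant] = []
    for var in pool:
        verdict = validate_design(var, rules, table)
        if not verdict.passed:
            failures.update(verdict.failed_rules)
            continue
        if var.peptide.tokens in seen:
            continue
        seen.add(var.peptide.tokens)
        valid.append(var)

    valid.sort(key=lambda v: [(e.position, e.residue) for e in v.edit_log])
    rng = random.Random(seed)
    rng.shuffle(valid)
    return GenerationResult(
        candidates=tuple(valid[:budget]), failure_counts=dict(failures)
    )
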