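"""Position-specific rules for cooperative homeodomain binding on P3 sites.

The classifier encodes residue requirements at 11 HD positions that govern
whether a homeodomain can form a cooperative dimer on the palindromic
TAAT-NNN-ATTA (P3) site. Eight rules are *critical* (violating any one
abolishes cooperativity) and three are *contributory* (violations reduce
the magnitude of cooperativity without abolishing it). Each rule either
requires a residue set at a position ("must be") or forbids one ("cannot
be"). Positions not covered by any rule never affect classification.

Rule sets are plain data: the packaged default can be dumped to and loaded
from YAML so users can amend it as the field evolves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .sequences import HD_LENGTH, HDSequence, _RESIDUE_SET

Mode = Literal["require", "forbid"]
Importance = Literal["critical", "contributory"]

#: Residue classes used in family censuses.
BRANCHED_HYDROPHOBIC = frozenset("VIL")


@dataclass(frozen=True)
class CooperativityRule:
    hd_position: int
    mode: Mode
    residues: frozenset[str]
    importance: Importance
    rationale: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.hd_position <= HD_LENGTH:
            raise ValueError(f"rule position {self.hd_position} out of range 1-{HD_LENGTH}")
        if self.mode not in ("require", "forbid"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.importance not in ("critical", "contributory"):
            raise ValueError(f"unknown rule importance {self.importance!r}")
        if not self.residues or not self.residues <= _RESIDUE_SET:
            raise ValueError("rule residues must be a nonempty subset of the canonical 20")
        object.__setattr__(self, "residues", frozenset(self.residues))

    def passes(self, residue: str) -> bool:
        """Whether ``residue`` satisfies this rule."""
        inside = residue in self.residues
        return inside if self.mode == "require" else not inside

    def describe(self) -> str:
        res = "/".join(sorted(self.residues))
        verb = "must be" if self.mode == "require" else "cannot be"
        return f"position {self.hd_position} {verb} {res} ({self.importance})"


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[CooperativityRule, ...]

    def __post_init__(self) -> None:
        positions = [r.hd_position for r in self.rules]
        if len(set(positions)) != len(positions):
            raise ValueError("rule positions must be unique within a ruleset")
        object.__setattr__(self, "rules", tuple(self.rules))

    def by_position(self, hd_position: int) -> CooperativityRule | None:
        for r in self.rules:
            if r.hd_position == hd_position:
                return r
        return None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(r.hd_position for r in self.rules)

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "position": r.hd_position,
                "mode": r.mode,
                "residues": sorted(r.residues),
                "importance": r.importance,
                "rationale": r.rationale,
            }
            for r in self.rules
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, list):
            raise ValueError(f"{path}: ruleset YAML must be a list of rules")
        return cls(
            tuple(
                CooperativityRule(
                    hd_position=int(entry["position"]),
                    mode=entry["mode"],
                    residues=frozenset(entry["residues"]),
                    importance=entry["importance"],
                    rationale=entry.get("rationale", ""),
                )
                for entry in data
            )
        )


def default_ruleset() -> RuleSet:
    """The 11 packaged P3-site cooperativity rules (8 critical, 3 contributory)."""
    r = CooperativityRule
    return RuleSet(
        (
            r(2, "require", frozenset("R"), "contributory",
              "R2 supports either the dimer interface or minor-groove insertion"),
            r(3, "require", frozenset("R"), "critical",
              "R3 is needed for the dimer interface or minor-groove insertion"),
            r(4, "forbid", frozenset("E"), "contributory",
              "E4 clashes electrostatically with E32 of the partner chain"),
            r(26, "require", frozenset("P"), "critical",
              "branched residues cannot pack in the narrow helix-1/helix-2 core"),
            r(28, "forbid", frozenset("R"), "critical",
              "R28 clashes with the basic N-terminal arm of the partner"),
            r(32, "require", frozenset("E"), "critical",
              "E32 hydrogen-bonds/salt-bridges to the partner's N-terminal arm"),
            r(42, "require", frozenset("E"), "critical",
              "E42 forms a salt bridge with R3 of the partner"),
            r(43, "forbid", frozenset("R"), "critical",
              "R43 clashes where the two recognition helices meet"),
            r(44, "forbid", frozenset("Q"), "critical",
              "Q44 cannot maintain the water-mediated hydrogen bond with E42"),
            r(46, "forbid", frozenset("RK"), "critical",
              "a basic residue at 46 clashes with R3 of the partner arm"),
            r(50, "forbid", frozenset("K"), "contributory",
              "K50 homeodomains show uniformly low cooperativity (mechanism unknown)"),
        )
    )


@dataclass(frozen=True)
class RuleVerdict:
    rule: CooperativityRule
    observed: str
    passed: bool


@dataclass(frozen=True)
class RuleEvaluation:
    """Per-rule verdicts for one sequence."""

    seq_id: str
    verdicts: tuple[RuleVerdict, ...]

    @property
    def violations(self) -> tuple[RuleVerdict, ...]:
        return tuple(v for v in self.verdicts if not v.passed)

    @property
    def violated_critical(self) -> tuple[RuleVerdict, ...]:
        return tuple(v for v in self.violations if v.rule.importance == "critical")

    @property
    def violated_contributory(self) -> tuple[RuleVerdict, ...]:
        return tuple(v for v in self.violations if v.rule.importance == "contributory")


Category = Literal["compliant", "contributory_conflict", "critical_conflict"]


@dataclass(frozen=True)
class ClassificationResult:
    category: Category
    evaluation: RuleEvaluation


def evaluate_rules(seq: HDSequence, rules: RuleSet) -> RuleEvaluation:
    """Evaluate every rule against the sequence; verdict order follows the ruleset."""
    verdicts = tuple(
        RuleVerdict(rule=r, observed=seq.residue_at(r.hd_position),
                    passed=r.passes(seq.residue_at(r.hd_position)))
        for r in rules.rules
    )
    return RuleEvaluation(seq_id=seq.id, verdicts=verdicts)


def classify(seq: HDSequence, rules: RuleSet) -> ClassificationResult:
    """Map rule verdicts to compliant / contributory_conflict / critical_conflict."""
    ev = evaluate_rules(seq, rules)
    if ev.violated_critical:
        category: Category = "critical_conflict"
    elif ev.violated_contributory:
        category = "contributory_conflict"
    else:
        category = "compliant"
    return ClassificationResult(category=category, evaluation=ev)


Scope = Literal["critical_only", "all_rules"]


def min_changes_to_cooperative(
    seq: HDSequence, rules: RuleSet, scope: Scope = "critical_only"
) -> int:
    """Minimum substitutions needed to satisfy the in-scope rules.

    Rules occupy distinct positions and any single violation is repairable
    by one substitution, so the minimum equals the count of violated
    in-scope positions.
    """
    if scope not in ("critical_only", "all_rules"):
        raise ValueError(f"unknown scope {scope!r}")
    ev = evaluate_rules(seq, rules)
    violations = ev.violated_critical if scope == "critical_only" else ev.violations
    return len(violations)


@dataclass(frozen=True)
class BatchSummary:
    """Per-factor rule report plus family-level aggregate counts."""

    table: "pd.DataFrame"
    n_sequences: int
    n_violators: int
    n_contributory_only: int
    residue_tallies: dict[str, int]


def batch_summary(seqs: Sequence[HDSequence], rules: RuleSet) -> BatchSummary:
    """Evaluate a family and aggregate violator counts and residue censuses.

    The residue tallies report the family-level censuses of interest:
    arginine vs glutamine at position 44, proline vs branched-hydrophobic
    (V/I/L) at position 26, and lysine at position 50.
    """
    import pandas as pd

    if not seqs:
        raise ValueError("batch_summary requires a non-empty sequence list")
    rows = []
    for seq in seqs:
        res = classify(seq, rules)
        ev = res.evaluation
        rows.append(
            {
                "id": seq.id,
                "family": seq.family,
                "category": res.category,
                "n_violations": len(ev.violations),
                "n_critical": len(ev.violated_critical),
                "n_contributory": len(ev.violated_contributory),
                "violated_positions": ",".join(
                    str(v.rule.hd_position) for v in ev.violations
                ),
                "min_changes_critical": len(ev.violated_critical),
                "min_changes_all": len(ev.violations),
            }
        )
    table = pd.DataFrame(rows)
    tallies = {
        "R44": sum(s.residue_at(44) == "R" for s in seqs),
        "Q44": sum(s.residue_at(44) == "Q" for s in seqs),
        "P26": sum(s.residue_at(26) == "P" for s in seqs),
        "branched_hydrophobic_26": sum(
            s.residue_at(26) in BRANCHED_HYDROPHOBIC for s in seqs
        ),
        "K50": sum(s.residue_at(50) == "K" for s in seqs),
        "Q46": sum(s.residue_at(46) == "Q" for s in seqs),
        "K46": sum(s.residue_at(46) == "K" for s in seqs),
    }
    return BatchSummary(
        table=table,
        n_sequences=len(seqs),
        n_violators=int((table["n_violations"] > 0).sum()),
        n_contributory_only=int(
            ((table["n_critical"] == 0) & (table["n_contributory"] > 0)).sum()
        ),
        residue_tallies=tallies,
    )
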