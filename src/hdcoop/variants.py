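"""Consequence prediction for homeodomain missense variants.

Given a missense variant in HD coordinates (e.g. R44Q) and its wild-type
domain sequence, the annotator predicts the biochemical consequence class:

* ``dna_binding`` — the substitution is expected to impair overall DNA
  binding (and therefore masks any cooperativity effect);
* ``cooperativity_decrease`` / ``cooperativity_increase`` — the
  substitution gains or removes a violation of the P3-site cooperativity
  rules, or perturbs a dimer-interface contact position;
* ``indeterminate`` — no evidence fires.

Decision order (first match wins; the full evidence trail is always
reported so users can re-rank):

1. DNA-binding heuristics — substitutions at the essential base-contact
   positions 5/51; glycine or proline introduced into the recognition
   helix (42-58); a bulky aromatic introduced at the minor-groove arm
   positions 2-3; a charged residue introduced at the turn proline 26.
2. The variant creates a rule violation absent in the wild type ->
   cooperativity_decrease, with the rule's severity.
3. The variant removes a wild-type rule violation -> cooperativity_increase.
4. The variant alters a protein-protein contact position without any rule
   transition -> cooperativity_decrease (interface-contact heuristic, no
   severity).
5. Otherwise indeterminate.

Annotation depends only on (position, ref, alt, sequence context); disease
labels are carried through but never consulted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import yaml

from .rules import CooperativityRule, RuleSet, evaluate_rules
from .sequences import HD_LENGTH, HDSequence, _RESIDUE_SET

ContactFlag = Literal["protein_protein", "dna_backbone", "dna_base", "minor_groove"]
CONTACT_FLAGS = ("protein_protein", "dna_backbone", "dna_base", "minor_groove")

CHARGED = frozenset("DEKR")
BULKY_AROMATIC = frozenset("WFY")
HELIX_BREAKER = frozenset("GP")


@dataclass(frozen=True)
class VariantRecord:
    protein: str
    hd_position: int
    ref: str
    alt: str
    disease: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.hd_position <= HD_LENGTH:
            raise ValueError(
                f"variant {self.label}: HD position out of range 1-{HD_LENGTH}"
            )
        for res in (self.ref, self.alt):
            if res not in _RESIDUE_SET:
                raise ValueError(f"variant {self.label}: non-canonical residue {res!r}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.label}: ref and alt are identical")

    @property
    def label(self) -> str:
        return f"{self.protein} {self.ref}{self.hd_position}{self.alt}"


@dataclass(frozen=True)
class ContactAnnotation:
    """Per-position structural contact flags (HD coordinates)."""

    positions: Mapping[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, flags in self.positions.items():
            if not 1 <= pos <= HD_LENGTH:
                raise ValueError(f"contact position {pos} out of range 1-{HD_LENGTH}")
            if not set(flags) <= set(CONTACT_FLAGS):
                raise ValueError(f"unknown contact flags at {pos}: {set(flags)}")

    def flags(self, pos: int) -> frozenset[str]:
        return self.positions.get(pos, frozenset())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ContactAnnotation":
        data = yaml.safe_load(Path(path).read_text())
        return cls({int(p): frozenset(flags) for p, flags in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        data = {int(p): sorted(flags) for p, flags in sorted(self.positions.items())}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def default_contacts() -> ContactAnnotation:
    """Packaged contact map containing only text-attested contacts.

    Protein-protein: 2, 3, 4, 25, 28, 32, 42, 43, 44, 46; DNA base: 5, 47,
    50, 51, 54; minor groove: 2, 3; DNA backbone: 46. The full published
    contact grid is figure-level data and can be supplied by the user as
    YAML to extend this map.
    """
    table: dict[int, set[str]] = {}
    for pos in (2, 3, 4, 25, 28, 32, 42, 43, 44, 46):
        table.setdefault(pos, set()).add("protein_protein")
    for pos in (5, 47, 50, 51, 54):
        table.setdefault(pos, set()).add("dna_base")
    for pos in (2, 3):
        table.setdefault(pos, set()).add("minor_groove")
    table.setdefault(46, set()).add("dna_backbone")
    return ContactAnnotation({p: frozenset(f) for p, f in table.items()})


@dataclass(frozen=True)
class HeuristicConfig:
    """Toggles for the named annotation heuristics (all on by default)."""

    essential_dna_contact: bool = True       # any substitution at 5 or 51
    helix3_destabilizer: bool = True         # G/P introduced at 42-58
    minor_groove_bulky_aromatic: bool = True  # W/F/Y introduced at 2-3
    charged_at_turn_proline: bool = True     # charged residue introduced at 26
    interface_contact: bool = True           # protein-protein position, no rule transition


Category = Literal[
    "cooperativity_decrease", "cooperativity_increase", "dna_binding", "indeterminate"
]


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantRecord
    category: Category
    severity: Literal["critical", "contributory"] | None
    triggered_rules: tuple[str, ...]
    heuristics_fired: tuple[str, ...]
    rationale: str


def _dna_binding_heuristics(
    v: VariantRecord, contacts: ContactAnnotation, cfg: HeuristicConfig
) -> list[str]:
    fired = []
    if cfg.essential_dna_contact and v.hd_position in (5, 51):
        fired.append("essential_dna_contact")
    if cfg.helix3_destabilizer and 42 <= v.hd_position <= 58 and v.alt in HELIX_BREAKER:
        fired.append("helix3_destabilizer")
    if (
        cfg.minor_groove_bulky_aromatic
        and v.hd_position in (2, 3)
        and v.alt in BULKY_AROMATIC
    ):
        fired.append("minor_groove_bulky_aromatic")
    if cfg.charged_at_turn_proline and v.hd_position == 26 and v.alt in CHARGED:
        fired.append("charged_at_turn_proline")
    return fired


def annotate_variant(
    v: VariantRecord,
    seq: HDSequence,
    rules: RuleSet,
    contacts: ContactAnnotation | None = None,
    heuristics: HeuristicConfig | None = None,
) -> ConsequenceCall:
    """Predict the consequence class of one variant on its wild-type domain."""
    contacts = contacts if contacts is not None else default_contacts()
    heuristics = heuristics if heuristics is not None else HeuristicConfig()

    observed = seq.residue_at(v.hd_position)
    if observed != v.ref:
        raise ValueError(
            f"variant {v.label}: reference residue mismatch — sequence "
            f"{seq.id!r} has {observed!r} at HD position {v.hd_position}"
        )

    rule = rules.by_position(v.hd_position)
    gained: CooperativityRule | None = None
    removed: CooperativityRule | None = None
    triggered: tuple[str, ...] = ()
    if rule is not None:
        ref_ok = rule.passes(v.ref)
        alt_ok = rule.passes(v.alt)
        if ref_ok and not alt_ok:
            gained = rule
        elif not ref_ok and alt_ok:
            removed = rule
        if gained or removed:
            triggered = (rule.describe(),)

    dna_fired = _dna_binding_heuristics(v, contacts, heuristics)
    interface_fired = (
        heuristics.interface_contact
        and gained is None
        and removed is None
        and "protein_protein" in contacts.flags(v.hd_position)
    )
    all_heuristics = tuple(dna_fired) + (("interface_contact",) if interface_fired else ())

    if dna_fired:
        return ConsequenceCall(
            v, "dna_binding", None, triggered, all_heuristics,
            f"{v.label}: predicted to impair overall DNA binding "
            f"({', '.join(dna_fired)})",
        )
    if gained is not None:
        return ConsequenceCall(
            v, "cooperativity_decrease", gained.importance, triggered, all_heuristics,
            f"{v.label}: gains violation of '{gained.describe()}'",
        )
    if removed is not None:
        return ConsequenceCall(
            v, "cooperativity_increase", removed.importance, triggered, all_heuristics,
            f"{v.label}: removes wild-type violation of '{removed.describe()}'",
        )
    if interface_fired:
        return ConsequenceCall(
            v, "cooperativity_decrease", None, triggered, all_heuristics,
            f"{v.label}: alters a protein-protein contact position "
            f"({v.hd_position}) without a rule transition",
        )
    return ConsequenceCall(
        v, "indeterminate", None, triggered, all_heuristics,
        f"{v.label}: no rule transition or heuristic evidence",
    )


@dataclass(frozen=True)
class BatchAnnotation:
    table: "pd.DataFrame"
    calls: tuple[ConsequenceCall, ...]
    skipped: tuple[str, ...]
    counts: dict[str, int]


def annotate_batch(
    variants: Sequence[VariantRecord],
    seqs: Sequence[HDSequence],
    rules: RuleSet,
    contacts: ContactAnnotation | None = None,
    heuristics: HeuristicConfig | None = None,
) -> BatchAnnotation:
    """Annotate a variant list; variants on unknown proteins are reported and skipped."""
    import pandas as pd

    by_id = {s.id: s for s in seqs}
    calls: list[ConsequenceCall] = []
    skipped: list[str] = []
    for v in variants:
        if v.protein not in by_id:
            skipped.append(v.label)
            continue
        calls.append(annotate_variant(v, by_id[v.protein], rules, contacts, heuristics))
    rows = [
        {
            "protein": c.variant.protein,
            "variant": f"{c.variant.ref}{c.variant.hd_position}{c.variant.alt}",
            "hd_position": c.variant.hd_position,
            "category": c.category,
            "severity": c.severity or "",
            "triggered_rules": ";".join(c.triggered_rules),
            "heuristics_fired": ";".join(c.heuristics_fired),
            "rationale": c.rationale,
        }
        for c in calls
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "protein", "variant", "hd_position", "category", "severity",
            "triggered_rules", "heuristics_fired", "rationale",
        ],
    )
    counts = {cat: 0 for cat in (
        "cooperativity_decrease", "cooperativity_increase", "dna_binding", "indeterminate"
    )}
    for c in calls:
        counts[c.category] += 1
    counts["cooperativity_total"] = (
        counts["cooperativity_decrease"] + counts["cooperativity_increase"]
    )
    return BatchAnnotation(
        table=table, calls=tuple(calls), skipped=tuple(skipped), counts=counts
    )


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV: ``protein  hd_position  ref  alt  [disease]``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein", "hd_position", "ref", "alt"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"{path}: variant TSV missing columns: {', '.join(missing)}")
        return [
            VariantRecord(
                protein=row["protein"],
                hd_position=int(row["hd_position"]),
                ref=row["ref"].upper(),
                alt=row["alt"].upper(),
                disease=(row.get("disease") or None),
            )
            for row in reader
        ]
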