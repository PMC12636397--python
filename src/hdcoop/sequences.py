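"""Homeodomain sequence types and I/O.

The homeodomain (HD) is a ~60-residue helix-turn-helix DNA-binding domain.
Throughout this package an HD is represented as exactly 60 canonical
one-letter residues numbered 1-60 (the field's standard HD coordinate
convention, so that residue names like R3, P26, Q50 are unambiguous).
Shorter or longer domains, gaps, and ambiguity codes (B, Z, X) are rejected
rather than imputed: every downstream frequency and rule computation assumes
a complete canonical 60-mer.

Family membership (Paired-like vs ANTP vs other) is supplied by the user as
an explicit table rather than inferred from sequence, because subfamily
classification is an external curation decision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HD_LENGTH = 60

#: Canonical one-letter amino-acid codes, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
_RESIDUE_SET = frozenset(CANONICAL_RESIDUES)

#: Allowed family labels.
FAMILIES = ("PairedLike", "ANTP", "other")


@dataclass(frozen=True)
class HDSequence:
    """A 60-residue homeodomain with a family label.

    Parameters
    ----------
    id
        Protein identifier (e.g. gene symbol).
    family
        One of ``"PairedLike"``, ``"ANTP"``, ``"other"``.
    residues
        Exactly 60 canonical one-letter codes (uppercase).
    hd_start_in_protein
        Optional 1-based position of HD residue 1 in the full-length
        protein, used to convert HD coordinates to protein coordinates.
    """

    id: str
    family: str
    residues: str
    hd_start_in_protein: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"sequence {self.id!r}: unknown family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if len(self.residues) != HD_LENGTH:
            raise ValueError(
                f"sequence {self.id!r} has length {len(self.residues)}, "
                f"expected exactly {HD_LENGTH} residues"
            )
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in _RESIDUE_SET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal residue {aa!r} at HD "
                    f"position {pos} (only the 20 canonical codes are allowed)"
                )

    def residue_at(self, hd_pos: int) -> str:
        """Residue at HD position ``hd_pos`` (1-60)."""
        _check_hd_pos(hd_pos)
        return self.residues[hd_pos - 1]

    def with_substitution(self, hd_pos: int, alt: str) -> "HDSequence":
        """Copy of this sequence with ``alt`` at HD position ``hd_pos``."""
        _check_hd_pos(hd_pos)
        residues = self.residues[: hd_pos - 1] + alt + self.residues[hd_pos:]
        return HDSequence(self.id, self.family, residues, self.hd_start_in_protein)


def _check_hd_pos(hd_pos: int) -> None:
    if not 1 <= hd_pos <= HD_LENGTH:
        raise ValueError(f"HD position {hd_pos} out of range 1-{HD_LENGTH}")


def hd_to_protein_position(seq: HDSequence, hd_pos: int) -> int:
    """Map HD position 1-60 to a 1-based full-length protein position.

    Requires ``seq.hd_start_in_protein``; e.g. with offset 209, HD position 1
    maps to protein position 209 and HD position 60 to 268.
    """
    _check_hd_pos(hd_pos)
    if seq.hd_start_in_protein is None:
        raise ValueError(
            f"sequence {seq.id!r}: protein-coordinate offset unknown "
            "(hd_start_in_protein is not set)"
        )
    return seq.hd_start_in_protein + hd_pos - 1


@dataclass(frozen=True)
class FamilyTable:
    """Mapping from sequence id to family label."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, fam in self.entries.items():
            if fam not in FAMILIES:
                raise ValueError(
                    f"family table: id {sid!r} has unknown family {fam!r}; "
                    f"expected one of {FAMILIES}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "FamilyTable":
        entries: dict[str, str] = {}
        for sid, fam in pairs:
            if sid in entries:
                raise ValueError(f"family table: duplicate id {sid!r}")
            entries[sid] = fam
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyTable":
        """Read a TSV with header ``id<TAB>family``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {"id", "family"} <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: expected TSV header with columns 'id' and 'family'"
                )
            return cls.from_pairs((row["id"], row["family"]) for row in reader)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "family"])
            for sid, fam in self.entries.items():
                writer.writerow([sid, fam])

    def family_of(self, sid: str) -> str:
        return self.entries[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries


def read_hd_fasta(path: str | Path, family_table: FamilyTable) -> list[HDSequence]:
    """Read 60-mer homeodomains from FASTA, labeling each via ``family_table``.

    Sequences are uppercased. Records whose id is absent from the table, that
    are not exactly 60 residues long, or that contain non-canonical
    characters raise ``ValueError`` naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    missing = [rec.id for rec in records if rec.id not in family_table]
    if missing:
        raise ValueError(
            f"{path}: ids missing from family table: {', '.join(missing)}"
        )
    return [
        HDSequence(rec.id, family_table.family_of(rec.id), str(rec.seq).upper())
        for rec in records
    ]


def write_hd_fasta(seqs: Sequence[HDSequence], path: str | Path) -> None:
    """Write sequences to FASTA (round-trips with :func:`read_hd_fasta`)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def family_table_of(seqs: Sequence[HDSequence]) -> FamilyTable:
    """Build a :class:`FamilyTable` from labeled sequences."""
    return FamilyTable.from_pairs((s.id, s.family) for s in seqs)
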