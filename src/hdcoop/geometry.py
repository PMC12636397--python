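"""Structural geometry of homeodomains: helix spacing and steric overlap.

Homeodomains are segmented in HD coordinates into the N-terminal arm
(1-8), helix 1 (9-25), helix 2 (26-39) and helix 3 (40-60). This module
provides:

* PDB/mmCIF reading (via gemmi) with an explicit per-chain mapping from
  author residue numbering to HD positions — no heuristic renumbering;
* C-alpha distance matrices and family comparisons of designated
  "inner" helix-helix residue pairs (with t-tests and Holm adjustment);
* Kabsch least-squares superposition and a segment-wise spacing graft that
  rebuilds one domain with another domain's helix packing (no bond-geometry
  regularization — the result is a rigid-segment chimera);
* solvent-accessible surface area (Shrake-Rupley, Bondi van der Waals
  radii, probe 1.4 A, 960 sphere points by default) and the pairwise
  steric-overlap statistic SA(A) + SA(B) - SA(A union B), computed with
  each residue pair isolated from the rest of the structure. Peptide-bonded
  (sequence-adjacent) pairs are not meaningful and are rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .emsa import holm_adjust

#: Bondi van der Waals radii (Angstrom); unlisted elements fall back to carbon.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_SASA_POINTS = 960


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"atom {self.name}: non-finite coordinates")

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW)


@dataclass(frozen=True)
class Residue:
    hd_position: int
    name: str
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass(frozen=True)
class StructureModel:
    """Chains of HD-numbered residues with atomic coordinates."""

    id: str
    chains: Mapping[str, tuple[Residue, ...]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            positions = [r.hd_position for r in residues]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(
                    f"model {self.id}, chain {cid}: HD positions must be strictly increasing"
                )

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        if chain_id not in self.chains:
            raise KeyError(
                f"model {self.id}: no chain {chain_id!r}; available: "
                f"{', '.join(sorted(self.chains))}"
            )
        return tuple(self.chains[chain_id])

    def residue(self, chain_id: str, hd_position: int) -> Residue:
        for r in self.chain(chain_id):
            if r.hd_position == hd_position:
                return r
        raise KeyError(
            f"model {self.id}: chain {chain_id} has no residue at HD position {hd_position}"
        )


@dataclass(frozen=True)
class SegmentDefinition:
    """Named HD segment ranges (inclusive); disjoint and covering 1-60."""

    arm: tuple[int, int] = (1, 8)
    helix1: tuple[int, int] = (9, 25)
    helix2: tuple[int, int] = (26, 39)
    helix3: tuple[int, int] = (40, 60)

    def ranges(self) -> dict[str, tuple[int, int]]:
        return {
            "arm": self.arm, "helix1": self.helix1,
            "helix2": self.helix2, "helix3": self.helix3,
        }

    def __post_init__(self) -> None:
        covered: list[int] = []
        for lo, hi in self.ranges().values():
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, 61)):
            raise ValueError("segments must be disjoint and cover HD positions 1-60")


DEFAULT_SEGMENTS = SegmentDefinition()

#: Packaged inward-facing C-alpha pairs per helix-helix combination.
#: Configurable; reproducing a published figure may require the authors' pairs.
DEFAULT_INNER_PAIRS: dict[str, tuple[tuple[int, int], ...]] = {
    "helix1-helix2": ((12, 37), (15, 33), (19, 30), (22, 29)),
    "helix1-helix3": ((13, 56), (16, 52), (20, 49), (23, 45)),
    "helix2-helix3": ((28, 54), (31, 51), (34, 47), (37, 44)),
}


# ---------------------------------------------------------------------------
# Structure reading


def read_structure(
    path: str | Path,
    mapping: Mapping[str, int],
    model_id: str | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into HD numbering.

    ``mapping`` gives, per chain, the author residue number of HD position 1
    (e.g. ``{"A": 209}`` when the domain starts at author residue 209).
    Residues mapping outside 1-60 are dropped; residues without a C-alpha
    atom trigger a warning. A chain named in the mapping but absent from the
    file is an error naming the available chains.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    available = [ch.name for ch in model]
    chains: dict[str, tuple[Residue, ...]] = {}
    for chain_id, author_start in mapping.items():
        chain = None
        for ch in model:
            if ch.name == chain_id:
                chain = ch
                break
        if chain is None:
            raise ValueError(
                f"{path}: chain {chain_id!r} not found; available chains: "
                f"{', '.join(available)}"
            )
        residues = []
        for res in chain:
            if res.seqid.num is None:
                continue
            hd_pos = res.seqid.num - author_start + 1
            if not 1 <= hd_pos <= 60:
                continue
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    xyz=(a.pos.x, a.pos.y, a.pos.z),
                )
                for a in res
            )
            residue = Residue(hd_position=hd_pos, name=res.name, atoms=atoms)
            if residue.ca is None:
                warnings.warn(
                    f"{path}: chain {chain_id} residue {res.name}{res.seqid.num} "
                    f"(HD {hd_pos}) has no C-alpha atom",
                    stacklevel=2,
                )
            residues.append(residue)
        chains[chain_id] = tuple(residues)
    return StructureModel(id=model_id or Path(path).stem, chains=chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model to PDB (HD positions become residue numbers)."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        ch = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.hd_position, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# C-alpha distances


@dataclass(frozen=True)
class CaDistanceMatrix:
    positions: tuple[int, ...]
    d: np.ndarray  # symmetric, zero diagonal, Angstrom

    def distance(self, pos_a: int, pos_b: int) -> float:
        i = self.positions.index(pos_a)
        j = self.positions.index(pos_b)
        return float(self.d[i, j])


def ca_coordinates(model: StructureModel, chain_id: str) -> tuple[tuple[int, ...], np.ndarray]:
    """(HD positions, n x 3 coordinates) of the chain's C-alpha atoms."""
    positions = []
    coords = []
    for res in model.chain(chain_id):
        if res.ca is not None:
            positions.append(res.hd_position)
            coords.append(res.ca.xyz)
    return tuple(positions), np.asarray(coords, dtype=float)


def ca_distance_matrix(model: StructureModel, chain_id: str) -> CaDistanceMatrix:
    positions, coords = ca_coordinates(model, chain_id)
    if len(positions) < 2:
        raise ValueError(
            f"model {model.id}, chain {chain_id}: need at least 2 C-alpha atoms"
        )
    diff = coords[:, None, :] - coords[None, :, :]
    return CaDistanceMatrix(positions=positions, d=np.sqrt((diff**2).sum(axis=2)))


# ---------------------------------------------------------------------------
# Inter-helix spacing comparison


@dataclass(frozen=True)
class HelixPairSummary:
    """Per-structure inner-pair distances and family-level comparison.

    ``records`` has one row per (combo, pair, family, structure) with the
    measured distance; ``summary`` one row per pair with family means, the
    mean difference (second family minus first), the two-sided t-test and
    Holm-adjusted p-value (flagged underpowered when either family has
    fewer than two resolvable structures for the pair).
    """

    families: tuple[str, str]
    records: "pd.DataFrame"
    summary: "pd.DataFrame"


def interhelix_comparison(
    models: Mapping[str, Sequence[StructureModel]],
    pairs: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    chain_id: str = "A",
) -> HelixPairSummary:
    """Compare designated inner helix-pair distances between two families."""
    import pandas as pd

    if len(models) != 2:
        raise ValueError("interhelix_comparison requires exactly two labeled families")
    fam_first, fam_second = list(models)
    pairs = dict(pairs) if pairs is not None else DEFAULT_INNER_PAIRS
    records = []
    for family, family_models in models.items():
        if not family_models:
            raise ValueError(f"family {family!r} has no structures")
        for model in family_models:
            dm = ca_distance_matrix(model, chain_id)
            have = set(dm.positions)
            for combo, combo_pairs in pairs.items():
                for pos_a, pos_b in combo_pairs:
                    if pos_a not in have or pos_b not in have:
                        records.append(
                            {
                                "combo": combo, "pair": f"{pos_a}-{pos_b}",
                                "family": family, "structure": model.id,
                                "distance": math.nan, "resolved": False,
                            }
                        )
                        continue
                    records.append(
                        {
                            "combo": combo, "pair": f"{pos_a}-{pos_b}",
                            "family": family, "structure": model.id,
                            "distance": dm.distance(pos_a, pos_b), "resolved": True,
                        }
                    )
    rec = pd.DataFrame(records)
    rows = []
    for (combo, pair), sub in rec[rec.resolved].groupby(["combo", "pair"], sort=False):
        a = sub.loc[sub.family == fam_first, "distance"].to_numpy()
        b = sub.loc[sub.family == fam_second, "distance"].to_numpy()
        underpowered = len(a) < 2 or len(b) < 2
        if underpowered:
            t, p = math.nan, math.nan
        else:
            from scipy import stats

            with warnings.catch_warnings():
                # degenerate (identical) families handled explicitly below
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=True)
            if math.isnan(t) and np.allclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
        rows.append(
            {
                "combo": combo, "pair": pair,
                f"mean_{fam_first}": a.mean() if len(a) else math.nan,
                f"mean_{fam_second}": b.mean() if len(b) else math.nan,
                "mean_difference": (b.mean() - a.mean())
                if len(a) and len(b) else math.nan,
                "t": float(t), "p": float(p), "underpowered": underpowered,
            }
        )
    summary = pd.DataFrame(rows)
    testable = summary[~summary.underpowered]
    summary["p_holm"] = math.nan
    if len(testable):
        summary.loc[testable.index, "p_holm"] = holm_adjust(testable.p.to_numpy())
    return HelixPairSummary(
        families=(fam_first, fam_second), records=rec, summary=summary
    )


# ---------------------------------------------------------------------------
# Superposition and spacing graft


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t, rmsd) such that ``x @ R.T + t``
    maps mobile points onto the target frame. Proper rotations only
    (reflections excluded via the sign correction on the smallest singular
    vector).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be n x 3 with equal n")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = (P @ R.T) + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _segment_positions(residues: Sequence[Residue], lo: int, hi: int) -> list[Residue]:
    return [r for r in residues if lo <= r.hd_position <= hi]


def graft_spacing(
    model: StructureModel,
    donor: StructureModel,
    segments: SegmentDefinition = DEFAULT_SEGMENTS,
    chain_id: str = "A",
    donor_chain_id: str | None = None,
) -> tuple[StructureModel, dict[str, float]]:
    """Rebuild ``model`` with the donor's segment packing.

    Each segment of the model chain is rigid-body superposed (on shared
    C-alpha positions) onto the corresponding donor segment and the whole
    segment is transformed; the per-segment C-alpha rmsd after superposition
    is reported. Internal segment geometry is preserved — only the relative
    placement of segments (the helix spacing) is taken from the donor. No
    bond regularization is applied at the seams.
    """
    donor_chain_id = donor_chain_id or chain_id
    model_res = model.chain(chain_id)
    donor_res = donor.chain(donor_chain_id)
    new_residues: list[Residue] = []
    report: dict[str, float] = {}
    for name, (lo, hi) in segments.ranges().items():
        seg_m = _segment_positions(model_res, lo, hi)
        seg_d = _segment_positions(donor_res, lo, hi)
        common = sorted(
            {r.hd_position for r in seg_m if r.ca is not None}
            & {r.hd_position for r in seg_d if r.ca is not None}
        )
        if len(common) < 3:
            raise ValueError(
                f"segment {name!r} ({lo}-{hi}): fewer than 3 shared C-alpha "
                f"positions between model and donor"
            )
        m_by_pos = {r.hd_position: r for r in seg_m}
        d_by_pos = {r.hd_position: r for r in seg_d}
        P = np.array([m_by_pos[p].ca.xyz for p in common])
        Q = np.array([d_by_pos[p].ca.xyz for p in common])
        R, t, rmsd = kabsch_superpose(P, Q)
        report[name] = rmsd
        for res in seg_m:
            atoms = tuple(
                replace(a, xyz=tuple(R @ np.asarray(a.xyz) + t)) for a in res.atoms
            )
            new_residues.append(replace(res, atoms=atoms))
    new_residues.sort(key=lambda r: r.hd_position)
    grafted = StructureModel(
        id=f"{model.id}~spacing({donor.id})", chains={chain_id: tuple(new_residues)}
    )
    return grafted, report


# ---------------------------------------------------------------------------
# Solvent-accessible surface area and steric overlap


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Each atom's sphere is inflated by the probe radius and sampled at
    ``n_points`` lattice points; a point is accessible when outside every
    other inflated sphere. Area = accessible fraction x 4 pi (r + probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) != len(radii):
        raise ValueError("coords must be n x 3 with matching radii")
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            # quick reject: spheres too far apart to intersect
            if np.linalg.norm(coords[j] - coords[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            r2 = expanded[j] ** 2
            # strictly inside buries the point; points exactly on a shared
            # surface (coincident spheres) are kept by the lower-index atom
            # only, so degenerate duplicates count their area once
            inside = d2 < r2 * (1.0 - 1e-9)
            on_boundary = ~inside & (d2 <= r2 * (1.0 + 1e-9))
            accessible &= ~(inside | (on_boundary & (j < i)))
        areas[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas


def _residue_arrays(residues: Sequence[Residue]) -> tuple[np.ndarray, np.ndarray]:
    atoms = [a for r in residues for a in r.atoms]
    if not atoms:
        raise ValueError("residue has no atoms")
    coords = np.array([a.xyz for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float)
    return coords, radii


def residue_sasa(
    residues: Sequence[Residue],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> float:
    """Total SASA of an isolated residue group (no other context atoms)."""
    coords, radii = _residue_arrays(residues)
    return float(shrake_rupley(coords, radii, probe_radius, n_points).sum())


@dataclass(frozen=True)
class OverlapResult:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    area_a: float
    area_b: float
    area_ab: float

    @property
    def overlap(self) -> float:
        return self.area_a + self.area_b - self.area_ab


def steric_overlap(
    model: StructureModel,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> OverlapResult:
    """Surface-area overlap of two residues, each treated as an isolated object.

    overlap = SA(A) + SA(B) - SA(A union B); near zero for spatially
    disjoint residues and bounded by the smaller residue's area. Bonded
    (sequence-adjacent, same-chain) pairs are rejected — their surfaces
    overlap trivially through the peptide bond.
    """
    (chain_a, pos_a), (chain_b, pos_b) = residue_a, residue_b
    if chain_a == chain_b and abs(pos_a - pos_b) == 1:
        raise ValueError(
            f"residues {residue_a} and {residue_b} are peptide-bonded; "
            "overlap is not reported for bonded pairs"
        )
    res_a = model.residue(chain_a, pos_a)
    res_b = model.residue(chain_b, pos_b)
    area_a = residue_sasa([res_a], probe_radius, n_points)
    area_b = residue_sasa([res_b], probe_radius, n_points)
    area_ab = residue_sasa([res_a, res_b], probe_radius, n_points)
    return OverlapResult(
        residue_a=residue_a, residue_b=residue_b,
        area_a=area_a, area_b=area_b, area_ab=area_ab,
    )


def interface_overlaps(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    max_ca_distance: float = 15.0,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> list[OverlapResult]:
    """All pairwise inter-chain residue overlaps within a C-alpha cutoff.

    Bonded pairs cannot arise across chains; the cutoff merely skips
    far-apart pairs whose overlap is identically ~0.
    """
    results = []
    for ra in model.chain(chain_a):
        if ra.ca is None:
            continue
        for rb in model.chain(chain_b):
            if rb.ca is None:
                continue
            d = float(np.linalg.norm(np.subtract(ra.ca.xyz, rb.ca.xyz)))
            if d > max_ca_distance:
                continue
            results.append(
                steric_overlap(
                    model, (chain_a, ra.hd_position), (chain_b, rb.hd_position),
                    probe_radius, n_points,
                )
            )
    return results
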