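"""Synthetic inputs: equilibrium gel-shift lanes, sequence families, helices.

The lane simulator inverts the Tau statistic into a generative mass-action
model of a probe with two identical half-sites. With ``x = [P]/kd_site``
(kd_site the microscopic per-half-site dissociation constant) and tau the
cooperativity factor,

    [PD]  = 2 x [D]          (two equivalent ways to occupy one site)
    [P2D] = tau x^2 [D]

so the macroscopic constants relate as Kd1 = kd_site / 2 and
Kd2 = 2 kd_site / tau, and recomputing 4 [P2D][D] / [PD]^2 from any
equilibrium state returns exactly tau. Free protein [P] is found by
monotone bracketing root-finding on the protein conservation law; both
probe and protein conservation then hold to ~1e-12 relative.

Band intensities are species concentrations scaled by independent
multiplicative lognormal noise (gel bands are positive and roughly
scale-proportional); mean-one factors with a configurable coefficient of
variation, or exact proportionality at noise_cv = 0. Additive Gaussian
noise is available behind a flag for robustness experiments.

Defaults mirror the assay design this package analyzes: 34 nM probe, four
protein concentrations (25/50/100/200 nM) in triplicate.

The module also draws homeodomain families from position-specific residue
frequency profiles and builds ideal alpha-helix C-alpha models (rise 1.5 A,
100 degrees/residue, radius 2.3 A) for geometry fixtures. All randomness
flows through a single explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .constraints import N_RESIDUES
from .emsa import LaneMeasurement
from .geometry import Atom, Residue, StructureModel
from .rules import RuleSet
from .sequences import CANONICAL_RESIDUES, HD_LENGTH, HDSequence, RESIDUE_INDEX


@dataclass(frozen=True)
class BindingModelConfig:
    """Configuration of the two-site equilibrium lane simulator."""

    tau_true: float
    kd_site: float = 200.0            # nM, microscopic per-half-site Kd
    d_total: float = 34.0             # nM probe in every reaction
    p_totals: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0)  # nM protein
    replicates: int = 3
    noise_cv: float = 0.0
    noise_model: str = "lognormal"    # or "gaussian"
    seed: int = 0
    probe_id: str = "P3"
    protein_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.tau_true < 0:
            raise ValueError("tau_true must be >= 0")
        if self.kd_site <= 0 or self.d_total <= 0:
            raise ValueError("kd_site and d_total must be positive")
        if any(p < 0 for p in self.p_totals):
            raise ValueError("protein concentrations must be nonnegative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium species concentrations (nM) for one reaction."""

    p_free: float
    d_free: float
    monomer: float
    dimer: float

    @property
    def tau(self) -> float:
        """Tau recomputed from the state (equals the generative tau)."""
        if self.monomer == 0:
            return math.nan
        return 4.0 * self.dimer * self.d_free / self.monomer**2

    @property
    def bound_fraction(self) -> float:
        total = self.d_free + self.monomer + self.dimer
        return (self.monomer + self.dimer) / total


def equilibrium_state(cfg: BindingModelConfig, p_total: float) -> EquilibriumState:
    """Solve the mass-action equilibrium at one total protein concentration.

    The protein-conservation residual is strictly increasing in [P], so
    bracketing on [0, p_total] always converges.
    """
    if p_total < 0:
        raise ValueError("p_total must be nonnegative")
    if p_total == 0:
        return EquilibriumState(0.0, cfg.d_total, 0.0, 0.0)
    kd, tau, d_tot = cfg.kd_site, cfg.tau_true, cfg.d_total

    def bound_protein(p: float) -> float:
        x = p / kd
        denom = 1.0 + 2.0 * x + tau * x * x
        d = d_tot / denom
        return d * (2.0 * x + 2.0 * tau * x * x)

    def residual(p: float) -> float:
        return p + bound_protein(p) - p_total

    try:
        p_free = brentq(residual, 0.0, p_total, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - monotone residual, unreachable
        raise RuntimeError(
            f"equilibrium solver failed to bracket: residual(0)={residual(0.0):.3g}, "
            f"residual(p_total)={residual(p_total):.3g}"
        ) from exc
    x = p_free / kd
    d_free = d_tot / (1.0 + 2.0 * x + tau * x * x)
    return EquilibriumState(
        p_free=p_free,
        d_free=d_free,
        monomer=2.0 * x * d_free,
        dimer=tau * x * x * d_free,
    )


def simulate_lanes(cfg: BindingModelConfig) -> list[LaneMeasurement]:
    """Generate one lane per (protein concentration, replicate), seeded.

    With noise_cv = 0 intensities are exactly proportional to species
    concentrations and the per-lane Tau estimator recovers tau_true to
    machine precision.
    """
    rng = np.random.default_rng(cfg.seed)
    lanes = []
    for p_total in cfg.p_totals:
        state = equilibrium_state(cfg, p_total)
        species = np.array([state.d_free, state.monomer, state.dimer])
        for rep in range(1, cfg.replicates + 1):
            if cfg.noise_cv == 0:
                noisy = species
            elif cfg.noise_model == "lognormal":
                sigma2 = math.log1p(cfg.noise_cv**2)
                factors = rng.lognormal(
                    mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=3
                )
                noisy = species * factors
            else:
                noisy = np.clip(
                    species * (1.0 + cfg.noise_cv * rng.standard_normal(3)), 0.0, None
                )
            lanes.append(
                LaneMeasurement(
                    probe=cfg.probe_id,
                    protein=cfg.protein_id,
                    concentration=p_total,
                    replicate=rep,
                    i_free=float(noisy[0]),
                    i_monomer=float(noisy[1]),
                    i_dimer=float(noisy[2]),
                )
            )
    return lanes


# ---------------------------------------------------------------------------
# Sequence families


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Draw sequences from a 60 x 20 position-specific frequency profile."""

    profile: np.ndarray
    n: int
    seed: int = 0
    family: str = "other"
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        profile = np.asarray(self.profile, dtype=float)
        if profile.shape != (HD_LENGTH, N_RESIDUES):
            raise ValueError(f"profile must be {HD_LENGTH}x{N_RESIDUES}")
        if np.any(profile < 0):
            raise ValueError("profile entries must be nonnegative")
        if not np.allclose(profile.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every profile row must sum to 1 (within 1e-9)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def simulate_family(cfg: SyntheticFamilyConfig) -> list[HDSequence]:
    """Draw ``n`` sequences, each position independently from its profile row."""
    rng = np.random.default_rng(cfg.seed)
    profile = np.asarray(cfg.profile, dtype=float)
    # normalize away float round-off so rng.choice sees exact simplex rows
    profile = profile / profile.sum(axis=1, keepdims=True)
    columns = np.empty((HD_LENGTH, cfg.n), dtype=int)
    for p in range(HD_LENGTH):
        columns[p] = rng.choice(N_RESIDUES, size=cfg.n, p=profile[p])
    return [
        HDSequence(
            id=f"{cfg.id_prefix}{i:04d}",
            family=cfg.family,
            residues="".join(CANONICAL_RESIDUES[columns[p, i]] for p in range(HD_LENGTH)),
        )
        for i in range(cfg.n)
    ]


def profile_from_consensus(consensus: str, identity: float = 1.0) -> np.ndarray:
    """Profile concentrated on a consensus 60-mer.

    Each row puts ``identity`` mass on the consensus residue and spreads the
    remainder uniformly over the other 19 residues.
    """
    if len(consensus) != HD_LENGTH:
        raise ValueError(f"consensus must be {HD_LENGTH} residues")
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    profile = np.full((HD_LENGTH, N_RESIDUES), (1.0 - identity) / (N_RESIDUES - 1))
    for p, aa in enumerate(consensus):
        profile[p, RESIDUE_INDEX[aa]] = identity
    return profile


def compliant_profile(rules: RuleSet, background: np.ndarray | None = None) -> np.ndarray:
    """Constrain a profile so every draw satisfies all rules with probability 1.

    Require-rules concentrate their position on the allowed residues;
    forbid-rules zero out the forbidden residues and renormalize. The
    background defaults to uniform.
    """
    if background is None:
        profile = np.full((HD_LENGTH, N_RESIDUES), 1.0 / N_RESIDUES)
    else:
        profile = np.array(background, dtype=float)
    for rule in rules.rules:
        row = profile[rule.hd_position - 1]
        mask = np.zeros(N_RESIDUES, dtype=bool)
        for aa in rule.residues:
            mask[RESIDUE_INDEX[aa]] = True
        if rule.mode == "require":
            row = np.where(mask, row, 0.0)
        else:
            row = np.where(mask, 0.0, row)
        if row.sum() == 0:
            raise ValueError(
                f"rule at position {rule.hd_position} leaves no admissible residue"
            )
        profile[rule.hd_position - 1] = row / row.sum()
    return profile


# ---------------------------------------------------------------------------
# Ideal helices


def ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain_id: str = "A",
    start_pos: int = 1,
    phase: float = 0.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    model_id: str = "ideal_helix",
) -> StructureModel:
    """C-alpha-only model of a regular alpha helix along +z.

    Residue i sits at angle ``phase + i * twist`` (degrees) on a cylinder of
    the given radius, climbing ``rise`` Angstrom per residue; consecutive
    C-alpha atoms are ~3.8 A apart at the default parameters.
    """
    if n_res < 2:
        raise ValueError("an ideal helix needs at least 2 residues")
    ox, oy, oz = origin
    residues = []
    for i in range(n_res):
        angle = math.radians(phase + i * twist)
        atom = Atom(
            name="CA",
            element="C",
            xyz=(
                ox + radius * math.cos(angle),
                oy + radius * math.sin(angle),
                oz + i * rise,
            ),
        )
        residues.append(
            Residue(hd_position=start_pos + i, name="ALA", atoms=(atom,))
        )
    return StructureModel(id=model_id, chains={chain_id: tuple(residues)})


def ideal_domain(
    helix2_offset: float = 9.0,
    helix3_offset: float = 9.0,
    chain_id: str = "A",
    model_id: str = "ideal_domain",
) -> StructureModel:
    """Toy full-domain C-alpha model for spacing fixtures.

    The arm (1-8) is an extended strand; helix 1 (9-25) runs up +z at
    x = 0; helix 2 (26-39) runs antiparallel at x = ``helix2_offset``;
    helix 3 (40-60) runs perpendicular at y = ``helix3_offset``. Only the
    *relative placement* of segments is meaningful — the fixture exists so
    spacing changes (e.g. splaying helix 2 outward) have a known magnitude.
    """
    residues: list[Residue] = []

    def add(pos: int, xyz: tuple[float, float, float]) -> None:
        residues.append(
            Residue(pos, "ALA", (Atom("CA", "C", xyz),))
        )

    for i, pos in enumerate(range(1, 9)):  # extended arm
        add(pos, (-3.0 * (8 - pos), -6.0, -4.0 + 0.5 * i))
    h1 = ideal_helix(17, start_pos=9, model_id="h1")
    for r in h1.chain("A"):
        residues.append(r)
    h2 = ideal_helix(14, start_pos=26, model_id="h2")
    for r in h2.chain("A"):
        a = r.ca
        # antiparallel: descend in z, shifted in x
        x, y, z = a.xyz
        residues.append(
            Residue(r.hd_position, "ALA",
                    (Atom("CA", "C", (x + helix2_offset, y, 24.0 - z)),))
        )
    h3 = ideal_helix(21, start_pos=40, model_id="h3")
    for r in h3.chain("A"):
        x, y, z = r.ca.xyz
        # perpendicular recognition helix: runs along +x at offset y
        residues.append(
            Residue(r.hd_position, "ALA",
                    (Atom("CA", "C", (z - 4.0, y + helix3_offset, x + 6.0)),))
        )
    residues.sort(key=lambda r: r.hd_position)
    return StructureModel(id=model_id, chains={chain_id: tuple(residues)})
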