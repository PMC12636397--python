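"""Tau cooperativity and probe depletion from gel-shift band intensities.

An EMSA lane resolves three probe species — free probe D, the monomer-bound
complex PD, and the dimer-bound complex P2D. With band intensity
proportional to molar probe species (one fluorophore per probe molecule),
the intensity fractions estimate the species fractions, and the
cooperativity statistic is

    tau = 4 [P2D][D] / [PD]^2

which equals 1 for independent binding of the two half-sites, >1 for
positive cooperativity, and <1 for anti-cooperativity. Tau is invariant to
lane-wide intensity rescaling (gel exposure).

Lanes qualify for Tau aggregation only when strictly more than 5% of the
probe is bound; lanes with no monomer band have an undefined (singular)
Tau and are excluded from means rather than imputed.

Group comparisons mirror the standard gel-quantitation statistics: Levene's
test (Brown-Forsythe, median-centered) to choose Student vs Welch t-tests,
one-way ANOVA, two-way ANOVA (protein x concentration, type-II sums of
squares), and Holm step-down adjustment of pairwise p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: A lane is included in Tau aggregation iff bound fraction > this (strict).
INCLUSION_THRESHOLD = 0.05

LANE_COLUMNS = (
    "probe", "protein", "concentration_nM", "replicate",
    "I_free", "I_monomer", "I_dimer",
)


@dataclass(frozen=True)
class LaneMeasurement:
    """Band intensities of the three probe species in one lane."""

    probe: str
    protein: str
    concentration: float  # nM total protein
    replicate: int
    i_free: float
    i_monomer: float
    i_dimer: float

    def __post_init__(self) -> None:
        intensities = (self.i_free, self.i_monomer, self.i_dimer)
        if not all(math.isfinite(x) for x in intensities):
            raise ValueError(f"lane {self._ref()}: intensities must be finite")
        if any(x < 0 for x in intensities):
            raise ValueError(f"lane {self._ref()}: intensities must be nonnegative")

    def _ref(self) -> str:
        return f"{self.protein}/{self.probe}@{self.concentration}nM rep{self.replicate}"


def lane_fractions(lane: LaneMeasurement) -> tuple[float, float, float]:
    """Species fractions (f_D, f_PD, f_P2D); intensities must not all be zero."""
    total = lane.i_free + lane.i_monomer + lane.i_dimer
    if total <= 0:
        raise ValueError(f"lane {lane._ref()}: all band intensities are zero")
    return lane.i_free / total, lane.i_monomer / total, lane.i_dimer / total


@dataclass(frozen=True)
class TauEstimate:
    lane: LaneMeasurement
    tau: float            # nan when undefined (no monomer band)
    bound_fraction: float
    included: bool

    @property
    def defined(self) -> bool:
        return math.isfinite(self.tau)


def tau_from_lane(lane: LaneMeasurement) -> TauEstimate:
    """Tau = 4 f_P2D f_D / f_PD^2 plus the >5%-bound inclusion flag."""
    f_d, f_pd, f_p2d = lane_fractions(lane)
    bound = f_pd + f_p2d
    tau = 4.0 * f_p2d * f_d / f_pd**2 if f_pd > 0 else math.nan
    return TauEstimate(
        lane=lane, tau=tau, bound_fraction=bound,
        included=bound > INCLUSION_THRESHOLD,
    )


@dataclass(frozen=True)
class DepletionMeasurement:
    lane: LaneMeasurement
    percent_bound: float  # 0-100


def depletion(lane: LaneMeasurement) -> DepletionMeasurement:
    """Free-probe depletion: percent of probe bound in any complex."""
    f_d, f_pd, f_p2d = lane_fractions(lane)
    return DepletionMeasurement(lane=lane, percent_bound=100.0 * (f_pd + f_p2d))


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD of Tau over the included, defined lanes of one protein/probe group."""

    protein: str
    probe: str
    mean_tau: float | None
    sd_tau: float | None
    n_lanes_included: int
    n_lanes_total: int

    @property
    def qualifying(self) -> bool:
        return self.n_lanes_included > 0


def summarize_group(lanes: Sequence[LaneMeasurement]) -> GroupSummary:
    """Aggregate one (protein, probe) group, pooling across concentrations.

    Only lanes passing the >5% inclusion rule with a defined Tau enter the
    mean and sample SD; a group with none returns an explicit
    no-qualifying-lanes summary (``mean_tau`` is None).
    """
    if not lanes:
        raise ValueError("summarize_group requires at least one lane")
    proteins = {l.protein for l in lanes}
    probes = {l.probe for l in lanes}
    if len(proteins) > 1 or len(probes) > 1:
        raise ValueError("summarize_group expects lanes from a single protein/probe group")
    estimates = [tau_from_lane(l) for l in lanes]
    taus = [e.tau for e in estimates if e.included and e.defined]
    if not taus:
        return GroupSummary(proteins.pop(), probes.pop(), None, None, 0, len(lanes))
    mean = float(np.mean(taus))
    sd = float(np.std(taus, ddof=1)) if len(taus) >= 2 else None
    return GroupSummary(proteins.pop(), probes.pop(), mean, sd, len(taus), len(lanes))


def summarize_lanes(lanes: Sequence[LaneMeasurement]) -> list[GroupSummary]:
    """Group lanes by (protein, probe) and summarize each group."""
    groups: dict[tuple[str, str], list[LaneMeasurement]] = {}
    for lane in lanes:
        groups.setdefault((lane.protein, lane.probe), []).append(lane)
    return [summarize_group(g) for _, g in sorted(groups.items())]


# ---------------------------------------------------------------------------
# Comparison statistics


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    note: str = ""


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    with warnings.catch_warnings():
        # zero-variance groups are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    # Identical nonzero-variance groups give t = 0, p = 1; identical
    # zero-variance groups are reported the same way rather than as nan.
    if math.isnan(stat) and np.allclose(np.mean(a), np.mean(b)):
        return 0.0, 1.0
    return float(stat), float(p)


Design = Literal["auto", "welch", "student"]


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: Design = "auto",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Levene's test, pairwise t-tests with Holm adjustment, one-way ANOVA.

    With ``design="auto"`` the pairwise test is Welch's when the
    median-centered Levene test rejects variance homogeneity at ``alpha``,
    and Student's otherwise; ``"welch"``/``"student"`` force the choice.
    Groups with fewer than two observations yield per-comparison error
    entries instead of statistics.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("compare_groups requires at least two groups")
    results: list[ComparisonResult] = []

    degenerate = [k for k in names if arrays[k].size < 2]
    valid = [k for k in names if arrays[k].size >= 2]
    for k in degenerate:
        results.append(
            ComparisonResult("error", (k,), math.nan, math.nan,
                             note=f"group {k!r} has fewer than 2 included lanes")
        )
    if len(valid) < 2:
        return results

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lev_stat, lev_p = stats.levene(*(arrays[k] for k in valid), center="median")
    results.append(ComparisonResult("levene", tuple(valid), float(lev_stat), float(lev_p)))

    if design == "auto":
        equal_var = lev_p >= alpha
    elif design == "student":
        equal_var = True
    elif design == "welch":
        equal_var = False
    else:
        raise ValueError(f"unknown design {design!r}")
    test_name = "student_t" if equal_var else "welch_t"

    pairs = list(combinations(valid, 2))
    raw = []
    stats_ = []
    for a, b in pairs:
        t, p = _two_sample_t(arrays[a], arrays[b], equal_var=equal_var)
        stats_.append(t)
        raw.append(p)
    adjusted = holm_adjust(raw)
    for (a, b), t, p, padj in zip(pairs, stats_, raw, adjusted):
        results.append(
            ComparisonResult(test_name, (a, b), t, p, adjusted_p=float(padj))
        )

    if len(valid) >= 2:
        f_stat, f_p = stats.f_oneway(*(arrays[k] for k in valid))
        if math.isnan(f_stat):
            f_stat, f_p = 0.0, 1.0
        results.append(
            ComparisonResult("oneway_anova", tuple(valid), float(f_stat), float(f_p))
        )
    return results


def two_way_anova(
    table: pd.DataFrame,
    response: str = "tau",
    factor_a: str = "protein",
    factor_b: str = "concentration_nM",
) -> list[ComparisonResult]:
    """Two-way ANOVA (factor_a x factor_b) with type-II sums of squares.

    Intended for the balanced protein-by-concentration designs used in
    replicate titrations; unbalanced input triggers a warning but is still
    analyzed (type-II SS remain well defined).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cell_counts = table.groupby([factor_a, factor_b], observed=True).size()
    if cell_counts.nunique() > 1:
        warnings.warn(
            "two_way_anova: unbalanced design (unequal cell counts)", stacklevel=2
        )
    df = table.rename(columns={response: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    label = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    out = []
    for term, row in anova.iterrows():
        if term == "Residual":
            continue
        out.append(
            ComparisonResult(
                "twoway_anova", (label.get(str(term), str(term)),),
                float(row["F"]), float(row["PR(>F)"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Lane CSV I/O


def lanes_to_frame(lanes: Sequence[LaneMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe": l.probe,
                "protein": l.protein,
                "concentration_nM": l.concentration,
                "replicate": l.replicate,
                "I_free": l.i_free,
                "I_monomer": l.i_monomer,
                "I_dimer": l.i_dimer,
            }
            for l in lanes
        ],
        columns=list(LANE_COLUMNS),
    )


def frame_to_lanes(df: pd.DataFrame, source: str = "<table>") -> list[LaneMeasurement]:
    missing = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: lane table missing columns: {', '.join(missing)}")
    return [
        LaneMeasurement(
            probe=str(row.probe),
            protein=str(row.protein),
            concentration=float(row.concentration_nM),
            replicate=int(row.replicate),
            i_free=float(row.I_free),
            i_monomer=float(row.I_monomer),
            i_dimer=float(row.I_dimer),
        )
        for row in df.itertuples(index=False)
    ]


def read_lane_csv(path: str | Path) -> list[LaneMeasurement]:
    """Read the lane CSV dialect: probe,protein,concentration_nM,replicate,I_free,I_monomer,I_dimer."""
    return frame_to_lanes(pd.read_csv(path), source=str(path))


def write_lane_csv(lanes: Sequence[LaneMeasurement], path: str | Path) -> None:
    lanes_to_frame(lanes).to_csv(path, index=False)


def tau_table(lanes: Sequence[LaneMeasurement]) -> pd.DataFrame:
    """Per-lane Tau, bound fraction, depletion and inclusion flags."""
    rows = []
    for lane in lanes:
        est = tau_from_lane(lane)
        rows.append(
            {
                "probe": lane.probe,
                "protein": lane.protein,
                "concentration_nM": lane.concentration,
                "replicate": lane.replicate,
                "tau": est.tau,
                "bound_fraction": est.bound_fraction,
                "percent_bound": 100.0 * est.bound_fraction,
                "included": est.included,
                "tau_defined": est.defined,
            }
        )
    return pd.DataFrame(rows)
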