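"""Optional matplotlib renderings of the tabular outputs.

All analysis runs on the CSV/TSV outputs; these plots are conveniences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .constraints import BitMap, DifferentialBitMap
from .emsa import LaneMeasurement, tau_from_lane
from .sequences import CANONICAL_RESIDUES

# coarse biochemical coloring for logo letters
_COLORS = {
    **{aa: "#1f77b4" for aa in "KRH"},     # basic
    **{aa: "#d62728" for aa in "DE"},      # acidic
    **{aa: "#2ca02c" for aa in "STNQ"},    # polar
    **{aa: "#9467bd" for aa in "GPC"},     # special
    **{aa: "#000000" for aa in "AVILMFWY"},  # hydrophobic
}


def plot_bitmap(bitmap: BitMap | DifferentialBitMap, ax=None):
    """Logo-style stacked-letter rendering of a (differential) bit map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3))
    heights = bitmap.heights if isinstance(bitmap, BitMap) else bitmap.delta
    for p in range(heights.shape[0]):
        col = heights[p]
        order = np.argsort(np.abs(col))
        pos_base, neg_base = 0.0, 0.0
        for a in order:
            h = col[a]
            if h == 0:
                continue
            aa = CANONICAL_RESIDUES[a]
            if h > 0:
                y, pos_base = pos_base, pos_base + h
            else:
                neg_base += h
                y = neg_base
            ax.bar(p + 1, abs(h), bottom=y if h > 0 else y, width=0.85,
                   color=_COLORS.get(aa, "0.4"), edgecolor="white", linewidth=0.2)
            if abs(h) > 0.25:
                ax.text(p + 1, y + abs(h) / 2, aa, ha="center", va="center",
                        fontsize=6, color="white")
    ax.set_xlabel("HD position")
    ax.set_ylabel("bits")
    ax.set_xlim(0.25, heights.shape[0] + 0.75)
    return ax


def plot_tau_bars(lanes: Sequence[LaneMeasurement], ax=None):
    """Mean-Tau bars per (protein, probe) group with per-lane dots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups: dict[str, list[float]] = {}
    for lane in lanes:
        est = tau_from_lane(lane)
        if est.included and est.defined:
            groups.setdefault(f"{lane.protein}\n{lane.probe}", []).append(est.tau)
    labels = sorted(groups)
    for i, label in enumerate(labels):
        taus = groups[label]
        ax.bar(i, np.mean(taus), color="0.8", edgecolor="0.2")
        ax.scatter(np.full(len(taus), i), taus, s=12, color="0.1", zorder=3)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel(r"$\tau$")
    ax.axhline(1.0, ls="--", lw=0.8, color="0.5")  # independent binding
    return ax
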