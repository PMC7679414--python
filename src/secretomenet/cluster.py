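"""Hierarchical ordering of abundance profiles and per-protein substrate
profiles, the inputs behind heat-map and radar-style displays.

Rows are clustered with average linkage (UPGMA) on Euclidean distances.
For distance purposes a missing value is filled with -10, the same sentinel
the network stage uses for "not detected"; the heat-map export keeps the
true missingness and records the display bounds ([-5, 10] on the normalized
log2 scale) as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import AbundanceTable

__all__ = [
    "Dendrogram",
    "hierarchical_order",
    "substrate_profile",
    "heatmap_matrix",
    "write_heatmap_tsv",
    "MISSING_FILL",
    "HEATMAP_BOUNDS",
    "PROFILE_BOUNDS",
]

#: Sentinel used in place of missing values when computing distances.
MISSING_FILL = -10.0

#: Display bounds for heat maps on the normalized log2 scale.
HEATMAP_BOUNDS = (-5.0, 10.0)

#: Display bounds for radar-style substrate profiles.
PROFILE_BOUNDS = (-4.0, 8.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree over matrix rows."""

    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.merges)]


def hierarchical_order(
    matrix: pd.DataFrame, missing_fill: float = MISSING_FILL
) -> Dendrogram:
    """Cluster rows by UPGMA on Euclidean distance.

    Missing entries are filled with ``missing_fill`` so that shared absence
    contributes zero distance — two proteins undetected on the same
    substrates cluster together, mirroring the grey blocks of the heat maps.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    filled = matrix.fillna(missing_fill).to_numpy(dtype=float)
    merges = linkage(pdist(filled, metric="euclidean"), method="average")
    return Dendrogram(merges=merges, labels=list(matrix.index))


def substrate_profile(
    table: AbundanceTable,
    protein_id: str,
    fungus: str,
    substrates: Sequence[str] | None = None,
) -> pd.Series:
    """Replicate-averaged abundance of one protein across substrates.

    Returns the vector in fixed substrate order with missing values
    preserved (NaN); rendering clamps to :data:`PROFILE_BOUNDS`.
    """
    if protein_id not in table.values.index:
        raise KeyError(f"unknown protein {protein_id!r}")
    sub = table.for_fungus(fungus)
    if substrates is None:
        substrates = sub.substrates
    row = sub.values.loc[protein_id]
    out = {}
    for s in substrates:
        vals = row[row.index.get_level_values("substrate") == s]
        out[s] = float(vals.iloc[0]) if len(vals) and np.isfinite(vals.iloc[0]) else np.nan
    return pd.Series(out, name=protein_id)


def heatmap_matrix(
    matrix: pd.DataFrame, dendrogram: Dendrogram
) -> tuple[pd.DataFrame, dict]:
    """Rows permuted to dendrogram leaf order, plus display metadata."""
    ordered = matrix.loc[dendrogram.leaf_order]
    meta = {
        "vmin": HEATMAP_BOUNDS[0],
        "vmax": HEATMAP_BOUNDS[1],
        "missing": "not detected",
        "missing_fill_for_distance": MISSING_FILL,
    }
    return ordered, meta


def write_heatmap_tsv(
    matrix: pd.DataFrame, path: str | Path, na_rep: str = "NA"
) -> Path:
    path = Path(path)
    out = matrix.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = ["|".join(str(x) for x in c) for c in out.columns]
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep=na_rep)
    return path


def render_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Optional PNG/SVG rendering (cosmetic; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, matrix.shape[0] * 0.12)))
    data = matrix.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("gray").copy()
    cmap.set_bad("0.6")  # grey = not detected
    im = ax.imshow(masked, aspect="auto", cmap=cmap,
                   vmin=HEATMAP_BOUNDS[0], vmax=HEATMAP_BOUNDS[1])
    ax.set_yticks([])
    ax.set_xticks(range(matrix.shape[1]))
    labels = ["|".join(str(x) for x in c) if isinstance(c, tuple) else str(c)
              for c in matrix.columns]
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="normalized log2 LFQ")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
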