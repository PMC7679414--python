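"""Detection filtering, robust normalization and replicate handling.

The detection filter keeps a protein (within one fungus) only if it was
quantified in at least two of the three biological replicates on at least
one carbon source.  A kept protein then counts as *present* on any substrate
where it appears in even a single replicate — the single-replicate
carry-over used by per-substrate detection counts.

Normalization brings every raw file onto a common scale: log2 transform,
then subtraction of the sample's Tukey biweight, a robust location estimate
that down-weights outlying proteins with the bisquare weight
``(1 - u^2)^2`` for ``|u| < 1``, ``u = (x - t) / (c * MAD)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "NormalizationParams",
    "FilterDecision",
    "detection_filter",
    "apply_filter",
    "tukey_biweight_location",
    "normalize",
    "replicate_correlation",
    "average_replicates",
]


@dataclass
class NormalizationParams:
    """Free parameters of the biweight location estimator."""

    c: float = 5.0
    epsilon: float = 1e-6
    max_iterations: int = 50
    one_step: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("tuning constant c must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class FilterDecision:
    """Outcome of the two-of-three replicate filter.

    ``keep_by_fungus`` holds, per fungus, the proteins that pass the filter
    within that fungus; ``present_on`` holds, per protein, the
    (fungus, substrate) pairs on which it counts as detected (including the
    single-replicate carry-over).  ``keep_global`` is true if the protein is
    kept in at least one fungus.
    """

    keep_by_fungus: dict[str, set[str]]
    present_on: dict[str, set[tuple[str, str]]]

    @property
    def keep_global(self) -> dict[str, bool]:
        kept = set().union(*self.keep_by_fungus.values()) if self.keep_by_fungus else set()
        return {p: (p in kept) for p in self.present_on}

    def kept(self, protein_id: str, fungus: str | None = None) -> bool:
        if fungus is not None:
            return protein_id in self.keep_by_fungus.get(fungus, set())
        return self.keep_global.get(protein_id, False)

    def present(self, protein_id: str, fungus: str, substrate: str) -> bool:
        return (fungus, substrate) in self.present_on.get(protein_id, set())


def detection_filter(table: AbundanceTable, min_replicates: int = 2) -> FilterDecision:
    """Apply the two-of-three replicate rule per fungus.

    Fewer than three replicates in the data does not relax the rule: the
    threshold stays at ``min_replicates`` detected replicates on some
    substrate.
    """
    detected = table.values.notna()
    # detected replicate count per protein per (fungus, substrate)
    counts = detected.T.groupby(level=["fungus", "substrate"], sort=False).sum().T
    keep_by_fungus: dict[str, set[str]] = {}
    present_on: dict[str, set[tuple[str, str]]] = {p: set() for p in table.protein_ids}
    for fungus in table.fungi:
        sub = counts.loc[:, counts.columns.get_level_values("fungus") == fungus]
        kept_mask = (sub >= min_replicates).any(axis=1)
        kept = set(sub.index[kept_mask])
        keep_by_fungus[fungus] = kept
        present = sub >= 1
        for pid in kept:
            for (f, s), flag in present.loc[pid].items():
                if flag:
                    present_on[pid].add((f, s))
    return FilterDecision(keep_by_fungus=keep_by_fungus, present_on=present_on)


def apply_filter(table: AbundanceTable, decision: FilterDecision) -> AbundanceTable:
    """Restrict the table to globally kept proteins, masking values in fungi
    where the protein failed the filter."""
    keep = decision.keep_global
    kept_ids = [p for p in table.protein_ids if keep.get(p, False)]
    df = table.values.loc[kept_ids].copy()
    for fungus in table.fungi:
        cols = df.columns.get_level_values("fungus") == fungus
        dropped = [p for p in kept_ids if p not in decision.keep_by_fungus.get(fungus, set())]
        if dropped:
            df.loc[dropped, cols] = np.nan
    return AbundanceTable(df, scale=table.scale)


def _mad(x: np.ndarray, center: float) -> float:
    return float(np.median(np.abs(x - center)))


def tukey_biweight_location(
    values: Iterable[float], params: NormalizationParams | None = None
) -> float:
    """Tukey's biweight (bisquare) robust estimate of the average.

    Starts at the median with the (unnormalized) MAD as scale; points beyond
    ``c * MAD`` receive zero weight.  With ``one_step`` a single weighted
    mean is taken; otherwise the re-weighting iterates to convergence.  A
    zero MAD (more than half the values identical) falls back to the median.
    """
    params = params or NormalizationParams()
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size == 0:
        raise ValueError("biweight of an empty sample")
    t = float(np.median(x))
    mad = _mad(x, t)
    if mad == 0.0:
        return t
    for _ in range(1 if params.one_step else params.max_iterations):
        u = np.clip((x - t) / (params.c * mad), -1.0, 1.0)
        w = (1.0 - u**2) ** 2  # bisquare; clipped |u| >= 1 gets weight 0
        if w.sum() == 0.0:  # pathological: everything beyond c*MAD
            return t
        t_new = float(np.sum(w * x) / np.sum(w))
        if abs(t_new - t) < params.epsilon:
            return t_new
        t = t_new
    return t


def normalize(table: AbundanceTable, params: NormalizationParams | None = None) -> AbundanceTable:
    """Per raw file: log2 transform, then subtract the sample's biweight.

    Missing entries stay missing.  Input may be linear (transformed here) or
    already log2.  Detected non-positive linear intensities are an error.
    """
    params = params or NormalizationParams()
    df = table.values.copy()
    if table.scale == "linear":
        bad = (df <= 0).any().any()
        if bad:
            raise ValueError("detected non-positive intensity; cannot log2 transform")
        df = np.log2(df)
    elif table.scale != "log2":
        df = df.copy()  # already normalized input is allowed; re-centering is ~0
    offsets = {}
    for col in df.columns:
        sample = df[col].dropna()
        if sample.empty:
            offsets[col] = 0.0
            continue
        offsets[col] = tukey_biweight_location(sample.to_numpy(), params)
    df = df - pd.Series(offsets)
    out = AbundanceTable(df, scale="log2_normalized")
    out.normalization_offsets = offsets  # per-sample biweight, for the log
    return out


def replicate_correlation(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Pearson r between replicate raw files, per fungus/substrate.

    Computed over pairwise-complete (both detected) proteins; with fewer
    than three common proteins r is undefined and reported as NaN.  The
    study's own QC quoted replicate correlations of 0.86-0.98.
    """
    rows = []
    df = table.values
    for fungus in table.fungi:
        for substrate in table.substrates:
            cols = [
                c for c in df.columns if c[0] == fungus and c[1] == substrate
            ]
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    a, b = df[cols[i]], df[cols[j]]
                    ok = a.notna() & b.notna()
                    n = int(ok.sum())
                    if n < 3:
                        r = np.nan
                    else:
                        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
                        if av.std() == 0 or bv.std() == 0:
                            r = np.nan
                        else:
                            r = float(np.corrcoef(av, bv)[0, 1])
                    rows.append(
                        {
                            "fungus": fungus,
                            "substrate": substrate,
                            "replicate_a": cols[i][2],
                            "replicate_b": cols[j][2],
                            "n_common": n,
                            "r": r,
                        }
                    )
    return pd.DataFrame(rows)


def correlation_range(qc: pd.DataFrame) -> pd.DataFrame:
    """Min/max replicate correlation per fungus from a QC table."""
    out = qc.dropna(subset=["r"]).groupby("fungus")["r"].agg(["min", "max"])
    return out.rename(columns={"min": "r_min", "max": "r_max"})


def average_replicates(table: AbundanceTable) -> AbundanceTable:
    """Mean over detected replicates; all replicates missing stays missing."""
    df = table.values
    averaged = df.T.groupby(level=["fungus", "substrate"], sort=False).mean().T
    averaged.columns = pd.MultiIndex.from_tuples(
        [(f, s, 0) for f, s in averaged.columns], names=["fungus", "substrate", "replicate"]
    )
    return AbundanceTable(averaged, scale=table.scale)
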