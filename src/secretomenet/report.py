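"""Secretome summary tables.

Two reporting products: a per-fungus identification summary (identified /
secreted / CAZyme / uncharacterized counts with half-up-rounded integer
percentages) and a per-fungus enzyme-class x substrate detection table in
which the per-substrate counts honor the single-replicate carry-over of the
detection filter and multi-class families are counted in every mapped
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EnzymeClassMap, ProteinAnnotation, class_members
from .preprocess import FilterDecision

__all__ = [
    "round_half_up",
    "percent",
    "SecretomeSummary",
    "summarize_secretome",
    "class_substrate_table",
    "CAZYME_CATEGORIES",
]

#: Categories counted as CAZymes in the summary (stand-alone CBMs included).
CAZYME_CATEGORIES = frozenset({"GH", "CE", "PL", "AA", "LPMO", "CBM-only"})


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent(count: int, total: int) -> int | None:
    """Integer percentage, half-up; undefined (None) for an empty secretome."""
    if total == 0:
        return None
    return round_half_up(100.0 * count / total)


@dataclass
class SecretomeSummary:
    """Per-fungus identification summary with aggregate rows."""

    per_fungus: pd.DataFrame  # index fungus; count and pct columns
    mean_cazyme_pct: int | None

    @property
    def totals(self) -> pd.Series:
        return self.per_fungus[
            ["n_identified", "n_secreted", "n_cazymes", "n_uncharacterized"]
        ].sum()

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]]
    ) -> "SecretomeSummary":
        """Build the summary from already-tallied per-fungus counts.

        ``counts`` maps fungus -> {n_identified, n_secreted, n_cazymes,
        n_uncharacterized}; percentages are recomputed here.
        """
        rows = {}
        for fungus, c in counts.items():
            n = int(c["n_identified"])
            rows[fungus] = {
                "n_identified": n,
                "n_secreted": int(c.get("n_secreted", 0)),
                "pct_secreted": percent(int(c.get("n_secreted", 0)), n),
                "n_cazymes": int(c.get("n_cazymes", 0)),
                "pct_cazymes": percent(int(c.get("n_cazymes", 0)), n),
                "n_uncharacterized": int(c.get("n_uncharacterized", 0)),
                "pct_uncharacterized": percent(int(c.get("n_uncharacterized", 0)), n),
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "fungus"
        pcts = [p for p in df["pct_cazymes"] if p is not None]
        mean_pct = round_half_up(float(np.mean(pcts))) if pcts else None
        return cls(per_fungus=df, mean_cazyme_pct=mean_pct)


def summarize_secretome(
    annotations_by_fungus: Mapping[str, Iterable[ProteinAnnotation]],
) -> SecretomeSummary:
    """Tally the per-fungus identification summary.

    Input is the set of annotations for proteins that passed the detection
    filter in each fungus.  CAZymes include stand-alone CBMs; the
    uncharacterized count covers proteins described as uncharacterized or
    with no predicted CAZy/peptidase domain.
    """
    counts: dict[str, dict[str, int]] = {}
    for fungus, anns in annotations_by_fungus.items():
        anns = list(anns)
        counts[fungus] = {
            "n_identified": len(anns),
            "n_secreted": sum(a.is_secreted_consensus for a in anns),
            "n_cazymes": sum(a.category in CAZYME_CATEGORIES for a in anns),
            "n_uncharacterized": sum(a.category == "uncharacterized" for a in anns),
        }
    return SecretomeSummary.from_counts(counts)


def class_substrate_table(
    annotations: Mapping[str, ProteinAnnotation],
    decision: FilterDecision,
    class_map: EnzymeClassMap,
    fungus: str,
    substrates: Sequence[str],
    genome_counts: Mapping[str, int] | None = None,
    include_cbm_only: bool = True,
) -> pd.DataFrame:
    """Per-substrate detection counts per enzyme class for one fungus.

    A protein counts on a substrate when the filter marks it present there —
    which includes single-replicate detections, provided the protein passed
    the two-replicate rule on some substrate.  Proteins whose families map
    to several classes are counted in each.  ``genome_counts`` (class ->
    genome-encoded total) is optional user input shown as its own column.
    """
    kept = decision.keep_by_fungus.get(fungus, set())
    kept_anns = {p: a for p, a in annotations.items() if p in kept}
    members = class_members(kept_anns, class_map)
    if include_cbm_only:
        members["CBM only"] = {p for p, a in kept_anns.items() if a.category == "CBM-only"}
    rows = []
    for cls_label, prots in members.items():
        row = {"enzyme_class": cls_label, "detected_total": len(prots)}
        if genome_counts is not None:
            row["genome_encoded"] = int(genome_counts.get(cls_label, 0))
        for s in substrates:
            row[s] = sum(decision.present(p, fungus, s) for p in prots)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("enzyme_class")
    lead = (["genome_encoded"] if genome_counts is not None else []) + ["detected_total"]
    return df[lead + list(substrates)]
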