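"""Synthetic secretome studies with planted co-expression structure.

The generator emulates the statistical shape of a plate-grown fungal
secretome LFQ experiment: several fungi grown on a panel of carbon sources
(one of them a free sugar on which no carbohydrate-active enzyme is
induced), three biological replicates per fungus x substrate, log-normal
protein abundances with substrate-dependent induction of co-regulated
enzyme classes, and left-censoring at a detection threshold so that weakly
expressed proteins go missing exactly where real LFQ tables show gaps.

The abundance of protein ``p`` in sample ``(f, s, r)`` is, on the log2
scale,

    x = base(p) + induction(class(p), s) + noise(f, s, r)

with ``base ~ N(base_mu, base_sigma^2)`` drawn once per protein,
a fixed additive induction effect per (enzyme class, substrate), and i.i.d.
replicate noise ``N(0, noise_sigma^2)``.  The table records the linear
intensity ``2**x`` when ``x`` reaches the detection threshold and a missing
value otherwise.  On the free-sugar substrate every enzyme class receives
zero induction.

Annotations are generated alongside: every protein in the class catalog
carries a CAZy family that maps to its class under the packaged class map, a
configurable fraction carries a second family (multi-domain proteins),
background proteins are a mix of peptidases, CBM-only and uncharacterized
proteins, and the three signal-peptide predictors are noisy reads of a true
secretion flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    EnzymeClassMap,
    ProteinAnnotation,
    read_abundance,
    read_annotations,
)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_study",
    "write_fixtures",
    "read_study",
    "default_class_catalog",
    "default_induction_effects",
    "DEFAULT_SUBSTRATES",
]

#: Carbon-source panel: three lignocellulosic substrates, pure cellulose,
#: and glucose as the free sugar.
DEFAULT_SUBSTRATES = ("bagasse", "birch", "spruce", "cellulose", "glucose")

#: Default per-class induction effect on the log2 scale.
DEFAULT_EFFECT = 6.0

_PEPTIDASE_POOL = ("S8", "S10", "A1", "M35", "M36", "C13")


def default_class_catalog() -> list[tuple[str, int]]:
    """Eight enzyme classes, six proteins each.

    Three co-induced pairs (cellulases on cellulose, hemicellulases on the
    grass/hardwood substrates, lignin oxidoreductases on softwood) plus two
    never-induced background classes.
    """
    return [
        ("endoglucanase", 6),
        ("cellobiohydrolase", 6),
        ("xylanase", 6),
        ("feruloyl_esterase", 6),
        ("laccase", 6),
        ("peroxidase", 6),
        ("beta_glucosidase", 6),
        ("polygalacturonase", 6),
    ]


def default_induction_effects(effect: float = DEFAULT_EFFECT) -> dict[tuple[str, str], float]:
    """Planted (class, substrate) induction map with three co-induced pairs."""
    eff: dict[tuple[str, str], float] = {}
    for cls in ("endoglucanase", "cellobiohydrolase"):
        eff[(cls, "cellulose")] = effect
    for cls in ("xylanase", "feruloyl_esterase"):
        eff[(cls, "bagasse")] = effect
        eff[(cls, "birch")] = effect
    for cls in ("laccase", "peroxidase"):
        eff[(cls, "spruce")] = effect
    return eff


@dataclass
class SyntheticConfig:
    """Study design and generative parameters; see the module docstring."""

    n_fungi: int = 5
    n_substrates: int = 5
    n_replicates: int = 3
    n_proteins: int = 90
    class_catalog: list[tuple[str, int]] = field(default_factory=default_class_catalog)
    induction_effects: dict[tuple[str, str], float] = field(
        default_factory=default_induction_effects
    )
    base_mu: float = 22.0
    base_sigma: float = 1.5
    noise_sigma: float = 0.8
    detection_threshold: float = 23.0
    multi_annotation_rate: float = 0.15
    predictor_error_rate: float = 0.1
    secretion_rate_cazyme: float = 0.9
    secretion_rate_background: float = 0.4
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    free_sugar: str = "glucose"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fungi", "n_substrates", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for name in ("multi_annotation_rate", "predictor_error_rate",
                     "secretion_rate_cazyme", "secretion_rate_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("base_sigma", "noise_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_substrates > len(self.substrates):
            raise ValueError("not enough substrate names for n_substrates")
        planted_total = sum(n for _, n in self.class_catalog)
        if planted_total > self.n_proteins:
            raise ValueError(
                f"class catalog assigns {planted_total} proteins but n_proteins={self.n_proteins}"
            )

    @property
    def substrate_panel(self) -> list[str]:
        panel = list(self.substrates[: self.n_substrates])
        if self.free_sugar not in panel:
            panel[-1] = self.free_sugar
        return panel

    @property
    def fungi(self) -> list[str]:
        return [f"fungus{i + 1}" for i in range(self.n_fungi)]


@dataclass
class TruthRecord:
    """Ground truth of a synthetic study, for recovery tests."""

    planted_pairs: set[frozenset[str]]
    class_labels: dict[str, tuple[str, ...]]  # protein -> true enzyme classes
    secreted: dict[str, bool]
    detection_threshold: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_pairs": sorted(sorted(p) for p in self.planted_pairs),
            "class_labels": {k: list(v) for k, v in sorted(self.class_labels.items())},
            "secreted": dict(sorted(self.secreted.items())),
            "detection_threshold": self.detection_threshold,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_pairs={frozenset(p) for p in payload["planted_pairs"]},
            class_labels={k: tuple(v) for k, v in payload["class_labels"].items()},
            secreted={k: bool(v) for k, v in payload["secreted"].items()},
            detection_threshold=float(payload["detection_threshold"]),
        )


def planted_pairs_from_effects(
    effects: Mapping[tuple[str, str], float], classes: Sequence[str]
) -> set[frozenset[str]]:
    """Class pairs whose induction profiles are identical and non-empty."""
    profiles = {
        c: tuple(sorted((s, e) for (cc, s), e in effects.items() if cc == c and e != 0.0))
        for c in classes
    }
    out: set[frozenset[str]] = set()
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            if profiles[a] and profiles[a] == profiles[b]:
                out.add(frozenset((a, b)))
    return out


def _representative_family(cls_label: str, class_map: EnzymeClassMap) -> str:
    """A CAZy family mapping to the class; prefer one mapping only to it."""
    exact = sorted(f for f, cs in class_map.mapping.items() if cs == frozenset((cls_label,)))
    if exact:
        return exact[0]
    any_hit = sorted(f for f, cs in class_map.mapping.items() if cls_label in cs)
    if not any_hit:
        raise ValueError(f"class {cls_label!r} has no family in the class map")
    return any_hit[0]


def generate_study(
    config: SyntheticConfig,
    class_map: EnzymeClassMap | None = None,
) -> tuple[AbundanceTable, dict[str, ProteinAnnotation], TruthRecord]:
    """Draw one full study; a fixed seed gives byte-identical output."""
    if class_map is None:
        class_map = EnzymeClassMap.default()
    rng = np.random.default_rng(config.seed)
    substrates = config.substrate_panel
    fungi = config.fungi
    reps = range(1, config.n_replicates + 1)

    # -- protein catalog and annotations --------------------------------
    protein_classes: list[tuple[str, ...]] = []
    families: list[set[str]] = []
    kinds: list[str] = []
    for cls_label, n in config.class_catalog:
        fam = _representative_family(cls_label, class_map)
        for _ in range(n):
            protein_classes.append((cls_label,))
            families.append({fam})
            kinds.append("cazyme")
    n_background = config.n_proteins - len(protein_classes)
    for k in range(n_background):
        protein_classes.append(())
        u = rng.uniform()
        if u < 0.45:
            families.append(set())
            kinds.append("uncharacterized")
        elif u < 0.80:
            families.append(set())
            kinds.append("peptidase")
        else:
            families.append({"CBM1"})
            kinds.append("cbm_only")

    n = len(protein_classes)
    width = max(4, len(str(max(n, 1))))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    # multi-domain proteins: a second family drawn from the map
    family_pool = sorted(class_map.mapping)
    annotations: dict[str, ProteinAnnotation] = {}
    truth_classes: dict[str, tuple[str, ...]] = {}
    truth_secreted: dict[str, bool] = {}
    for i, pid in enumerate(protein_ids):
        fams = set(families[i])
        classes = set(protein_classes[i])
        if kinds[i] == "cazyme" and rng.uniform() < config.multi_annotation_rate:
            extra = family_pool[rng.integers(len(family_pool))]
            fams.add(extra)
            classes.update(class_map.lookup(extra))
        peptidases: set[str] = set()
        description = ""
        if kinds[i] == "peptidase":
            peptidases.add(_PEPTIDASE_POOL[rng.integers(len(_PEPTIDASE_POOL))])
        elif kinds[i] == "uncharacterized":
            description = "uncharacterized protein"
        secreted_rate = (
            config.secretion_rate_cazyme if kinds[i] == "cazyme"
            else config.secretion_rate_background
        )
        truly_secreted = bool(rng.uniform() < secreted_rate)
        calls = tuple(
            bool(truly_secreted ^ (rng.uniform() < config.predictor_error_rate))
            for _ in range(3)
        )
        annotations[pid] = ProteinAnnotation(
            protein_id=pid,
            cazy_families=frozenset(fams),
            peptidase_families=frozenset(peptidases),
            predictor_calls=calls,
            description=description,
        )
        truth_classes[pid] = tuple(sorted(classes))
        truth_secreted[pid] = truly_secreted

    # -- abundances ------------------------------------------------------
    columns = pd.MultiIndex.from_tuples(
        [(f, s, r) for f in fungi for s in substrates for r in reps],
        names=["fungus", "substrate", "replicate"],
    )
    base = rng.normal(config.base_mu, config.base_sigma, size=n)
    induction = np.zeros((n, len(substrates)))
    for i in range(n):
        for j, s in enumerate(substrates):
            if s == config.free_sugar:
                continue  # no enzyme class is induced on the free sugar
            effects = [
                config.induction_effects.get((c, s), 0.0) for c in truth_classes[protein_ids[i]]
            ]
            induction[i, j] = max(effects, default=0.0)
    noise = rng.normal(0.0, config.noise_sigma, size=(n, len(columns)))
    log2x = np.empty((n, len(columns)))
    for k, (_f, s, _r) in enumerate(columns):
        sj = substrates.index(s)
        log2x[:, k] = base + induction[:, sj] + noise[:, k]
    detected = log2x >= config.detection_threshold
    linear = np.where(detected, np.exp2(log2x), np.nan)

    table = AbundanceTable(
        pd.DataFrame(linear, index=protein_ids, columns=columns), scale="linear"
    )
    truth = TruthRecord(
        planted_pairs=planted_pairs_from_effects(
            config.induction_effects, [c for c, _ in config.class_catalog]
        ),
        class_labels=truth_classes,
        secreted=truth_secreted,
        detection_threshold=config.detection_threshold,
    )
    return table, annotations, truth


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "abundance": "abundance.tsv",
    "cazy": "cazy.tsv",
    "merops": "merops.tsv",
    "signalp": "signalp.tsv",
    "phobius": "phobius.tsv",
    "wolfpsort": "wolfpsort.tsv",
    "descriptions": "descriptions.tsv",
    "class_map": "class_map.tsv",
    "truth": "truth.json",
}


def write_fixtures(
    bundle: tuple[AbundanceTable, Mapping[str, ProteinAnnotation], TruthRecord],
    directory: str | Path,
    class_map: EnzymeClassMap | None = None,
) -> dict[str, Path]:
    """Write the TSV/JSON input set a real study would provide.

    Output is deterministic given the bundle: rows follow the abundance
    table's protein order and annotation families are sorted.
    """
    table, annotations, truth = bundle
    if class_map is None:
        class_map = EnzymeClassMap.default()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}

    table.to_tsv(paths["abundance"])

    ordered = [annotations[p] for p in table.protein_ids]
    cazy_rows = [(a.protein_id, f) for a in ordered for f in sorted(a.cazy_families)]
    pd.DataFrame(cazy_rows, columns=["protein_id", "family"]).to_csv(
        paths["cazy"], sep="\t", index=False
    )
    merops_rows = [(a.protein_id, f) for a in ordered for f in sorted(a.peptidase_families)]
    pd.DataFrame(merops_rows, columns=["protein_id", "family"]).to_csv(
        paths["merops"], sep="\t", index=False
    )
    for idx, key in enumerate(("signalp", "phobius", "wolfpsort")):
        rows = [(a.protein_id, int(a.predictor_calls[idx])) for a in ordered]
        pd.DataFrame(rows, columns=["protein_id", "secreted"]).to_csv(
            paths[key], sep="\t", index=False
        )
    pd.DataFrame(
        [(a.protein_id, a.description) for a in ordered],
        columns=["protein_id", "description"],
    ).to_csv(paths["descriptions"], sep="\t", index=False)
    class_map.to_tsv(paths["class_map"])
    truth.to_json(paths["truth"])
    return paths


def read_study(
    directory: str | Path,
) -> tuple[AbundanceTable, dict[str, ProteinAnnotation], EnzymeClassMap, TruthRecord]:
    """Read back a fixture directory written by :func:`write_fixtures`."""
    directory = Path(directory)
    p = {k: directory / v for k, v in FIXTURE_FILES.items()}
    table = read_abundance(p["abundance"])
    annotations = read_annotations(
        table.protein_ids,
        p["cazy"],
        p["merops"],
        (p["signalp"], p["phobius"], p["wolfpsort"]),
        p["descriptions"],
    )
    class_map = EnzymeClassMap.from_tsv(p["class_map"])
    truth = TruthRecord.from_json(p["truth"])
    return table, annotations, class_map, truth
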