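"""Input tables, annotation rules and the secretion-consensus vote.

The quantification input is a MaxQuant-style protein-groups table reduced to
a TSV of LFQ intensities: one row per protein, one column per raw file, the
column header encoding the sample as ``fungus|substrate|replicate``.  A zero
or blank intensity means the protein was not quantified in that raw file.

Annotations arrive as reduced TSV dialects of the upstream predictors'
outputs: CAZy family assignments (dbCAN-style, one hit per row), peptidase
family assignments (MEROPS-style), and three signal-peptide predictor call
tables reduced to per-protein booleans.  How the upstream predictors were
thresholded (in particular WoLF-PSORT's score-based "fungal pattern") is
outside this package; the boolean tables are taken at face value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "AbundanceTable",
    "ProteinAnnotation",
    "EnzymeClassMap",
    "read_abundance",
    "consensus_secretion",
    "assign_category",
    "class_members",
    "read_annotations",
    "LPMO_FAMILIES",
    "CATALYTIC_PREFIXES",
]

#: AA families whose members are lytic polysaccharide monooxygenases.
LPMO_FAMILIES = frozenset({"AA9", "AA11", "AA13", "AA14", "AA16"})

#: CAZy prefixes that denote a catalytic module (CBM is binding-only).
CATALYTIC_PREFIXES = ("GH", "CE", "PL", "AA")

CATEGORIES = (
    "GH", "CE", "PL", "AA", "LPMO",
    "CBM-only", "peptidase", "uncharacterized", "other",
)


class SampleKey(NamedTuple):
    """One raw file: a (fungus, substrate, replicate) triple."""

    fungus: str
    substrate: str
    replicate: int

    def __str__(self) -> str:  # header form
        return f"{self.fungus}|{self.substrate}|{self.replicate}"

    @classmethod
    def parse(cls, token: str) -> "SampleKey":
        parts = token.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"malformed sample key {token!r}: expected fungus|substrate|replicate"
            )
        fungus, substrate, rep = parts
        try:
            replicate = int(rep)
        except ValueError as exc:
            raise ValueError(f"malformed sample key {token!r}: replicate not an integer") from exc
        return cls(fungus, substrate, replicate)


@dataclass
class AbundanceTable:
    """Proteins x samples quantification matrix with explicit missingness.

    ``values`` is a DataFrame indexed by protein id with a three-level column
    MultiIndex (fungus, substrate, replicate); NaN marks "not detected".
    ``scale`` records what the numbers are: raw ``linear`` LFQ intensities,
    ``log2`` transformed, or ``log2_normalized`` (log2 minus the per-sample
    Tukey biweight).
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2", "log2_normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dup}")
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValueError("columns must be a (fungus, substrate, replicate) MultiIndex")
        if cols.has_duplicates:
            raise ValueError("duplicate sample keys")

    # -- structure -----------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(f, s, int(r)) for f, s, r in self.values.columns]

    @property
    def fungi(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.values.columns.get_level_values(0):
            seen.setdefault(f, None)
        return list(seen)

    @property
    def substrates(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns.get_level_values(1):
            seen.setdefault(s, None)
        return list(seen)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def for_fungus(self, fungus: str) -> "AbundanceTable":
        sub = self.values.loc[:, self.values.columns.get_level_values(0) == fungus]
        return AbundanceTable(sub, scale=self.scale)

    def subset(self, protein_ids: Iterable[str]) -> "AbundanceTable":
        wanted = [p for p in self.protein_ids if p in set(protein_ids)]
        return AbundanceTable(self.values.loc[wanted], scale=self.scale)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.values.copy(), scale=self.scale)

    # -- serialization -------------------------------------------------
    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.values.copy()
        out.columns = [str(SampleKey(f, s, int(r))) for f, s, r in out.columns]
        out.index.name = "protein_id"
        # %.17g is round-trippable for float64, so read-back is lossless
        out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")
        return path

    def equals(self, other: "AbundanceTable") -> bool:
        if self.scale != other.scale:
            return False
        a, b = self.values, other.values
        if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
            return False
        return bool(((a.values == b.values) | (np.isnan(a.values) & np.isnan(b.values))).all())


def _columns_from_tokens(tokens: Sequence[str]) -> pd.MultiIndex:
    keys = [SampleKey.parse(t) for t in tokens]
    return pd.MultiIndex.from_tuples(keys, names=["fungus", "substrate", "replicate"])


def read_abundance(path: str | Path, scale: str = "linear") -> AbundanceTable:
    """Read a proteins x samples TSV.

    Blank cells and zeros are recorded as missing — a MaxQuant LFQ intensity
    of 0 means the protein was not quantified in that raw file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in {path}: {dup}")
    df.columns = _columns_from_tokens(list(df.columns))
    df = df.astype(float)
    if scale == "linear":
        df = df.mask(df == 0.0)
    return AbundanceTable(df, scale=scale)


def consensus_secretion(calls: Sequence[bool | None]) -> bool:
    """Majority vote over the three signal-peptide predictors.

    A protein is called secreted when at least two of the three predictors
    call a signal peptide.  A missing call counts as a "not secreted" vote
    (a predictor that returned nothing found no signal peptide).
    """
    if len(calls) != 3:
        raise ValueError(f"expected exactly three predictor calls, got {len(calls)}")
    return sum(bool(c) for c in calls if c is not None) >= 2


def _family_prefix(token: str) -> str:
    i = 0
    while i < len(token) and token[i].isalpha():
        i += 1
    return token[:i].upper()


def _family_root(token: str) -> str:
    # subfamily notation: AA3_2 -> family AA3, subfamily 2
    return token.split("_", 1)[0]


@dataclass
class ProteinAnnotation:
    """Per-protein functional annotation.

    Overlapping membership is first-class: a protein may carry several CAZy
    families (multi-domain proteins) and a peptidase family at the same time.
    ``is_secreted_consensus`` and ``category`` are derived on construction.
    """

    protein_id: str
    cazy_families: frozenset[str] = frozenset()
    peptidase_families: frozenset[str] = frozenset()
    predictor_calls: tuple[bool, bool, bool] = (False, False, False)
    description: str = ""
    is_secreted_consensus: bool = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.cazy_families = frozenset(self.cazy_families)
        self.peptidase_families = frozenset(self.peptidase_families)
        if len(self.predictor_calls) != 3:
            raise ValueError("predictor_calls must hold exactly three booleans")
        self.predictor_calls = tuple(bool(c) for c in self.predictor_calls)
        self.is_secreted_consensus = consensus_secretion(self.predictor_calls)
        self.category = assign_category(self)


def assign_category(annotation: "ProteinAnnotation") -> str:
    """Assign the single reporting category for a protein.

    Precedence: a catalytic CAZy module (GH > CE > PL > AA; an AA module from
    an LPMO family is reported as LPMO) beats a peptidase domain — a protein
    predicted as both carbohydrate esterase and peptidase counts as CE.  A
    peptidase beats CBM-only; a protein with only a binding module is
    "CBM-only".  With no domain at all, or a description calling it
    uncharacterized, the protein is "uncharacterized".
    """
    catalytic = sorted(
        f for f in annotation.cazy_families if _family_prefix(f) in CATALYTIC_PREFIXES
    )
    if catalytic:
        for prefix in CATALYTIC_PREFIXES:
            fams = [f for f in catalytic if _family_prefix(f) == prefix]
            if fams:
                if prefix == "AA" and any(_family_root(f) in LPMO_FAMILIES for f in fams):
                    return "LPMO"
                return prefix
    if annotation.peptidase_families:
        return "peptidase"
    if any(_family_prefix(f) == "CBM" for f in annotation.cazy_families):
        return "CBM-only"
    if "uncharacterized" in annotation.description.lower() or not annotation.cazy_families:
        return "uncharacterized"
    return "other"


@dataclass
class EnzymeClassMap:
    """Mapping from CAZy family (or subfamily) tokens to enzyme-class labels.

    A family may map to several classes (GH5 is both an endoglucanase and an
    endomannanase family); a subfamily-specific row (AA3_1) takes precedence
    over the plain family row when present.
    """

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.mapping = {fam: frozenset(cls) for fam, cls in self.mapping.items()}

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for cls_set in self.mapping.values():
            for c in sorted(cls_set):
                seen.setdefault(c, None)
        return list(seen)

    def lookup(self, family_token: str) -> frozenset[str]:
        """Classes for a family token; subfamily row first, then family row."""
        if family_token in self.mapping:
            return self.mapping[family_token]
        root = _family_root(family_token)
        return self.mapping.get(root, frozenset())

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EnzymeClassMap":
        mapping: dict[str, set[str]] = {}
        for fam, label in pairs:
            mapping.setdefault(fam, set()).add(label)
        return cls({f: frozenset(s) for f, s in mapping.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeClassMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [(fam, c) for fam in sorted(self.mapping) for c in sorted(self.mapping[fam])]
        pd.DataFrame(rows, columns=["family", "enzyme_class"]).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def default(cls) -> "EnzymeClassMap":
        """The packaged map of lignocellulose-relevant families to classes."""
        ref = resources.files("secretomenet.data").joinpath("class_map.tsv")
        with resources.as_file(ref) as p:
            return cls.from_tsv(p)


def class_members(
    annotations: Mapping[str, ProteinAnnotation] | Iterable[ProteinAnnotation],
    class_map: EnzymeClassMap,
) -> dict[str, set[str]]:
    """Group proteins into (possibly overlapping) enzyme-class sets.

    A protein with multiple annotations joins every mapped class; unmapped
    families simply contribute nothing.  Malformed family tokens (no CAZy
    prefix) are skipped with a warning.
    """
    if isinstance(annotations, Mapping):
        annotations = annotations.values()
    members: dict[str, set[str]] = {c: set() for c in class_map.classes}
    for ann in annotations:
        for fam in sorted(ann.cazy_families):
            prefix = _family_prefix(fam)
            if prefix not in CATALYTIC_PREFIXES + ("CBM",):
                warnings.warn(f"unknown CAZy family token {fam!r} on {ann.protein_id}; skipped")
                continue
            for cls_label in class_map.lookup(fam):
                members.setdefault(cls_label, set()).add(ann.protein_id)
    return members


# ---------------------------------------------------------------------------
# Reduced-TSV annotation bundle
# ---------------------------------------------------------------------------

def _read_family_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for pid, fam in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(pid), set()).add(str(fam))
    return out


def _read_call_tsv(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {str(p): str(v).strip() in ("1", "True", "true") for p, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_annotations(
    protein_ids: Iterable[str],
    cazy_path: str | Path,
    peptidase_path: str | Path,
    predictor_paths: Sequence[str | Path],
    descriptions_path: str | Path | None = None,
) -> dict[str, ProteinAnnotation]:
    """Assemble per-protein annotations from the reduced TSV bundle.

    ``predictor_paths`` are the three boolean call tables (SignalP-, Phobius-
    and WoLF-PSORT-style, in that order).  Proteins absent from a predictor
    table get a False vote; proteins absent from the family tables get empty
    family sets.
    """
    if len(predictor_paths) != 3:
        raise ValueError("exactly three predictor call tables are required")
    cazy = _read_family_tsv(cazy_path)
    merops = _read_family_tsv(peptidase_path)
    calls = [_read_call_tsv(p) for p in predictor_paths]
    descriptions: dict[str, str] = {}
    if descriptions_path is not None:
        df = pd.read_csv(descriptions_path, sep="\t", dtype=str).fillna("")
        descriptions = {str(p): str(d) for p, d in zip(df.iloc[:, 0], df.iloc[:, 1])}
    out: dict[str, ProteinAnnotation] = {}
    for pid in protein_ids:
        pid = str(pid)
        out[pid] = ProteinAnnotation(
            protein_id=pid,
            cazy_families=frozenset(cazy.get(pid, set())),
            peptidase_families=frozenset(merops.get(pid, set())),
            predictor_calls=tuple(c.get(pid, False) for c in calls),
            description=descriptions.get(pid, ""),
        )
    return out
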