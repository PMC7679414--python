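"""Enzyme-class co-expression networks.

The pipeline's core computation.  Per fungus, a protein-level weighted graph
is built: after substituting missing normalized values with -10 (the floor
of the observed LFQ scale), the edge weight between two proteins is the
absolute Pearson correlation of their profiles across all raw files,
optionally raised to a soft-thresholding power beta (default 1, i.e. the
correlation itself).

The protein graph is then collapsed onto (possibly overlapping) enzyme
classes S_1..S_n.  The interaction coefficient between classes i and j is
the mean pairwise edge weight

    C_ij = sum_{v in S_i} sum_{u in S_j} e_vu / (|S_i| * |S_j|)

and for the intra-class case i = j both numerator and denominator are
reduced by |S_i| to discard each protein's unit self-correlation:

    C_ii = (sum sum e_vu - |S_i|) / (|S_i|^2 - |S_i|)

The per-fungus class networks are averaged entry-wise (entries undefined in
a fungus — empty class — are omitted from the mean), node strength is the
sum of a node's defined incident weights (self-loop counted once), weights
are discretized to integers 0..100, and edges are pruned with the marginal
likelihood filter: under a strength-preserving null each of the T unit
edges attaches to pair (i, j) with probability p_ij = k_i * k_j / (2 T^2),
so an observed integer weight w has upper-tail p-value
P(Binomial(T, p_ij) >= w).  Edges with p < alpha (default 0.05) survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cluster import MISSING_FILL

__all__ = [
    "ProteinNetwork",
    "ClassNetwork",
    "EdgeSignificance",
    "impute_missing",
    "protein_adjacency",
    "collapse_classes",
    "average_class_networks",
    "node_strength",
    "discretize_weights",
    "edge_pvalue",
    "mlf_edge_pvalues",
    "filter_network",
    "export_network",
    "import_graphml",
]


def impute_missing(matrix: pd.DataFrame, fill: float = MISSING_FILL) -> pd.DataFrame:
    """Substitute missing normalized values with the LFQ floor (-10)."""
    return matrix.fillna(fill)


@dataclass
class ProteinNetwork:
    """Symmetric weighted graph over one fungus's proteins; weights in [0,1],
    unit diagonal."""

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.nanmin(w) < -1e-12 or np.nanmax(w) > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("diagonal must be 1")
        self.weights = w

    def edge(self, a: str, b: str) -> float:
        i, j = self.node_ids.index(a), self.node_ids.index(b)
        return float(self.weights[i, j])


def protein_adjacency(matrix: pd.DataFrame, beta: float = 1.0) -> ProteinNetwork:
    """Protein co-expression adjacency: |Pearson r|^beta over sample profiles.

    Expects an imputed (no-NaN) matrix of proteins x raw files.  A constant
    profile has undefined correlation; its edges are set to 0 (an
    all-imputed protein carries no co-expression signal).  The diagonal is 1.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate profiles")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    adj = np.clip(adj, 0.0, 1.0)
    adj = (adj + adj.T) / 2  # exact symmetry against fp noise
    return ProteinNetwork(node_ids=list(matrix.index), weights=adj)


@dataclass
class ClassNetwork:
    """Enzyme-class graph: interaction coefficients C (NaN = undefined),
    class sizes |S_i|, and optionally integer weights and edge p-values."""

    classes: list[str]
    sizes: np.ndarray  # |S_i| per class
    C: np.ndarray  # symmetric, NaN where undefined; diagonal = intra-class
    int_weights: np.ndarray | None = None  # 0 = no edge, off-diagonal only
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.classes)
        self.sizes = np.asarray(self.sizes, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if C.shape != (n, n):
            raise ValueError("C shape does not match class count")
        if not np.allclose(C, C.T, equal_nan=True, atol=1e-12):
            raise ValueError("C must be symmetric")
        defined = ~np.isnan(C)
        if defined.any() and (C[defined].min() < -1e-9 or C[defined].max() > 1 + 1e-9):
            raise ValueError("defined C entries must lie in [0, 1]")
        self.C = C

    def index(self, label: str) -> int:
        return self.classes.index(label)

    def coefficient(self, a: str, b: str) -> float:
        return float(self.C[self.index(a), self.index(b)])

    def size(self, label: str) -> int:
        return int(self.sizes[self.index(label)])


def collapse_classes(
    net: ProteinNetwork, class_sets: Mapping[str, set[str] | Sequence[str]]
) -> ClassNetwork:
    """Collapse a protein graph onto enzyme classes (overlap allowed).

    ``class_sets`` maps class label -> member proteins (must be network
    nodes).  Empty classes yield undefined (NaN) entries; an intra-class
    coefficient needs at least two members, otherwise it is undefined.
    """
    labels = list(class_sets)
    index = {p: i for i, p in enumerate(net.node_ids)}
    n_cls = len(labels)
    membership = np.zeros((len(net.node_ids), n_cls))
    for j, label in enumerate(labels):
        for p in class_sets[label]:
            if p not in index:
                raise KeyError(f"class {label!r} member {p!r} is not a network node")
            membership[index[p], j] = 1.0
    sizes = membership.sum(axis=0)
    pair_sums = membership.T @ net.weights @ membership  # sum_{v in Si} sum_{u in Sj} e_vu
    C = np.full((n_cls, n_cls), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(sizes, sizes)
        off = np.where(denom > 0, pair_sums / denom, np.nan)
    C[:, :] = off
    for i in range(n_cls):
        s = sizes[i]
        if s >= 2:
            C[i, i] = (pair_sums[i, i] - s) / (s * s - s)
        else:
            C[i, i] = np.nan
    C = np.clip(C, 0.0, 1.0)  # guard fp noise at the boundaries
    return ClassNetwork(classes=labels, sizes=sizes, C=C)


def average_class_networks(nets: Sequence[ClassNetwork]) -> ClassNetwork:
    """Entry-wise mean over per-fungus class networks.

    Entries undefined in a fungus (class absent there) are omitted from the
    mean; entries undefined everywhere stay undefined.  Node size of the
    averaged network is the total class membership across fungi.
    """
    if not nets:
        raise ValueError("no networks to average")
    labels: dict[str, None] = {}
    for net in nets:
        for c in net.classes:
            labels.setdefault(c, None)
    classes = list(labels)
    n = len(classes)
    stack = np.full((len(nets), n, n), np.nan)
    sizes = np.zeros(n)
    for k, net in enumerate(nets):
        pos = [classes.index(c) for c in net.classes]
        stack[np.ix_([k], pos, pos)] = net.C
        sizes[pos] += net.sizes
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries stay NaN
        mean = np.nanmean(stack, axis=0)
    return ClassNetwork(classes=classes, sizes=sizes, C=mean)


def node_strength(net: ClassNetwork) -> dict[str, float]:
    """Strength: sum of a node's defined incident weights, self-loop once."""
    out = {}
    for i, label in enumerate(net.classes):
        row = net.C[i]
        out[label] = float(np.nansum(row)) if np.any(~np.isnan(row)) else 0.0
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def discretize_weights(net: ClassNetwork, scale: int = 100) -> ClassNetwork:
    """Map continuous weights in [0,1] onto integers 0..scale (half-up).

    Off-diagonal entries only; a weight rounding to 0 means "no edge".
    Intra-class coefficients are kept as node annotations and not
    discretized.
    """
    defined = ~np.isnan(net.C)
    if defined.any() and (net.C[defined].min() < 0 or net.C[defined].max() > 1):
        raise ValueError("weights must lie in [0, 1] before discretization")
    n = len(net.classes)
    w = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(net.C[i, j]):
                w[i, j] = w[j, i] = _round_half_up(scale * net.C[i, j])
    return ClassNetwork(
        classes=list(net.classes), sizes=net.sizes.copy(), C=net.C.copy(), int_weights=w
    )


@dataclass
class EdgeSignificance:
    """Marginal-likelihood-filter bookkeeping for one edge."""

    i: str
    j: str
    w: int
    k_i: int
    k_j: int
    T: int
    p_ij: float
    pvalue: float


def edge_pvalue(w: int, k_i: int, k_j: int, T: int) -> float:
    """Upper-tail p-value of one edge under the strength-preserving null:
    P(Binomial(T, k_i*k_j / (2 T^2)) >= w)."""
    if T <= 0:
        raise ValueError("T must be positive")
    p_ij = min(float(k_i) * float(k_j) / (2.0 * T * T), 1.0)
    return float(stats.binom.sf(w - 1, T, p_ij))


def mlf_edge_pvalues(net: ClassNetwork) -> list[EdgeSignificance]:
    """Upper-tail binomial p-values for every integer-weighted edge.

    Null model: the T unit edges of the discretized graph attach
    independently to pair (i, j) with probability p_ij = k_i k_j / (2 T^2),
    where k are integer node strengths; the observed weight w is compared
    with Binomial(T, p_ij).  Self-loops are excluded from the null.  Also
    fills ``net.pvalues`` (NaN where no edge).
    """
    if net.int_weights is None:
        raise ValueError("discretize the network before computing edge p-values")
    w = net.int_weights
    n = len(net.classes)
    k = w.sum(axis=1)  # integer strengths over off-diagonal edges
    T = int(w.sum() // 2)
    pvals = np.full((n, n), np.nan)
    edges: list[EdgeSignificance] = []
    if T == 0:
        net.pvalues = pvals
        return edges
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0:
                continue
            p_ij = min(float(k[i]) * float(k[j]) / (2.0 * T * T), 1.0)
            pvalue = edge_pvalue(int(w[i, j]), int(k[i]), int(k[j]), T)
            pvals[i, j] = pvals[j, i] = pvalue
            edges.append(
                EdgeSignificance(
                    i=net.classes[i], j=net.classes[j], w=int(w[i, j]),
                    k_i=int(k[i]), k_j=int(k[j]), T=T, p_ij=p_ij, pvalue=pvalue,
                )
            )
    net.pvalues = pvals
    return edges


def filter_network(net: ClassNetwork, alpha: float = 0.05) -> ClassNetwork:
    """Keep edges with p < alpha; nodes stay even if isolated.

    Strengths are a property of the pre-filter network and are not
    recomputed here; intra-class self-loops are exempt from filtering.
    """
    if net.pvalues is None:
        raise ValueError("compute edge p-values before filtering")
    n = len(net.classes)
    C = net.C.copy()
    w = net.int_weights.copy() if net.int_weights is not None else None
    pv = net.pvalues.copy()
    for i in range(n):
        for j in range(i + 1, n):
            significant = (not np.isnan(pv[i, j])) and pv[i, j] < alpha
            if not significant:
                C[i, j] = C[j, i] = np.nan
                if w is not None:
                    w[i, j] = w[j, i] = 0
    return ClassNetwork(
        classes=list(net.classes), sizes=net.sizes.copy(), C=C,
        int_weights=w, pvalues=pv,
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _to_graph(net: ClassNetwork, strengths: Mapping[str, float] | None) -> nx.Graph:
    g = nx.Graph()
    strengths = strengths or node_strength(net)
    for i, label in enumerate(net.classes):
        attrs = {"size": int(net.sizes[i]), "strength": float(strengths.get(label, 0.0))}
        if not np.isnan(net.C[i, i]):
            attrs["intra_C"] = float(net.C[i, i])
        g.add_node(label, **attrs)
    n = len(net.classes)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(net.C[i, j]):
                continue
            if net.int_weights is not None and net.int_weights[i, j] == 0:
                continue
            attrs = {"C": float(net.C[i, j])}
            if net.int_weights is not None:
                attrs["w_int"] = int(net.int_weights[i, j])
            if net.pvalues is not None and not np.isnan(net.pvalues[i, j]):
                attrs["pvalue"] = float(net.pvalues[i, j])
            g.add_edge(net.classes[i], net.classes[j], **attrs)
    return g


def export_network(
    net: ClassNetwork,
    path_base: str | Path,
    formats: Sequence[str] = ("graphml", "sif"),
    strengths: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write the class network for downstream visualization.

    ``graphml`` gives a single file with node attributes (size, strength,
    intra-class C) and edge attributes (C, integer weight, p-value);
    ``sif`` gives a Cytoscape-style ``.sif`` plus an edge-attribute TSV and
    a node-attribute TSV.
    """
    path_base = Path(path_base)
    path_base.parent.mkdir(parents=True, exist_ok=True)
    g = _to_graph(net, strengths)
    out: dict[str, Path] = {}
    if "graphml" in formats:
        p = path_base.with_suffix(".graphml")
        nx.write_graphml(g, p)
        out["graphml"] = p
    if "sif" in formats:
        sif = path_base.with_suffix(".sif")
        with open(sif, "w") as fh:
            isolated = [v for v in g.nodes if g.degree(v) == 0]
            for a, b in sorted(g.edges):
                fh.write(f"{a}\tco\t{b}\n")
            for v in sorted(isolated):
                fh.write(f"{v}\n")
        out["sif"] = sif
        edge_rows = [
            {"source": a, "target": b, **g.edges[a, b]} for a, b in sorted(g.edges)
        ]
        ep = path_base.parent / (path_base.name + "_edges.tsv")
        pd.DataFrame(edge_rows, columns=["source", "target", "C", "w_int", "pvalue"]).to_csv(
            ep, sep="\t", index=False
        )
        out["edges"] = ep
        node_rows = [{"class": v, **g.nodes[v]} for v in sorted(g.nodes)]
        np_path = path_base.parent / (path_base.name + "_nodes.tsv")
        pd.DataFrame(node_rows).to_csv(np_path, sep="\t", index=False)
        out["nodes"] = np_path
    return out


def import_graphml(path: str | Path) -> ClassNetwork:
    """Read back a GraphML export into a :class:`ClassNetwork`."""
    g = nx.read_graphml(path)
    classes = sorted(g.nodes)
    n = len(classes)
    sizes = np.array([float(g.nodes[c].get("size", 0)) for c in classes])
    C = np.full((n, n), np.nan)
    w = np.zeros((n, n), dtype=int)
    pv = np.full((n, n), np.nan)
    has_w = has_p = False
    for i, c in enumerate(classes):
        if "intra_C" in g.nodes[c]:
            C[i, i] = float(g.nodes[c]["intra_C"])
    for a, b, attrs in g.edges(data=True):
        i, j = classes.index(a), classes.index(b)
        C[i, j] = C[j, i] = float(attrs["C"])
        if "w_int" in attrs:
            w[i, j] = w[j, i] = int(attrs["w_int"])
            has_w = True
        if "pvalue" in attrs:
            pv[i, j] = pv[j, i] = float(attrs["pvalue"])
            has_p = True
    return ClassNetwork(
        classes=classes, sizes=sizes, C=C,
        int_weights=w if has_w else None, pvalues=pv if has_p else None,
    )
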