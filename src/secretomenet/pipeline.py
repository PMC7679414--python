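"""End-to-end pipeline runner.

Executes, from a single YAML config (or an equivalent dict):

    detection filter -> log2 + biweight normalization -> replicate QC ->
    replicate averaging -> hierarchical ordering -> per-fungus protein
    adjacency -> class collapse -> cross-fungus average -> strength ->
    discretization -> marginal likelihood filter -> exports and report
    tables

and writes every artifact plus a manifest into a run directory.  The same
config and seed give byte-identical manifests and artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .cluster import heatmap_matrix, hierarchical_order, write_heatmap_tsv
from .io import EnzymeClassMap, class_members
from .network import (
    average_class_networks,
    collapse_classes,
    discretize_weights,
    export_network,
    filter_network,
    impute_missing,
    mlf_edge_pvalues,
    node_strength,
    protein_adjacency,
)
from .preprocess import (
    NormalizationParams,
    apply_filter,
    average_replicates,
    detection_filter,
    normalize,
    replicate_correlation,
)
from .report import class_substrate_table, summarize_secretome
from .simulate import SyntheticConfig, generate_study, read_study, write_fixtures

__all__ = ["run_pipeline", "load_config", "build_class_network"]


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _study_from_config(cfg: dict[str, Any], run_dir: Path):
    study = cfg.get("study")
    if not isinstance(study, dict):
        raise ValueError("config is missing the 'study' section")
    if "synthetic" in study:
        overrides = dict(study["synthetic"] or {})
        if "class_catalog" in overrides:
            overrides["class_catalog"] = [tuple(x) for x in overrides["class_catalog"]]
        if "induction_effects" in overrides:
            overrides["induction_effects"] = {
                (c, s): float(e) for c, s, e in overrides["induction_effects"]
            }
        config = SyntheticConfig(**overrides)
        class_map = EnzymeClassMap.default()
        table, annotations, truth = generate_study(config, class_map)
        write_fixtures((table, annotations, truth), run_dir / "inputs", class_map)
        return table, annotations, class_map, truth, {"seed": config.seed}
    if "directory" in study:
        table, annotations, class_map, truth = read_study(study["directory"])
        return table, annotations, class_map, truth, {"directory": str(study["directory"])}
    raise ValueError(
        "config key 'study' must provide either 'synthetic' (with a seed) "
        "or 'directory' (a fixture directory with abundance.tsv)"
    )


def build_class_network(
    normalized,
    annotations,
    class_map: EnzymeClassMap,
    decision,
    beta: float = 1.0,
    alpha: float = 0.05,
):
    """Per-fungus adjacency -> collapse -> average -> discretize -> MLF.

    Returns (averaged network, discretized network with p-values, filtered
    network, strengths).  Adjacency is computed on replicate-level
    normalized samples after -10 imputation, per fungus, over the proteins
    kept in that fungus.
    """
    per_fungus = []
    for fungus in normalized.fungi:
        kept = sorted(decision.keep_by_fungus.get(fungus, set()))
        if len(kept) < 2:
            continue
        sub = normalized.for_fungus(fungus).values.loc[kept]
        adjacency = protein_adjacency(impute_missing(sub), beta=beta)
        kept_anns = {p: a for p, a in annotations.items() if p in set(kept)}
        class_sets = class_members(kept_anns, class_map)
        per_fungus.append(collapse_classes(adjacency, class_sets))
    averaged = average_class_networks(per_fungus)
    strengths = node_strength(averaged)
    discretized = discretize_weights(averaged)
    mlf_edge_pvalues(discretized)
    filtered = filter_network(discretized, alpha=alpha)
    return averaged, discretized, filtered, strengths


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> Path:
    """Run every stage and write artifacts plus ``manifest.json``."""
    cfg = load_config(config)
    run_dir = Path(out_dir or cfg.get("output", "run"))
    run_dir.mkdir(parents=True, exist_ok=True)

    table, annotations, class_map, truth, study_meta = _study_from_config(cfg, run_dir)

    filter_cfg = cfg.get("filter", {}) or {}
    norm_cfg = cfg.get("normalization", {}) or {}
    net_cfg = cfg.get("network", {}) or {}
    params = NormalizationParams(
        c=float(norm_cfg.get("c", 5.0)),
        one_step=bool(norm_cfg.get("one_step", False)),
        epsilon=float(norm_cfg.get("epsilon", 1e-6)),
    )
    min_replicates = int(filter_cfg.get("min_replicates", 2))
    beta = float(net_cfg.get("beta", 1.0))
    alpha = float(net_cfg.get("alpha", 0.05))

    artifacts: list[str] = []

    def _save(name: str, path: Path) -> None:
        artifacts.append(str(path.relative_to(run_dir)))

    # filter -> normalize -> QC -> averages
    decision = detection_filter(table, min_replicates=min_replicates)
    filtered_table = apply_filter(table, decision)
    normalized = normalize(filtered_table, params)
    qc = replicate_correlation(normalized)
    qc_path = run_dir / "qc_replicate_correlation.tsv"
    qc.to_csv(qc_path, sep="\t", index=False, na_rep="NA")
    _save("qc", qc_path)
    averaged = average_replicates(normalized)
    avg_path = run_dir / "averaged_abundance.tsv"
    averaged.to_tsv(avg_path)
    _save("averaged", avg_path)

    # clustering / heat maps, per fungus
    for fungus in averaged.fungi:
        kept = sorted(decision.keep_by_fungus.get(fungus, set()))
        if len(kept) < 2:
            continue
        matrix = averaged.for_fungus(fungus).values.loc[kept]
        dend = hierarchical_order(matrix)
        ordered, _meta = heatmap_matrix(matrix, dend)
        hp = write_heatmap_tsv(ordered, run_dir / f"heatmap_{fungus}.tsv")
        _save(f"heatmap_{fungus}", hp)

    # co-expression networks
    averaged_net, discretized, filtered_net, strengths = build_class_network(
        normalized, annotations, class_map, decision, beta=beta, alpha=alpha
    )
    net_dir = run_dir / "network"
    for name, net in (("class_network", discretized), ("class_network_filtered", filtered_net)):
        for key, p in export_network(net, net_dir / name, strengths=strengths).items():
            _save(f"{name}_{key}", p)

    # report tables
    summary = summarize_secretome(
        {
            f: [annotations[p] for p in sorted(decision.keep_by_fungus.get(f, set()))]
            for f in table.fungi
        }
    )
    t1 = run_dir / "report_secretome_summary.tsv"
    summary.per_fungus.to_csv(t1, sep="\t", na_rep="NA")
    _save("summary", t1)
    for fungus in table.fungi:
        df = class_substrate_table(
            annotations, decision, class_map, fungus, table.substrates
        )
        p = run_dir / f"report_class_substrate_{fungus}.tsv"
        df.to_csv(p, sep="\t")
        _save(f"class_substrate_{fungus}", p)

    manifest = {
        "package": "secretomenet",
        "version": __version__,
        "study": study_meta,
        "parameters": {
            "filter.min_replicates": min_replicates,
            "normalization.c": params.c,
            "normalization.one_step": params.one_step,
            "normalization.epsilon": params.epsilon,
            "network.beta": beta,
            "network.alpha": alpha,
        },
        "n_proteins_input": len(table.protein_ids),
        "n_proteins_kept": int(sum(summary.per_fungus["n_identified"])),
        "mean_cazyme_pct": summary.mean_cazyme_pct,
        "artifacts": sorted(artifacts),
    }
    manifest_path = run_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return run_dir
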