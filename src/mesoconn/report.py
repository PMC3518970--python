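"""One-call analysis report tying the whole pipeline together.

``run_report`` executes condense → global → local → motifs → matrices →
vulnerability → PCA on a records/hierarchy input and writes diff-able
TSV and GraphML artifacts to an output directory, together with the full
configuration and seeds, so every artifact is reproducible byte-for-byte
from (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .connectome import (
    build_connectome,
    condense,
    connectome_to_graphml,
    read_records_csv,
)
from .global_metrics import global_summary
from .local_metrics import local_table
from .matrices import (
    communicability_matrix,
    distance_matrix,
    matching_matrix,
    write_pair_matrix_tsv,
)
from .motifs import motif_significance, motif_table
from .ontology import leaves_at_view, load_hierarchy
from .pca_profile import feature_table, parzen_density, pca, pca_table
from .vulnerability import edge_vulnerability_matrix, node_significance

__all__ = ["RunConfig", "run_report"]


@dataclass
class RunConfig:
    records_path: str
    hierarchy_path: str
    out_dir: str
    collapsed: list[str] = field(default_factory=list)
    side: str = "unilateral"
    seed: int = 0
    replicates: int = 200
    swap_multiplier: int = 10
    motif_sizes: tuple[int, ...] = (3, 4)
    shapley_perms: int = 10_000


def run_report(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Any missing input aborts with a configuration error before any
    artifact is written; a failing stage aborts with a stage-tagged
    message.
    """
    records_path = Path(cfg.records_path)
    hierarchy_path = Path(cfg.hierarchy_path)
    for p in (records_path, hierarchy_path):
        if not p.exists():
            raise FileNotFoundError(f"configuration error: input {p} not found")
    out = Path(cfg.out_dir)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    h = _stage("load", load_hierarchy, str(hierarchy_path))
    records = _stage("load", read_records_csv, records_path)
    leaf_order = _stage("view", leaves_at_view, h, cfg.collapsed)
    built = _stage("build", build_connectome, records, leaf_order,
                   side=cfg.side, hierarchy=h)
    cond = _stage("condense", condense, built)

    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, default=list) + "\n")
    connectome_to_graphml(cond, out / "condensed.graphml")

    gm = _stage("global", global_summary, cond, n_rand=cfg.replicates, seed=cfg.seed)
    pd.DataFrame([dataclasses.asdict(gm)]).to_csv(
        out / "global.tsv", sep="\t", index=False)

    lt = _stage("local", local_table, cond,
                shapley_perms=cfg.shapley_perms, seed=cfg.seed)
    lt.to_csv(out / "local.tsv", sep="\t")

    for k in cfg.motif_sizes:
        stats = _stage(f"motifs k={k}", motif_significance, cond, k,
                       n_rand=cfg.replicates,
                       swap_multiplier=cfg.swap_multiplier, seed=cfg.seed)
        motif_table(stats, k).to_csv(out / f"motifs{k}.tsv", sep="\t", index=False)

    for pm in (distance_matrix(cond), communicability_matrix(cond),
               matching_matrix(cond, "in"), matching_matrix(cond, "out"),
               matching_matrix(cond, "all")):
        write_pair_matrix_tsv(pm, out / f"{pm.kind}.tsv")

    if cond.n_nodes >= 3:
        sig = _stage("vulnerability", node_significance, cond)
        pd.Series(sig, name="significance_percent").sort_values(
            ascending=False).rename_axis("region").to_csv(
            out / "vulnerability_nodes.tsv", sep="\t")
        write_pair_matrix_tsv(edge_vulnerability_matrix(cond),
                              out / "vulnerability_edges.tsv")

        ft = _stage("pca", feature_table, cond)
        ft.to_csv(out / "features.tsv", sep="\t")
        res = _stage("pca", pca, ft)
        pca_table(res).to_csv(out / "pca_loadings.tsv", sep="\t")
        pd.DataFrame(res.scores, index=res.nodes,
                     columns=["C1", "C2"]).to_csv(out / "pca_scores.tsv", sep="\t")
        xs, ys, dens = parzen_density(res.scores)
        pd.DataFrame(dens, index=ys, columns=xs).to_csv(
            out / "pca_density.tsv", sep="\t")
    return out
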