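"""End-to-end orchestration: filters -> consensus -> soft clustering ->
embedding -> trajectories -> genes, with seeded stages and on-disk outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusConfig, build_consensus, estimate_k
from .embed import pre_embedding
from .genes import fit_gene_cluster, marker_genes, transition_genes
from .preprocess import (
    ExpressionMatrix,
    filter_cells,
    filter_genes,
    load_expression,
    select_informative_genes,
)
from .softcluster import symnmf
from .trajectory import build_transition_graph, infer_trajectories, pseudotime

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_quantc"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_path: str | None = None
    input_format: str = "csv"
    orientation: str = "genes_by_cells"
    min_gene_fraction: float = 0.05
    min_cell_fraction: float = 0.10
    min_variance: float = 0.005
    n_top_genes: int = 3000
    log_transform: bool = False
    k: int | str = "auto"  # "auto" = eigengap estimate
    k_max: int = 10
    lambda1: float = 0.3
    lambda2: float = 10.0
    tc_threshold: float | str = "auto"
    rho_threshold: float = 0.64
    min_gap: float = 0.03
    initial_cluster: int | str = "auto"
    n_restarts: int = 10
    seed: int = 0
    out_dir: str = "tcquant_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Hierarchical per-stage seeds so stages can be re-run in isolation."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_quantc(
    cfg: RunConfig, X: ExpressionMatrix | None = None
) -> dict[str, Any]:
    """Run the full pipeline and write every stage output under
    ``cfg.out_dir``.  Returns the in-memory result bundle.

    ``X`` may be supplied directly (e.g. from the simulator); otherwise it is
    loaded from ``cfg.input_path``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": seeds,
        "stages_completed": [],
    }
    results: dict[str, Any] = {"manifest": manifest}

    def done(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        # -- 1. preprocess ------------------------------------------------
        stage = "preprocess"
        if X is None:
            if cfg.input_path is None:
                raise ValueError("no input matrix given")
            X = load_expression(cfg.input_path, cfg.input_format, cfg.orientation)
        X = filter_cells(X, cfg.min_gene_fraction)
        X = filter_genes(X, cfg.min_cell_fraction, cfg.min_variance)
        report = select_informative_genes(
            X, n_top=cfg.n_top_genes, seed=seeds[0], log_transform=cfg.log_transform
        )
        sel = [X.gene_names.index(g) for g in report.selected_genes]
        Xs = X.subset(genes=np.array(sel))
        Xs.save(out / "filtered_expression.tsv")
        report.save(out / "feature_selection.tsv")
        results.update(X=Xs, feature_report=report)
        done(stage)

        # -- 2. consensus -------------------------------------------------
        stage = "consensus"
        M = build_consensus(Xs, ConsensusConfig(), seed=seeds[1])
        pd.DataFrame(M.values, index=M.cell_names, columns=M.cell_names).to_csv(
            out / "consensus.tsv", sep="\t"
        )
        if cfg.k == "auto":
            est = estimate_k(M, k_max=cfg.k_max)
            k = est.k
            np.savetxt(out / "laplacian_eigenvalues.tsv", est.laplacian_eigenvalues)
            results["k_estimate"] = est
        else:
            k = int(cfg.k)
        results.update(consensus=M, k=k)
        done(stage)

        # -- 3. soft clustering -------------------------------------------
        stage = "softcluster"
        sc = symnmf(M, k=k, seed=seeds[2], n_restarts=cfg.n_restarts)
        sc.finalize(tc_threshold=cfg.tc_threshold)
        results["soft"] = sc
        done(stage)

        # -- 4. embedding --------------------------------------------------
        stage = "embed"
        emb = pre_embedding(sc.H, sc.P, lambda1=cfg.lambda1)
        np.savetxt(out / "cluster_centers.tsv", emb.centers, delimiter="\t")
        results["embedding"] = emb
        done(stage)

        # -- 5. trajectories ----------------------------------------------
        stage = "trajectory"
        graph = build_transition_graph(sc.P, sc.tc_mask)
        initial = _pick_initial(cfg.initial_cluster, graph, sc)
        trajs = infer_trajectories(graph, initial, sc.P, sc.tc_mask, cpi=sc.cpi)
        pt = pseudotime(emb.coords, trajs)
        edges = [
            {"a": int(a), "b": int(b), "tc_count": int(graph.tc_counts[a, b])}
            for a, b in graph.neighbors.edges
        ]
        pd.DataFrame(edges).to_csv(out / "transition_edges.tsv", sep="\t", index=False)
        (out / "trajectories.json").write_text(
            json.dumps(
                [
                    {
                        "cluster_path": t.cluster_path,
                        "probability": t.probability,
                        "n_cells": len(t.cell_order),
                        "cells": [sc.cell_names[i] for i in t.cell_order],
                    }
                    for t in trajs
                ],
                indent=2,
            )
        )
        cell_table = pd.DataFrame(
            {
                "cluster": sc.hard_labels,
                "cpi": sc.cpi,
                "is_tc": sc.tc_mask,
                "pseudotime": pt,
                "x": emb.coords[:, 0],
                "y": emb.coords[:, 1],
            },
            index=sc.cell_names,
        )
        cell_table.to_csv(out / "cells.tsv", sep="\t")
        results.update(graph=graph, trajectories=trajs, pseudotime_values=pt,
                       cell_table=cell_table, initial_cluster=initial)
        done(stage)

        # -- 6. genes ------------------------------------------------------
        stage = "genes"
        all_markers: dict[int, list] = {}
        tg_rows = []
        top = trajs[0] if trajs else None
        if top is not None and len(top.cell_order) >= 3:
            D = Xs.values
            fit = fit_gene_cluster(
                D[:, top.cell_order],
                sc.H[top.cell_order],
                lambda2=cfg.lambda2,
                seed=seeds[3],
                gene_names=Xs.gene_names,
            )
            all_markers = marker_genes(fit, min_gap=cfg.min_gap)
            results["gene_fit"] = fit
            for a, b in zip(top.cluster_path[:-1], top.cluster_path[1:]):
                cand = [g for g, _ in all_markers.get(a, []) + all_markers.get(b, [])]
                seg_cells = [
                    c for c in top.cell_order
                    if sc.hard_labels[c] in (a, b)
                ]
                if len(seg_cells) < 3 or not cand:
                    continue
                for gene, rho, direction in transition_genes(
                    D, seg_cells, cand, gene_names=Xs.gene_names,
                    rho_threshold=cfg.rho_threshold,
                ):
                    tg_rows.append(
                        {"pair": f"{a}-{b}", "gene": gene, "rho": rho,
                         "direction": direction}
                    )
        marker_rows = [
            {"cluster": j, "gene": g, "score": s}
            for j, lst in all_markers.items()
            for g, s in lst
        ]
        pd.DataFrame(marker_rows).to_csv(out / "markers.tsv", sep="\t", index=False)
        pd.DataFrame(tg_rows).to_csv(out / "transition_genes.tsv", sep="\t", index=False)
        results.update(markers=all_markers, transition_gene_table=pd.DataFrame(tg_rows))
        done(stage)
    except Exception:
        logger.exception("pipeline aborted during stage %r", stage)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    return results


def _pick_initial(choice, graph, sc) -> int:
    """Initial cluster: user override, else the non-ICS cluster with the
    fewest transition cells around it (low transition activity marks the
    start or end of the trajectory)."""
    if choice != "auto":
        return int(choice)
    k = sc.k
    tc_around = graph.tc_counts.sum(axis=1)
    candidates = [c for c in range(k) if c not in graph.ics_candidates]
    if not candidates:
        candidates = list(range(k))
    return int(min(candidates, key=lambda c: (tc_around[c], c)))
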