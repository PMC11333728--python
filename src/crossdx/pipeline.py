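"""End-to-end orchestration of the cross-disease discovery pipeline.

Stage order mirrors the analysis narrative: per-cohort differential
expression → within-disease common DEGs → cross-disease shared DEGs and
fold-change association → PPI hub selection (when a network is given) →
gene-set enrichment (when a GMT is given) → docking-score drug ranking
(when a BAS matrix is given).  Every stage writes its own TSV/JSON output;
a single JSON report indexes the per-stage summaries, and a MANIFEST file
records which stages completed so partial runs remain auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from crossdx import io
from crossdx.crossdisease import (
    aggregate_disease_fold_changes,
    association_permutation_p,
    intersect_common_degs,
    intersect_shared_degs,
)
from crossdx.diffexpr import run_diffexpr
from crossdx.drugrank import rank_bas_matrix, select_candidate_drugs
from crossdx.enrich import enrich_collection, enrichment_frame
from crossdx.netrank import centrality_table, select_hubs
from crossdx.synthdata import SimulationConfig, generate_two_disease_studies

logger = logging.getLogger(__name__)

STAGES = ("simulate", "deg", "shared", "hubs", "enrich", "drugrank")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (paths or a simulation), thresholds, seed."""

    outdir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    expr_disease1: list[tuple[str, str]] = field(default_factory=list)  # (expr, samples)
    expr_disease2: list[tuple[str, str]] = field(default_factory=list)
    p_cut: float = 0.05
    fc_cut: float = 1.0
    adjust: str = "bh"
    intersect_mode: str = "strict"
    n_perm: int = 999
    network_path: str | None = None
    hub_k: int = 10
    hub_method: str = "mean_rank"
    gmt_path: str | None = None
    enrich_p_cut: float = 0.05
    bas_path: str | None = None
    avg_cut: float = -7.7
    per_receptor_cut: float = -7.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(outdir=Path(raw.pop("outdir", "crossdx_out")), **{
            k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}
        })
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all configured stages; returns (and writes) the report dict.

    Deterministic given the config seed.  A stage failure raises
    :class:`StageError` after the MANIFEST marks the incomplete stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {s: "pending" for s in STAGES}
    report: dict[str, Any] = {
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(config).items()},
    }

    def _finish(stage: str) -> None:
        manifest[stage] = "done"
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def _fail(stage: str, exc: Exception) -> StageError:
        manifest[stage] = "failed"
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return StageError(stage, exc)

    # -- simulate / load -----------------------------------------------
    network = None
    collection = None
    bas = None
    truth = None
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            studies1, studies2, truth = generate_two_disease_studies(sim)
            truth.frame().to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
            for i, st in enumerate(studies1 + studies2):
                io.write_expression_study(
                    st, outdir / f"expr_{st.study_id}.tsv",
                    outdir / f"samples_{st.study_id}.tsv")
        else:
            studies1 = [io.read_expression_study(e, s) for e, s in config.expr_disease1]
            studies2 = [io.read_expression_study(e, s) for e, s in config.expr_disease2]
        if config.network_path:
            network = io.read_network(config.network_path)
        if config.gmt_path:
            collection = io.read_gmt(config.gmt_path)
        if config.bas_path:
            bas = io.read_bas_matrix(config.bas_path)
        _finish("simulate")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise _fail("simulate", exc)

    # -- differential expression ---------------------------------------
    try:
        deg_by_disease = []
        deg_counts = {}
        for studies in (studies1, studies2):
            tables = []
            for st in studies:
                deg, _ = run_diffexpr(st, p_cut=config.p_cut, fc_cut=config.fc_cut,
                                      adjust=config.adjust)  # type: ignore[arg-type]
                io.write_deg_table(deg, outdir / f"deg_{st.study_id}.tsv")
                deg_counts[st.study_id] = {"up": deg.up_count, "down": deg.down_count}
                tables.append(deg)
            deg_by_disease.append(tables)
        report["deg_counts"] = deg_counts
        _finish("deg")
    except Exception as exc:
        raise _fail("deg", exc)

    # -- cross-disease intersection + association ----------------------
    try:
        cdegs = [intersect_common_degs(tabs, mode=config.intersect_mode)  # type: ignore[arg-type]
                 for tabs in deg_by_disease]
        report["cdeg_counts"] = [
            {"up": sum(1 for d in c.values() if d == "up"),
             "down": sum(1 for d in c.values() if d == "down")}
            for c in cdegs
        ]
        shared_candidates = sorted(set(cdegs[0]) & set(cdegs[1]))
        profiles = [
            aggregate_disease_fold_changes(tabs, shared_candidates, disease_id=f"disease{i+1}")
            for i, tabs in enumerate(deg_by_disease)
        ]
        shared = intersect_shared_degs(cdegs[0], cdegs[1],
                                       profile_1=profiles[0], profile_2=profiles[1])
        rows = [{"gene": g, "dir_disease1": shared.direction_1[g],
                 "dir_disease2": shared.direction_2[g],
                 "alog2fc_disease1": shared.alog2fc_1.get(g),
                 "alog2fc_disease2": shared.alog2fc_2.get(g)}
                for g in shared.genes]
        import pandas as pd
        pd.DataFrame(rows, columns=["gene", "dir_disease1", "dir_disease2",
                                    "alog2fc_disease1", "alog2fc_disease2"]).to_csv(
            outdir / "shared_degs.tsv", sep="\t", index=False)
        report["sdeg_counts"] = {"total": len(shared.genes),
                                 "up": shared.n_up, "down": shared.n_down}
        if len(shared.genes) >= 3:
            assoc = association_permutation_p(profiles[0], profiles[1], shared.genes,
                                              n_perm=config.n_perm, seed=config.seed)
            report["association"] = {"r": assoc.r, "n_genes": assoc.n_genes,
                                     "p_perm": assoc.p_perm, "n_perm": assoc.n_perm,
                                     "seed": assoc.seed}
            (outdir / "association.json").write_text(
                json.dumps(report["association"], indent=2))
        else:
            report["association"] = None
            logger.warning("fewer than 3 shared genes: association skipped")
        _finish("shared")
    except Exception as exc:
        raise _fail("shared", exc)

    # -- hubs -----------------------------------------------------------
    try:
        if network is not None:
            table = centrality_table(network)
            table.table.to_csv(outdir / "centrality.tsv", sep="\t")
            hubs = select_hubs(network, k=config.hub_k, method=config.hub_method,  # type: ignore[arg-type]
                               table=table)
            with open(outdir / "hubs.tsv", "w") as fh:
                fh.write("gene\taggregate\n")
                for g in hubs.genes:
                    fh.write(f"{g}\t{hubs.aggregate[g]}\n")
            report["hubs"] = [str(g) for g in hubs.genes]
        else:
            report["hubs"] = None
        _finish("hubs")
    except Exception as exc:
        raise _fail("hubs", exc)

    # -- enrichment ------------------------------------------------------
    try:
        if collection is not None:
            query = report["hubs"] if report["hubs"] else \
                (shared.genes if shared.genes else [])
            query = [g for g in query if g in collection.universe]
            if query:
                results = enrich_collection(query, collection, p_cut=config.enrich_p_cut)
                enrichment_frame(results).to_csv(outdir / "enrichment.tsv",
                                                 sep="\t", index=False)
                report["enrichment"] = [
                    {"set": r.set_name, "p": r.p, "adj_p": r.adj_p, "k": r.k}
                    for r in results[:10]
                ]
            else:
                report["enrichment"] = None
        else:
            report["enrichment"] = None
        _finish("enrich")
    except Exception as exc:
        raise _fail("enrich", exc)

    # -- drug ranking ----------------------------------------------------
    try:
        if bas is not None:
            ranking = rank_bas_matrix(bas)
            ranking.ligand_means.rename("mean_bas").to_csv(
                outdir / "ligand_ranking.tsv", sep="\t")
            selection = select_candidate_drugs(ranking, avg_cut=config.avg_cut,
                                               per_receptor_cut=config.per_receptor_cut)
            selection.to_csv(outdir / "drug_selection.tsv", sep="\t", index=False)
            report["drug_ranking"] = list(ranking.ligand_means.index[:10])
            report["drug_selection"] = list(selection["ligand"])
        else:
            report["drug_ranking"] = None
            report["drug_selection"] = None
        _finish("drugrank")
    except Exception as exc:
        raise _fail("drugrank", exc)

    from crossdx import __version__
    report["version"] = __version__
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
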