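"""Readers/writers for the pipeline's plain-text interchange formats.

Expression matrices and sample sheets are TSV; networks are 2-column edge
lists (TSV) or SIF; gene sets are GMT; binding-affinity matrices are CSV
with receptor row labels and ligand column headers; molecule descriptor and
ADMET tables are TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from crossdx.diffexpr import DEGTable, ExpressionStudy
from crossdx.drugrank import ADMETProfile, BASMatrix, MoleculeDescriptors
from crossdx.enrich import GeneSetCollection
from crossdx.netrank import BipartiteRegulatorNetwork, build_graph


# -- expression ------------------------------------------------------------


def write_expression_study(study: ExpressionStudy, expr_path: str | Path,
                           samples_path: str | Path) -> None:
    frame = pd.DataFrame(study.matrix, index=pd.Index(study.gene_ids, name="gene_id"),
                         columns=[f"S{i:03d}" for i in range(len(study.groups))])
    frame.to_csv(expr_path, sep="\t")
    pd.DataFrame({"sample_id": frame.columns, "group": study.groups}).to_csv(
        samples_path, sep="\t", index=False)


def read_expression_study(expr_path: str | Path, samples_path: str | Path,
                          study_id: str | None = None,
                          pseudocount: float = 0.0) -> ExpressionStudy:
    """Load a genes × samples TSV plus its sample sheet.

    ``pseudocount`` is added to every intensity when explicitly given;
    non-positive values otherwise raise, rather than being silently patched.
    """
    frame = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"]))
    missing = [c for c in frame.columns if c not in groups]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing[:5]}")
    return ExpressionStudy(
        gene_ids=[str(g) for g in frame.index],
        matrix=frame.to_numpy(dtype=float) + pseudocount,
        groups=[groups[c] for c in frame.columns],
        study_id=study_id or Path(expr_path).stem,
    )


# -- DEG tables ------------------------------------------------------------


def write_deg_table(deg: DEGTable, path: str | Path) -> None:
    deg.table.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path, study_id: str | None = None,
                   p_cut: float = 0.05, fc_cut: float = 1.0) -> DEGTable:
    tab = pd.read_csv(path, sep="\t")
    required = {"gene_id", "alog2fc", "adj_p", "direction"}
    if not required <= set(tab.columns):
        raise ValueError(f"DEG table {path} missing columns {required - set(tab.columns)}")
    tab["gene_id"] = tab["gene_id"].astype(str)
    return DEGTable(study_id=study_id or Path(path).stem, table=tab,
                    p_cut=p_cut, fc_cut=fc_cut)


# -- networks --------------------------------------------------------------


def read_network(path: str | Path) -> nx.Graph:
    """Edge list from 2-column TSV, or SIF (node1 <relation> node2 ...)."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if path.suffix.lower() == ".sif":
                if len(parts) == 1:
                    nodes.append(parts[0])
                else:
                    edges.extend((parts[0], t) for t in parts[2:])
            else:
                if parts[0].lower() in ("source", "node1", "protein1"):
                    continue  # header
                edges.append((parts[0], parts[1]))
    return build_graph(edges, nodes)


def write_network(graph: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".sif":
            for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
                fh.write(f"{u}\tpp\t{v}\n")
            for v in sorted(nx.isolates(graph), key=str):
                fh.write(f"{v}\n")
        else:
            for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
                fh.write(f"{u}\t{v}\n")


def read_regulator_network(path: str | Path) -> BipartiteRegulatorNetwork:
    """3-column TSV: regulator, kind (TF|miRNA), target gene."""
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["regulator", "kind", "gene"], comment="#")
    if str(tab.iloc[0, 0]).lower() == "regulator":
        tab = tab.iloc[1:]
    return BipartiteRegulatorNetwork(
        edges=[(str(r), str(k), str(g)) for r, k, g in tab.itertuples(index=False)]
    )


def write_regulator_network(network: BipartiteRegulatorNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg, kind, gene in network.edges:
            fh.write(f"{reg}\t{kind}\t{gene}\n")


# -- gene sets -------------------------------------------------------------


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = {g for g in genes if g}
    return GeneSetCollection(sets=sets,
                             universe=set(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# -- binding-affinity matrices ---------------------------------------------


def read_bas_matrix(path: str | Path) -> BASMatrix:
    """CSV with receptor row labels and ligand column headers; empty = missing."""
    frame = pd.read_csv(path, index_col=0)
    return BASMatrix(scores=frame.astype(float))


def write_bas_matrix(matrix: BASMatrix, path: str | Path) -> None:
    matrix.scores.to_csv(path)


# -- molecule tables -------------------------------------------------------

_DESCRIPTOR_COLS = {
    "name": "name",
    "molecular_weight": "molecular_weight",
    "logp": "logp",
    "hbond_acceptors": "hbond_acceptors",
    "hbond_donors": "hbond_donors",
    "polar_surface_area": "polar_surface_area",
    "rotatable_bonds": "rotatable_bonds",
}


def read_descriptors(path: str | Path) -> list[MoleculeDescriptors]:
    tab = pd.read_csv(path, sep="\t")
    out = []
    for row in tab.to_dict("records"):
        out.append(MoleculeDescriptors(
            name=str(row["name"]),
            molecular_weight=float(row["molecular_weight"]),
            logp=float(row["logp"]),
            hbond_acceptors=int(row["hbond_acceptors"]),
            hbond_donors=int(row["hbond_donors"]),
            polar_surface_area=float(row["polar_surface_area"])
            if "polar_surface_area" in row and pd.notna(row["polar_surface_area"]) else None,
            rotatable_bonds=int(row["rotatable_bonds"])
            if "rotatable_bonds" in row and pd.notna(row["rotatable_bonds"]) else None,
        ))
    return out


def _parse_flag(value) -> bool | None:
    if pd.isna(value):
        return None
    return str(value).strip().lower() in ("yes", "true", "1")


def read_admet(path: str | Path) -> list[ADMETProfile]:
    tab = pd.read_csv(path, sep="\t")
    out = []
    for row in tab.to_dict("records"):
        out.append(ADMETProfile(
            name=str(row["name"]),
            hia=float(row["hia"]),
            logbb=float(row["logbb"]),
            caco2=float(row["caco2"]) if pd.notna(row.get("caco2")) else None,
            pgp_inhibitor=_parse_flag(row.get("pgp_inhibitor")),
            logps=float(row["logps"]) if pd.notna(row.get("logps")) else None,
            cyp3a4_inhibitor=_parse_flag(row.get("cyp3a4_inhibitor")),
            total_clearance=float(row["total_clearance"])
            if pd.notna(row.get("total_clearance")) else None,
            ames_positive=_parse_flag(row.get("ames")),
            lc50=float(row["lc50"]) if pd.notna(row.get("lc50")) else None,
            ld50=float(row["ld50"]) if pd.notna(row.get("ld50")) else None,
        ))
    return out
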