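#!/usr/bin/env python
"""Generate the synthetic two-disease study set and auxiliary fixtures.

Emulates the eight-cohort case/control design (four cohorts per disease,
6–27 samples per group) with 2000 genes: 90 shared-up, 30 shared-down,
40 disease-specific genes per disease at ±1.5 log2 with cross-disease
effect correlation 0.8, and a scaled-inverse-chi-square variance prior
(d0=4, s0²=0.05).  Also writes a planted-hub PPI network, a gene-set
collection with one planted enriched set, and a 15×148 binding-affinity
matrix with three planted strong binders.

Outputs under results/sim/.
"""

from pathlib import Path

from crossdx import io
from crossdx.synthdata import (
    SimulationConfig,
    SyntheticNetworkSpec,
    generate_bas_matrix,
    generate_gene_set_collection,
    generate_ppi_graph,
    generate_two_disease_studies,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    studies1, studies2, truth = generate_two_disease_studies(cfg)
    for st in studies1 + studies2:
        io.write_expression_study(st, OUT / f"expr_{st.study_id}.tsv",
                                  OUT / f"samples_{st.study_id}.tsv")
    truth.frame().to_csv(OUT / "truth_labels.tsv", sep="\t", index=False)
    print(f"wrote {len(studies1) + len(studies2)} cohorts "
          f"({cfg.n_genes} genes) with planted truth to {OUT}")

    graph = generate_ppi_graph(SyntheticNetworkSpec(
        n_background_nodes=100, n_planted_hubs=1, hub_degree=20,
        background_density=0.02, seed=SEED))
    io.write_network(graph, OUT / "ppi_network.tsv")
    print(f"PPI fixture: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges, 1 planted hub (HUB00)")

    shared_up = truth.genes_of_class("shared_up")[:10]
    collection = generate_gene_set_collection(
        n_sets=50, set_size_range=(20, 60), universe=truth.gene_ids,
        planted_set=shared_up, seed=SEED)
    io.write_gmt(collection, OUT / "gene_sets.gmt")
    print(f"gene-set fixture: {len(collection.sets)} sets, planted set of "
          f"{len(shared_up)} genes")

    matrix, strong = generate_bas_matrix(n_receptors=15, n_ligands=148,
                                         n_strong_ligands=3, seed=SEED)
    io.write_bas_matrix(matrix, OUT / "bas_matrix.csv")
    print(f"BAS fixture: 15x148 scores, planted strong binders: {strong}")


if __name__ == "__main__":
    main()
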