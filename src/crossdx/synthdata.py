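"""Synthetic inputs with the statistical structure the pipeline assumes.

The expression generator emulates a two-disease, multi-cohort microarray
design: several independent case/control cohorts per disease, strictly
positive intensities (generated on the log2 scale and exponentiated), a
hierarchical per-gene variance model ``sigma_g^2 ~ d0 * s0^2 / chi2_{d0}``
(the scaled inverse chi-square prior under which the moderated t-statistic
is calibrated), and planted gene classes: shared-up and shared-down genes
differentially expressed in both diseases with bivariate-normally correlated
effect sizes (correlation ``rho``, so the fold-change association statistic
has a known target), disease-specific genes perturbed in one disease only,
and null genes with zero effect everywhere.

Companion generators produce a PPI graph with planted hubs, a gene-set
collection with one planted enriched set, and a receptor × ligand
binding-affinity matrix with planted strong binders, so the network,
enrichment and drug-ranking stages all have known ground truth.

All generators are deterministic given their seed; per-dataset sub-streams
are derived from a single seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from crossdx.diffexpr import ExpressionStudy
from crossdx.drugrank import BASMatrix
from crossdx.enrich import GeneSetCollection


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation settings."""


#: case/control sizes of the eight cohorts the emulated study design uses
#: (four cohorts per disease; islet/muscle T2D arrays run 6–12 per group,
#: the renal tumor/normal pairs 12–27)
DEFAULT_SAMPLES_DISEASE1 = ((6, 7), (12, 12), (12, 12), (12, 12))
DEFAULT_SAMPLES_DISEASE2 = ((14, 14), (27, 27), (12, 12), (13, 13))


@dataclass
class SimulationConfig:
    """Settings for the two-disease expression simulation.

    Effects are in log2 units: a shared-up gene has true aLog2FC drawn
    around ``+effect_mean`` in both diseases (``-effect_mean`` for
    shared-down), with per-class bivariate-normal spread ``effect_sd`` and
    cross-disease correlation ``cross_disease_effect_correlation``.
    """

    seed: int = 0
    n_genes: int = 2000
    n_datasets_per_disease: int = 4
    samples_per_group: Sequence[tuple[int, int]] | None = None
    n_shared_up: int = 90
    n_shared_down: int = 30
    n_specific_per_disease: int = 40
    effect_mean: float = 1.5
    effect_sd: float = 0.25
    cross_disease_effect_correlation: float = 0.8
    variance_prior_df: float = 4.0  # d0
    variance_prior_scale: float = 0.05  # s0^2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    disease_ids: tuple[str, str] = ("disease1", "disease2")

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_datasets_per_disease, self.n_shared_up,
                  self.n_shared_down, self.n_specific_per_disease)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be non-negative")
        planted = self.n_shared_up + self.n_shared_down + 2 * self.n_specific_per_disease
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if not -1.0 <= self.cross_disease_effect_correlation <= 1.0:
            raise ConfigurationError("effect correlation must lie in [-1, 1]")
        if self.variance_prior_df <= 0 or self.variance_prior_scale <= 0:
            raise ConfigurationError("variance prior hyperparameters must be positive")
        if self.effect_sd < 0 or self.baseline_log2_sd < 0:
            raise ConfigurationError("spread parameters must be non-negative")

    def samples_for(self, disease_index: int) -> list[tuple[int, int]]:
        if self.samples_per_group is not None:
            sizes = [tuple(s) for s in self.samples_per_group]
        else:
            default = (DEFAULT_SAMPLES_DISEASE1, DEFAULT_SAMPLES_DISEASE2)[disease_index]
            sizes = [tuple(s) for s in default]
        if len(sizes) < self.n_datasets_per_disease:
            raise ConfigurationError(
                "samples_per_group shorter than n_datasets_per_disease"
            )
        sizes = sizes[: self.n_datasets_per_disease]
        if any(n1 < 2 or n2 < 2 for n1, n2 in sizes):
            raise ConfigurationError("each group needs >= 2 samples")
        return sizes


@dataclass
class TruthLabels:
    """Planted ground truth: per-gene class, per-disease effect, variance."""

    gene_ids: list[str]
    gene_class: dict[str, str]  # shared_up | shared_down | specific_<id> | null
    effect_1: dict[str, float]
    effect_2: dict[str, float]
    variance: dict[str, float]

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g in self.gene_ids if self.gene_class[g] == cls]

    @property
    def shared_genes(self) -> list[str]:
        return [g for g in self.gene_ids
                if self.gene_class[g] in ("shared_up", "shared_down")]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids,
             "class": [self.gene_class[g] for g in self.gene_ids],
             "effect_disease1": [self.effect_1[g] for g in self.gene_ids],
             "effect_disease2": [self.effect_2[g] for g in self.gene_ids],
             "variance": [self.variance[g] for g in self.gene_ids]}
        )


def generate_two_disease_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], list[ExpressionStudy], TruthLabels]:
    """Simulate both diseases' cohorts plus the planted truth.

    Per gene g: baseline b_g ~ N(baseline_log2_mean, baseline_log2_sd^2) and
    variance sigma_g^2 ~ d0*s0^2/chi2_{d0}.  In each cohort, control samples
    are N(b_g, sigma_g^2) on log2 scale and case samples N(b_g + effect,
    sigma_g^2); intensities are 2**(log2 value), hence strictly positive.
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])

    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    classes = (
        ["shared_up"] * config.n_shared_up
        + ["shared_down"] * config.n_shared_down
        + [f"specific_{config.disease_ids[0]}"] * config.n_specific_per_disease
        + [f"specific_{config.disease_ids[1]}"] * config.n_specific_per_disease
        + ["null"] * (n - config.n_shared_up - config.n_shared_down
                      - 2 * config.n_specific_per_disease)
    )

    rho = config.cross_disease_effect_correlation
    sd = config.effect_sd
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    mu = config.effect_mean

    effect = np.zeros((n, 2))
    for cls, sign in (("shared_up", 1.0), ("shared_down", -1.0)):
        idx = [i for i, c in enumerate(classes) if c == cls]
        if idx:
            effect[idx] = master.multivariate_normal([sign * mu, sign * mu], cov,
                                                     size=len(idx))
    for d in (0, 1):
        idx = [i for i, c in enumerate(classes)
               if c == f"specific_{config.disease_ids[d]}"]
        if idx:
            signs = master.choice([-1.0, 1.0], size=len(idx))
            effect[idx, d] = signs * master.normal(mu, sd, size=len(idx))

    d0, s0_2 = config.variance_prior_df, config.variance_prior_scale
    sigma2 = d0 * s0_2 / master.chisquare(d0, size=n)
    baseline = master.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    truth = TruthLabels(
        gene_ids=gene_ids,
        gene_class=dict(zip(gene_ids, classes)),
        effect_1=dict(zip(gene_ids, effect[:, 0])),
        effect_2=dict(zip(gene_ids, effect[:, 1])),
        variance=dict(zip(gene_ids, sigma2)),
    )

    studies: tuple[list[ExpressionStudy], list[ExpressionStudy]] = ([], [])
    dataset_seeds = ss.spawn(2 * config.n_datasets_per_disease + 1)[1:]
    k = 0
    for d in (0, 1):
        for c, (n1, n2) in enumerate(config.samples_for(d)):
            rng = np.random.default_rng(dataset_seeds[k])
            k += 1
            log2x = np.empty((n, n1 + n2))
            sig = np.sqrt(sigma2)[:, None]
            log2x[:, :n1] = (baseline[:, None] + effect[:, d][:, None]
                             + rng.normal(0.0, 1.0, size=(n, n1)) * sig)
            log2x[:, n1:] = (baseline[:, None]
                             + rng.normal(0.0, 1.0, size=(n, n2)) * sig)
            studies[d].append(
                ExpressionStudy(
                    gene_ids=gene_ids,
                    matrix=2.0 ** log2x,
                    groups=["case"] * n1 + ["control"] * n2,
                    study_id=f"{config.disease_ids[d]}_cohort{c + 1}",
                )
            )
    return studies[0], studies[1], truth


# ---------------------------------------------------------------------------
# network fixture
# ---------------------------------------------------------------------------


@dataclass
class SyntheticNetworkSpec:
    """PPI fixture: sparse background plus hubs of strictly larger degree."""

    n_background_nodes: int = 100
    n_planted_hubs: int = 1
    hub_degree: int = 20
    background_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_hubs >= self.n_background_nodes:
            raise ConfigurationError("need fewer hubs than background nodes")
        if self.hub_degree >= self.n_background_nodes + self.n_planted_hubs:
            raise ConfigurationError("hub_degree must be below the node count")
        if not 0.0 <= self.background_density <= 1.0:
            raise ConfigurationError("background density must lie in [0, 1]")
        if min(self.n_background_nodes, self.n_planted_hubs, self.hub_degree) < 0:
            raise ConfigurationError("counts must be non-negative")


def generate_ppi_graph(spec: SyntheticNetworkSpec) -> nx.Graph:
    """Undirected simple graph with planted hubs attached to ``hub_degree`` nodes.

    Background nodes are wired as an Erdős–Rényi graph whose expected degree
    stays well below ``hub_degree``, so planted hubs dominate every
    centrality measure by construction.
    """
    rng = np.random.default_rng(spec.seed)
    bg = [f"B{i:04d}" for i in range(spec.n_background_nodes)]
    hubs = [f"HUB{i:02d}" for i in range(spec.n_planted_hubs)]
    g = nx.Graph()
    g.add_nodes_from(bg + hubs)
    # background: Erdos-Renyi among background nodes
    for i in range(len(bg)):
        for j in range(i + 1, len(bg)):
            if rng.random() < spec.background_density:
                g.add_edge(bg[i], bg[j])
    for h in hubs:
        neighbors = rng.choice(len(bg), size=spec.hub_degree, replace=False)
        for j in neighbors:
            g.add_edge(h, bg[j])
    return g


# ---------------------------------------------------------------------------
# gene-set fixture
# ---------------------------------------------------------------------------


def generate_gene_set_collection(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    planted_set: Sequence[str],
    seed: int = 0,
    planted_name: str = "PLANTED",
) -> GeneSetCollection:
    """Random gene sets plus one designated set containing the planted genes."""
    universe = list(universe)
    planted = set(planted_set)
    if not planted <= set(universe):
        raise ConfigurationError("planted_set must be a subset of the universe")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ConfigurationError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    if planted:
        size = max(len(planted), int(rng.integers(lo, hi + 1)))
        extra = [g for g in universe if g not in planted]
        pad = rng.choice(len(extra), size=size - len(planted), replace=False) \
            if size > len(planted) else []
        sets[planted_name] = planted | {extra[i] for i in pad}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i:03d}"] = {universe[j] for j in members}
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# binding-affinity fixture
# ---------------------------------------------------------------------------


def generate_bas_matrix(
    n_receptors: int,
    n_ligands: int,
    n_strong_ligands: int,
    strong_mean: float = -9.0,
    weak_mean: float = -5.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[BASMatrix, list[str]]:
    """Docking-score matrix with planted strong binders (more negative kcal/mol).

    Returns the matrix and the planted strong-ligand names.
    """
    if min(n_receptors, n_ligands, n_strong_ligands) < 0 or noise_sd < 0:
        raise ConfigurationError("dimensions and noise_sd must be non-negative")
    if n_strong_ligands > n_ligands:
        raise ConfigurationError("n_strong_ligands exceeds n_ligands")
    if not strong_mean < weak_mean:
        raise ConfigurationError(
            "strong_mean must be more negative (stronger) than weak_mean"
        )
    rng = np.random.default_rng(seed)
    receptors = [f"R{i:02d}" for i in range(n_receptors)]
    ligands = [f"L{j:03d}" for j in range(n_ligands)]
    means = np.full(n_ligands, weak_mean)
    means[:n_strong_ligands] = strong_mean
    scores = means[None, :] + rng.normal(0.0, noise_sd, size=(n_receptors, n_ligands))
    frame = pd.DataFrame(scores, index=receptors, columns=ligands)
    return BASMatrix(scores=frame), ligands[:n_strong_ligands]
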