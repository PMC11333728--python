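"""Cross-cohort and cross-disease DEG intersection and fold-change association.

Within one disease, genes called differentially expressed with a consistent
direction across the disease's cohorts form the common DEGs (cDEGs).  Genes
that are cDEGs in both diseases, with matching direction by default, form the
shared DEGs (sDEGs).  The per-disease average log2 fold changes of the shared
genes are then correlated (Pearson's r) to quantify how similarly the two
diseases perturb the shared transcriptional program; a permutation test
supplies a significance level for that local association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from crossdx.diffexpr import DEGTable

IntersectMode = Literal["strict", "majority"]


@dataclass
class FoldChangeProfile:
    """Per-disease aggregated fold changes: gene → mean aLog2FC over cohorts."""

    disease_id: str
    fold_changes: dict[str, float]
    n_datasets: dict[str, int]
    rejects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, v in self.fold_changes.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite aggregated fold change for {g!r}")
            if self.n_datasets.get(g, 0) < 1:
                raise ValueError(f"gene {g!r} has no contributing dataset")


@dataclass
class SharedDEGSet:
    """Genes surviving cross-disease intersection with per-disease metadata."""

    genes: list[str]
    direction_1: dict[str, str]
    direction_2: dict[str, str]
    alog2fc_1: dict[str, float]
    alog2fc_2: dict[str, float]

    @property
    def n_up(self) -> int:
        return sum(1 for g in self.genes
                   if self.direction_1[g] == self.direction_2[g] == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for g in self.genes
                   if self.direction_1[g] == self.direction_2[g] == "down")


@dataclass
class AssociationResult:
    """Pearson correlation of per-disease fold changes over shared genes."""

    r: float
    n_genes: int
    excluded: list[str] = field(default_factory=list)
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("association requires >= 3 genes")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


def intersect_common_degs(
    deg_tables: Sequence[DEGTable],
    mode: IntersectMode = "strict",
) -> dict[str, str]:
    """Genes DE with the same direction across a disease's cohorts.

    ``strict`` keeps a gene iff it is called a DEG with the SAME direction in
    every table; ``majority`` iff the same-direction call holds in more than
    half of the tables.  Returns gene → direction.
    """
    if not deg_tables:
        raise ValueError("need at least one DEG table")
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(deg_tables)
    votes: dict[str, dict[str, int]] = {}
    for tab in deg_tables:
        if tab.table["gene_id"].duplicated().any():
            dup = tab.table.loc[tab.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(
                f"duplicate gene id {dup!r} in table {tab.study_id!r}"
            )
        for gene, direction in tab.directions().items():
            votes.setdefault(gene, {"up": 0, "down": 0})[direction] += 1
    out: dict[str, str] = {}
    for gene, v in votes.items():
        for direction in ("up", "down"):
            k = v[direction]
            if (mode == "strict" and k == n) or (mode == "majority" and k > n / 2):
                out[gene] = direction
    return out


def aggregate_disease_fold_changes(
    deg_tables: Sequence[DEGTable],
    genes: Iterable[str],
    disease_id: str = "disease",
) -> FoldChangeProfile:
    """Unweighted mean of per-cohort aLog2FC over cohorts measuring each gene.

    Genes absent from every table are listed in ``rejects`` rather than
    silently dropped.
    """
    per_table = [tab.fold_changes() for tab in deg_tables]
    fold_changes: dict[str, float] = {}
    counts: dict[str, int] = {}
    rejects: list[str] = []
    for gene in genes:
        vals = [fc[gene] for fc in per_table if gene in fc]
        if not vals:
            rejects.append(gene)
            continue
        fold_changes[gene] = float(np.mean(vals))
        counts[gene] = len(vals)
    return FoldChangeProfile(
        disease_id=disease_id, fold_changes=fold_changes, n_datasets=counts,
        rejects=rejects,
    )


def intersect_shared_degs(
    cdegs_1: Mapping[str, str],
    cdegs_2: Mapping[str, str],
    require_concordant: bool = True,
    profile_1: FoldChangeProfile | None = None,
    profile_2: FoldChangeProfile | None = None,
) -> SharedDEGSet:
    """Genes that are common DEGs in both diseases.

    With ``require_concordant`` (default) the per-disease directions must
    match; otherwise discordant genes are kept and labelled per disease.
    """
    common = sorted(set(cdegs_1) & set(cdegs_2))
    genes = [g for g in common
             if not require_concordant or cdegs_1[g] == cdegs_2[g]]
    fc1 = profile_1.fold_changes if profile_1 else {}
    fc2 = profile_2.fold_changes if profile_2 else {}
    return SharedDEGSet(
        genes=genes,
        direction_1={g: cdegs_1[g] for g in genes},
        direction_2={g: cdegs_2[g] for g in genes},
        alog2fc_1={g: fc1[g] for g in genes if g in fc1},
        alog2fc_2={g: fc2[g] for g in genes if g in fc2},
    )


def _matched_vectors(
    profile_x: FoldChangeProfile,
    profile_y: FoldChangeProfile,
    genes: Iterable[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if genes is None:
        genes = sorted(set(profile_x.fold_changes) | set(profile_y.fold_changes))
    genes = list(genes)
    kept = [g for g in genes
            if g in profile_x.fold_changes and g in profile_y.fold_changes]
    excluded = [g for g in genes if g not in kept]
    x = np.array([profile_x.fold_changes[g] for g in kept])
    y = np.array([profile_y.fold_changes[g] for g in kept])
    return x, y, kept, excluded


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("zero variance in a fold-change vector: r undefined")
    return float(np.sum(xc * yc) / denom)


def local_association(
    profile_x: FoldChangeProfile,
    profile_y: FoldChangeProfile,
    genes: Iterable[str] | None = None,
) -> AssociationResult:
    """Pearson correlation of the two diseases' aLog2FC over matched genes."""
    x, y, kept, excluded = _matched_vectors(profile_x, profile_y, genes)
    if len(kept) < 3:
        raise ValueError(f"need >= 3 genes present in both profiles, got {len(kept)}")
    return AssociationResult(r=_pearson(x, y), n_genes=len(kept), excluded=excluded)


def association_permutation_p(
    profile_x: FoldChangeProfile,
    profile_y: FoldChangeProfile,
    genes: Iterable[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Two-sided permutation p for the local association.

    Permutes the gene labels of the second profile; the add-one estimator
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)`` avoids zero p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, y, kept, excluded = _matched_vectors(profile_x, profile_y, genes)
    if len(kept) < 3:
        raise ValueError(f"need >= 3 genes present in both profiles, got {len(kept)}")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_p = _pearson(x, rng.permutation(y))
        if abs(r_p) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AssociationResult(
        r=r_obs, n_genes=len(kept), excluded=excluded,
        p_perm=p, n_perm=n_perm, seed=seed,
    )
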