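"""Hypergeometric gene-set enrichment and methylation beta-values.

Enrichment of a query gene list (e.g. the shared key genes) in an annotated
set A_i is assessed from the 2×2 contingency table

                    in A_i        not in A_i
    query             k_i          n - k_i
    not query      M_i - k_i    N - M_i - n + k_i

with N the annotated universe, via the one-sided (over-representation)
hypergeometric tail P(X >= k); Benjamini–Hochberg adjustment is applied
across a collection.  Methylation level at a CpG probe is summarized as
beta = M / (M + U + 100), with M and U the methylated and unmethylated
intensities; the +100 stabilizer bounds beta below 1 at low total intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from crossdx.diffexpr import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over an annotated universe of N genes."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: set(genes) for name, genes in self.sets.items()}
        if self.universe is None:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        else:
            self.universe = set(self.universe)
            for name, genes in self.sets.items():
                extra = genes - self.universe
                if extra:
                    raise ValueError(
                        f"set {name!r} has {len(extra)} genes outside the universe"
                    )

    @property
    def n_universe(self) -> int:
        return len(self.universe)


@dataclass
class ContingencyTable:
    """2×2 over-representation table; cells sum to the universe size N."""

    k: int  # query ∩ set
    M: int  # set size
    n: int  # query size
    N: int  # universe size

    def __post_init__(self) -> None:
        cells = self.cells
        if any(c < 0 for c in cells):
            raise ValueError(f"negative contingency cell in {cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.k, self.M - self.k, self.n - self.k,
                self.N - self.M - self.n + self.k)


@dataclass
class EnrichmentResult:
    set_name: str
    k: int
    M: int
    n: int
    N: int
    p: float
    adj_p: float
    overlap: list[str] = field(default_factory=list)
    significant: bool = False


def build_contingency(query_genes: Iterable[str], set_genes: Iterable[str],
                      universe: Iterable[str]) -> ContingencyTable:
    """Contingency table for a query against one annotated set.

    Query genes outside the universe are dropped with a warning; the set must
    be contained in the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
    aset = set(set_genes)
    if aset - universe:
        raise ValueError("annotated set contains genes outside the universe")
    return ContingencyTable(k=len(query & aset), M=len(aset), n=len(query),
                            N=len(universe))


def enrichment_test(table: ContingencyTable) -> float:
    """One-sided over-representation p-value, P(X >= k), X ~ Hypergeom(N, M, n)."""
    return float(hypergeom.sf(table.k - 1, table.N, table.M, table.n))


def enrich_collection(query_genes: Iterable[str], collection: GeneSetCollection,
                      p_cut: float = 0.05) -> list[EnrichmentResult]:
    """Test every set in the collection, BH-adjust, sort by raw p."""
    query = set(query_genes)
    if not query or not collection.sets:
        raise ValueError("query and collection must be non-empty")
    names = sorted(collection.sets)
    tables = [build_contingency(query, collection.sets[name], collection.universe)
              for name in names]
    raw = [enrichment_test(t) for t in tables]
    adj = adjust_pvalues(raw, method="bh")
    eff_query = query & collection.universe
    results = [
        EnrichmentResult(
            set_name=name, k=t.k, M=t.M, n=t.n, N=t.N, p=p, adj_p=a,
            overlap=sorted(eff_query & collection.sets[name]),
            significant=bool(a < p_cut),
        )
        for name, t, p, a in zip(names, tables, raw, adj)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set": r.set_name, "k": r.k, "M": r.M, "n": r.n, "N": r.N,
             "p": r.p, "adj_p": r.adj_p, "significant": r.significant,
             "overlap": ",".join(r.overlap)}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def beta_value(m_intensity: float, u_intensity: float) -> float:
    """Methylation fraction beta = M / (M + U + 100), in [0, 1)."""
    if m_intensity < 0 or u_intensity < 0:
        raise ValueError("methylation intensities must be non-negative")
    return m_intensity / (m_intensity + u_intensity + 100.0)


def beta_table(meth: pd.DataFrame) -> pd.DataFrame:
    """Add a ``beta`` column to a (probe, gene, M, U) intensity table."""
    out = meth.copy()
    out["beta"] = [beta_value(m, u) for m, u in zip(out["M"], out["U"])]
    return out


def compare_group_beta(meth: pd.DataFrame, group_col: str = "group",
                       margin: float = 0.0) -> pd.DataFrame:
    """Mean beta per probe and group, with a hypo/hyper call at ``margin``.

    Expects columns probe, gene, M, U and a two-level group column (e.g.
    tumor/normal).  A probe is called ``hypo`` when the first group's mean
    beta is below the second's by more than ``margin``, ``hyper`` for the
    reverse, ``none`` otherwise.  No universal margin exists; 0 simply
    compares the means.
    """
    tab = beta_table(meth)
    groups = sorted(tab[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    rows = []
    for (probe, gene), sub in tab.groupby(["probe", "gene"], sort=True):
        b1 = sub.loc[sub[group_col] == g1, "beta"].mean()
        b2 = sub.loc[sub[group_col] == g2, "beta"].mean()
        diff = b1 - b2
        call = "hypo" if diff < -margin else ("hyper" if diff > margin else "none")
        rows.append({"probe": probe, "gene": gene, f"beta_{g1}": b1,
                     f"beta_{g2}": b2, "delta_beta": diff, "call": call})
    return pd.DataFrame(rows)
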