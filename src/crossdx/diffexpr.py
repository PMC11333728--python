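"""Per-cohort two-group differential expression with a moderated t-statistic.

A cohort is a genes × samples matrix of strictly positive intensities with a
case/control label per sample.  For each gene the average log2 fold change
(aLog2FC) of case over control is computed, and significance is assessed with
an empirical-Bayes moderated t-statistic: the per-gene pooled residual
variance ``s_g^2`` (``d_g = n1 + n2 - 2`` df) is shrunk toward a prior
variance ``s0^2`` carrying ``d0`` prior degrees of freedom,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t ``aLog2FC_g / (s~_g * sqrt(1/n1 + 1/n2))`` is referred to
a t distribution on ``d0 + d_g`` degrees of freedom.  The hyperparameters
``(d0, s0^2)`` are estimated by closed-form moment matching on
``log s_g^2``, which is exact under the hierarchical model
``s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_{d_g} / d_g`` with
``sigma_g^2 ~ d0 s0^2 / chi2_{d0}`` (scaled inverse chi-square prior).

Genes are then called up/down-regulated by the combined rule
``adj.p < p_cut and |aLog2FC| > fc_cut``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

AdjustMethod = Literal["bh", "bonferroni", "none"]


class DataError(ValueError):
    """Raised for invalid expression data (non-positive intensities etc.)."""


class EstimationError(RuntimeError):
    """Raised when variance hyperparameters cannot be estimated."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """One cohort: positive intensity matrix (genes × samples) plus labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    matrix
        Strictly positive expression intensities, shape (n_genes, n_samples).
    groups
        Per-sample label, each ``"case"`` or ``"control"``.
    study_id
        Cohort identifier (e.g. a GEO accession).
    """

    gene_ids: list[str]
    matrix: np.ndarray
    groups: list[str]
    study_id: str = "study"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.groups = list(self.groups)
        if self.matrix.ndim != 2:
            raise DataError("expression matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.gene_ids), len(self.groups)):
            raise DataError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.gene_ids)} genes and {len(self.groups)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids must be unique")
        bad = set(self.groups) - {CASE, CONTROL}
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("expression matrix contains non-finite values")
        if np.any(self.matrix <= 0):
            g, s = np.argwhere(self.matrix <= 0)[0]
            raise DataError(
                f"non-positive intensity for gene {self.gene_ids[g]!r} in "
                f"sample {s} of study {self.study_id!r}; log2 fold changes "
                "require positive intensities (pass a pseudocount explicitly "
                "upstream if this is intended)"
            )

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == CASE for g in self.groups])

    @property
    def n1(self) -> int:
        """Number of case samples."""
        return int(self.case_mask.sum())

    @property
    def n2(self) -> int:
        """Number of control samples."""
        return len(self.groups) - self.n1

    @property
    def log2_matrix(self) -> np.ndarray:
        return np.log2(self.matrix)


@dataclass
class ModeratedFitSummary:
    """Empirical-Bayes variance shrinkage summary for one cohort."""

    prior_df: float  # d0, may be math.inf
    prior_variance: float  # s0^2
    residual_variance: np.ndarray  # s_g^2 per gene
    residual_df: float  # d_g = n1 + n2 - 2 (same for every gene)

    @property
    def posterior_variance(self) -> np.ndarray:
        """Shrunken variance s~_g^2, between s_g^2 and s0^2 elementwise."""
        if math.isinf(self.prior_df):
            return np.full_like(self.residual_variance, self.prior_variance)
        d0, dg = self.prior_df, self.residual_df
        return (d0 * self.prior_variance + dg * self.residual_variance) / (d0 + dg)


@dataclass
class DEGTable:
    """Per-gene test results for one cohort plus the thresholds applied."""

    study_id: str
    table: pd.DataFrame  # gene_id, alog2fc, t, p, adj_p, direction
    p_cut: float
    fc_cut: float
    adjust: str = "bh"

    @property
    def up_count(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def down_count(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def directions(self) -> dict[str, str]:
        """gene → direction for genes called up or down."""
        sub = self.table[self.table["direction"] != "none"]
        return dict(zip(sub["gene_id"], sub["direction"]))

    def fold_changes(self) -> dict[str, float]:
        return dict(zip(self.table["gene_id"], self.table["alog2fc"]))


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def compute_alog2fc(study: ExpressionStudy, gene: str | None = None) -> np.ndarray | float:
    """Average log2 fold change of case over control.

    For unequal group sizes this is the difference of group means of log2
    intensities; for equal sizes it is the index-paired mean log-ratio.  The
    two forms coincide when n1 = n2, so a single vectorized difference of
    means is computed; the paired branch is kept for the equal-size case to
    mirror the published definition exactly.

    Returns the per-gene vector, or a scalar when ``gene`` is given.
    """
    case = study.log2_matrix[:, study.case_mask]
    ctrl = study.log2_matrix[:, ~study.case_mask]
    if study.n1 == study.n2:
        # paired mean log-ratio; algebraically identical to the difference
        # of means under index pairing
        fc = np.mean(case - ctrl, axis=1)
    else:
        fc = case.mean(axis=1) - ctrl.mean(axis=1)
    if gene is None:
        return fc
    try:
        idx = study.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not in study {study.study_id!r}") from None
    return float(fc[idx])


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone transformation of the Newton step on 1/trigamma, which
    converges for all y > 0.  Returns ``inf`` for y <= 0 (no finite solution).
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    else:
        logger.warning("trigamma_inverse did not converge; returning last iterate")
    return x


def _fit_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log sample variances.

    Under the hierarchical model, e_g = log s_g^2 - psi(dg/2) + log(dg/2)
    has mean log s0^2 + psi(d0/2) - log(d0/2) and variance
    psi'(dg/2) + psi'(d0/2); solving the variance equation for d0 with the
    trigamma inverse and back-substituting gives s0^2.
    """
    ok = s2 > 0
    if ok.sum() == 0:
        raise EstimationError("all genes have zero residual variance")
    if ok.sum() < s2.size:
        logger.warning("%d genes with zero residual variance excluded from prior fit",
                       s2.size - ok.sum())
    z = np.log(s2[ok])
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    n = e.size
    if n < 2:
        logger.warning("single usable gene: no prior df estimable, using d0 = 0")
        return 0.0, float(np.exp(e).mean())
    emean = float(e.mean())
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    evar -= float(special.polygamma(1, dg / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
    else:
        d0 = math.inf
    if math.isinf(d0):
        s0_2 = float(np.exp(emean))
    else:
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_2


def fit_moderated_t(
    study: ExpressionStudy,
    prior_df: float | None = None,
    prior_variance: float | None = None,
) -> tuple[ModeratedFitSummary, np.ndarray, np.ndarray]:
    """Fit the moderated t-statistic for every gene of one cohort.

    Parameters
    ----------
    study
        The cohort; needs at least two case and two control samples.
    prior_df, prior_variance
        Optional overrides of the estimated hyperparameters; ``prior_df=0``
        recovers the classical pooled two-sample t, ``prior_df=inf`` fixes
        every posterior variance at ``prior_variance``.

    Returns
    -------
    (summary, t, p)
        The fit summary and per-gene moderated t and two-sided p-values.
    """
    n1, n2 = study.n1, study.n2
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"study {study.study_id!r} needs >= 2 samples per group "
            f"(got {n1} case, {n2} control)"
        )
    log2x = study.log2_matrix
    case = log2x[:, study.case_mask]
    ctrl = log2x[:, ~study.case_mask]
    dg = float(n1 + n2 - 2)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / dg

    if prior_df is None:
        if len(study.gene_ids) < 2:
            logger.warning("single-gene input: falling back to d0 = 0 (classical t)")
            d0, s0_2 = 0.0, float(s2.mean()) if s2.size else 1.0
        else:
            d0, s0_2 = _fit_variance_prior(s2, dg)
            if math.isinf(d0):
                logger.warning("no excess dispersion in log-variances: d0 = inf")
    else:
        d0 = float(prior_df)
        if prior_variance is not None:
            s0_2 = float(prior_variance)
        elif d0 == 0.0:
            s0_2 = float(s2[s2 > 0].mean()) if np.any(s2 > 0) else 1.0
        else:
            _, s0_2 = _fit_variance_prior(s2, dg)
    if prior_variance is not None:
        s0_2 = float(prior_variance)

    summary = ModeratedFitSummary(
        prior_df=d0, prior_variance=s0_2, residual_variance=s2, residual_df=dg
    )
    post = summary.posterior_variance
    fc = np.asarray(compute_alog2fc(study))
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + dg)
    return summary, t, p


# ---------------------------------------------------------------------------
# multiple testing + classification
# ---------------------------------------------------------------------------


def adjust_bh(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    return adjust_pvalues(raw_p, method="bh")


def adjust_pvalues(raw_p: Sequence[float], method: AdjustMethod = "bh") -> np.ndarray:
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def classify_degs(
    results: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 1.0,
    study_id: str = "study",
    adjust: str = "bh",
) -> DEGTable:
    """Apply the combined DEG rule: adj.p < p_cut and |aLog2FC| > fc_cut.

    ``results`` must carry columns ``gene_id``, ``alog2fc`` and ``adj_p``
    (``t`` and ``p`` are passed through when present).
    """
    tab = results.copy()
    up = (tab["adj_p"] < p_cut) & (tab["alog2fc"] > fc_cut)
    down = (tab["adj_p"] < p_cut) & (tab["alog2fc"] < -fc_cut)
    tab["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return DEGTable(study_id=study_id, table=tab, p_cut=p_cut, fc_cut=fc_cut, adjust=adjust)


def run_diffexpr(
    study: ExpressionStudy,
    p_cut: float = 0.05,
    fc_cut: float = 1.0,
    adjust: AdjustMethod = "bh",
    prior_df: float | None = None,
    prior_variance: float | None = None,
) -> tuple[DEGTable, ModeratedFitSummary]:
    """Full per-cohort analysis: fold change, moderated t, adjustment, calls."""
    summary, t, p = fit_moderated_t(study, prior_df=prior_df, prior_variance=prior_variance)
    fc = np.asarray(compute_alog2fc(study))
    adj = adjust_pvalues(p, method=adjust)
    tab = pd.DataFrame(
        {"gene_id": study.gene_ids, "alog2fc": fc, "t": t, "p": p, "adj_p": adj}
    )
    deg = classify_degs(tab, p_cut=p_cut, fc_cut=fc_cut, study_id=study.study_id,
                        adjust=adjust)
    return deg, summary
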