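"""Docking-score drug prioritization and rule-based drug-likeness screening.

A binding-affinity-score (BAS) matrix holds predicted docking energies
(kcal/mol, more negative = stronger binding) for receptor proteins (rows)
against candidate ligands (columns).  Ligands are prioritized by their
column mean over available receptors, strongest first; candidate drugs are
those whose mean beats an average cut (default −7.7 kcal/mol), with any
receptor they fail to bind strongly (entry ≥ −7.0 kcal/mol by default)
reported alongside.  Screening of the prioritized molecules applies
Lipinski's rule of five (MW ≤ 500 Da, LogP ≤ 5, H-bond donors ≤ 5,
acceptors ≤ 10) and threshold rules on predicted ADMET indices (intestinal
absorption HIA ≥ 30% = high; blood–brain barrier LogBB ≥ 0.3 = permeant,
< −1 = poor).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd


@dataclass
class BASMatrix:
    """Receptor × ligand binding-affinity scores; NaN marks missing entries."""

    scores: pd.DataFrame  # index: receptor ids, columns: ligand ids, kcal/mol

    def __post_init__(self) -> None:
        if self.scores.shape[0] < 1 or self.scores.shape[1] < 1:
            raise ValueError("BAS matrix needs at least one receptor and one ligand")
        if self.scores.index.duplicated().any() or self.scores.columns.duplicated().any():
            raise ValueError("duplicate receptor or ligand labels")
        vals = self.scores.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (infinite) binding scores")

    @property
    def receptors(self) -> list[str]:
        return list(self.scores.index)

    @property
    def ligands(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class DrugRanking:
    """Ligands and receptors ordered by mean BAS, strongest (most negative) first."""

    ligand_means: pd.Series  # ordered, most negative first
    receptor_means: pd.Series
    excluded_ligands: list[str]
    min_coverage: float
    matrix: BASMatrix


def rank_bas_matrix(matrix: BASMatrix, min_coverage: float = 0.8) -> DrugRanking:
    """Order ligands by column mean and receptors by row mean over available scores.

    Ligands with fewer than ``min_coverage`` × n_receptors non-missing entries
    are excluded and reported rather than ranked on thin evidence.
    """
    scores = matrix.scores
    n_rec = scores.shape[0]
    coverage = scores.notna().sum(axis=0) / n_rec
    kept = coverage[coverage >= min_coverage].index
    excluded = [c for c in scores.columns if c not in set(kept)]
    if len(kept) == 0:
        raise ValueError("no ligand meets the coverage floor")
    lig_means = scores[kept].mean(axis=0, skipna=True)
    lig_means = lig_means.iloc[np.lexsort((lig_means.index.astype(str), lig_means.values))]
    rec_means = scores.mean(axis=1, skipna=True)
    rec_means = rec_means.iloc[np.lexsort((rec_means.index.astype(str), rec_means.values))]
    return DrugRanking(ligand_means=lig_means, receptor_means=rec_means,
                       excluded_ligands=excluded, min_coverage=min_coverage,
                       matrix=matrix)


def select_candidate_drugs(ranking: DrugRanking, avg_cut: float = -7.7,
                           per_receptor_cut: float = -7.0) -> pd.DataFrame:
    """Ligands whose mean BAS beats ``avg_cut``, with weak-binding receptors listed.

    For each selected ligand the report names the receptors (if any) where the
    individual score fails the strong-binding threshold (entry ≥
    ``per_receptor_cut``), so exceptions like a single weakly bound receptor
    are visible rather than hidden in the average.
    """
    rows = []
    scores = ranking.matrix.scores
    for ligand, mean in ranking.ligand_means.items():
        if not mean < avg_cut:
            continue
        col = scores[ligand]
        weak = sorted(col.index[(col >= per_receptor_cut) & col.notna()].astype(str))
        rows.append({
            "ligand": ligand,
            "mean_bas": float(mean),
            "n_receptors": int(col.notna().sum()),
            "weak_receptors": ",".join(weak),
            "binds_all_strongly": len(weak) == 0,
        })
    return pd.DataFrame(rows, columns=["ligand", "mean_bas", "n_receptors",
                                       "weak_receptors", "binds_all_strongly"])


# ---------------------------------------------------------------------------
# drug-likeness / ADMET rules
# ---------------------------------------------------------------------------


@dataclass
class MoleculeDescriptors:
    """Physicochemical descriptors for the rule-of-five check."""

    name: str
    molecular_weight: float  # Da
    logp: float
    hbond_acceptors: int
    hbond_donors: int
    polar_surface_area: float | None = None  # Å^2
    rotatable_bonds: int | None = None

    def __post_init__(self) -> None:
        for fname in ("molecular_weight", "logp", "hbond_acceptors", "hbond_donors"):
            if getattr(self, fname) is None:
                raise ValueError(f"missing descriptor field {fname!r} for {self.name!r}")
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular weight must be positive for {self.name!r}")
        if self.hbond_acceptors < 0 or self.hbond_donors < 0:
            raise ValueError(f"H-bond counts must be non-negative for {self.name!r}")


LIPINSKI_BOUNDS = {
    "MW": 500.0,    # molecular weight <= 500 Da
    "LogP": 5.0,    # octanol/water partition <= 5
    "HBD": 5,       # H-bond donors <= 5
    "HBA": 10,      # H-bond acceptors <= 10
}


def lipinski_violations(desc: MoleculeDescriptors) -> tuple[int, list[str]]:
    """Count of rule-of-five violations and the names of the violated rules."""
    violated = []
    if desc.molecular_weight > LIPINSKI_BOUNDS["MW"]:
        violated.append("MW")
    if desc.logp > LIPINSKI_BOUNDS["LogP"]:
        violated.append("LogP")
    if desc.hbond_donors > LIPINSKI_BOUNDS["HBD"]:
        violated.append("HBD")
    if desc.hbond_acceptors > LIPINSKI_BOUNDS["HBA"]:
        violated.append("HBA")
    return len(violated), violated


@dataclass
class ADMETProfile:
    """Predicted ADMET indices consumed as inputs; only thresholds are applied."""

    name: str
    hia: float  # human intestinal absorption, %
    logbb: float  # blood-brain barrier partition
    caco2: float | None = None
    pgp_inhibitor: bool | None = None
    logps: float | None = None
    cyp3a4_inhibitor: bool | None = None
    total_clearance: float | None = None
    ames_positive: bool | None = None
    lc50: float | None = None  # minnow toxicity, log mM
    ld50: float | None = None  # oral rat acute toxicity, mol/kg

    def __post_init__(self) -> None:
        if not 0.0 <= self.hia <= 100.0:
            raise ValueError(f"HIA must lie in [0, 100], got {self.hia} for {self.name!r}")


def classify_admet(profile: ADMETProfile, hia_cut: float = 30.0) -> dict:
    """Threshold verdicts: absorption high iff HIA ≥ hia_cut; BBB tri-level.

    BBB: ``permeant`` when LogBB ≥ 0.3, ``poor`` when LogBB < −1,
    ``intermediate`` otherwise.  Boolean flags are echoed into the report.
    """
    bbb = ("permeant" if profile.logbb >= 0.3
           else "poor" if profile.logbb < -1.0
           else "intermediate")
    return {
        "name": profile.name,
        "hia_verdict": "high" if profile.hia >= hia_cut else "low",
        "bbb_verdict": bbb,
        "pgp_inhibitor": profile.pgp_inhibitor,
        "cyp3a4_inhibitor": profile.cyp3a4_inhibitor,
        "ames_positive": profile.ames_positive,
    }
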