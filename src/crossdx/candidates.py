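"""Published descriptor and ADMET prediction tables for the three
prioritized repurposing candidates (Digoxin, Imatinib, Dovitinib).

These values are consumed as inputs — the package applies only the decision
rules (rule of five, HIA and LogBB thresholds) to them, it never predicts
such properties itself.
"""

from __future__ import annotations

from crossdx.drugrank import ADMETProfile, MoleculeDescriptors

CANDIDATE_DESCRIPTORS: dict[str, MoleculeDescriptors] = {
    "Digoxin": MoleculeDescriptors(
        name="Digoxin", molecular_weight=780.0, logp=4.84,
        hbond_acceptors=14, hbond_donors=6,
        polar_surface_area=203.06, rotatable_bonds=7,
    ),
    "Imatinib": MoleculeDescriptors(
        name="Imatinib", molecular_weight=493.0, logp=4.04,
        hbond_acceptors=6, hbond_donors=2,
        polar_surface_area=86.28, rotatable_bonds=8,
    ),
    "Dovitinib": MoleculeDescriptors(
        name="Dovitinib", molecular_weight=393.43, logp=2.26,
        hbond_acceptors=4, hbond_donors=3,
        polar_surface_area=94.04, rotatable_bonds=2,
    ),
}

CANDIDATE_ADMET: dict[str, ADMETProfile] = {
    "Digoxin": ADMETProfile(
        name="Digoxin", hia=68.58, logbb=-1.39, caco2=0.59,
        pgp_inhibitor=True, logps=-3.81, cyp3a4_inhibitor=False,
        total_clearance=3.67, ames_positive=False, lc50=4.35, ld50=3.7,
    ),
    "Imatinib": ADMETProfile(
        name="Imatinib", hia=93.85, logbb=-1.37, caco2=1.09,
        pgp_inhibitor=True, logps=-2.51, cyp3a4_inhibitor=True,
        total_clearance=0.72, ames_positive=False, lc50=2.08, ld50=2.9,
    ),
    "Dovitinib": ADMETProfile(
        name="Dovitinib", hia=83.63, logbb=-0.71, caco2=0.47,
        pgp_inhibitor=False, logps=-2.27, cyp3a4_inhibitor=True,
        total_clearance=0.76, ames_positive=True, lc50=3.04, ld50=2.4,
    ),
}
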