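#!/usr/bin/env python
"""Docking-score drug ranking and rule-based screening of the candidates.

Orders the 148 ligands of the binding-affinity fixture by column-mean BAS
(strongest first), selects candidates with mean < −7.7 kcal/mol while
reporting any receptor bound weaker than −7.0 kcal/mol, and applies the
rule-of-five and ADMET threshold rules to the published descriptor tables
of the three prioritized molecules.
"""

from pathlib import Path

import pandas as pd

from crossdx import io
from crossdx.candidates import CANDIDATE_ADMET, CANDIDATE_DESCRIPTORS
from crossdx.drugrank import classify_admet, lipinski_violations, \
    rank_bas_matrix, select_candidate_drugs

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "drugs"
    out.mkdir(parents=True, exist_ok=True)
    matrix = io.read_bas_matrix(ROOT / "sim" / "bas_matrix.csv")
    ranking = rank_bas_matrix(matrix)
    ranking.ligand_means.rename("mean_bas").to_csv(out / "ligand_ranking.tsv",
                                                   sep="\t")
    selection = select_candidate_drugs(ranking, avg_cut=-7.7,
                                       per_receptor_cut=-7.0)
    selection.to_csv(out / "drug_selection.tsv", sep="\t", index=False)
    print("strongest 5 ligands by mean BAS:",
          ", ".join(f"{l} ({m:.2f})"
                    for l, m in ranking.ligand_means.head(5).items()))
    print(f"{len(selection)} ligands pass mean BAS < -7.7 kcal/mol: "
          + ", ".join(selection['ligand']))

    rows = []
    for name, desc in CANDIDATE_DESCRIPTORS.items():
        count, rules = lipinski_violations(desc)
        verdicts = classify_admet(CANDIDATE_ADMET[name])
        rows.append({"name": name, "lipinski_violations": count,
                     "violated_rules": ",".join(rules),
                     "hia_verdict": verdicts["hia_verdict"],
                     "bbb_verdict": verdicts["bbb_verdict"]})
        print(f"{name}: {count} rule-of-five violations"
              f"{' (' + ', '.join(rules) + ')' if rules else ''}; "
              f"HIA {verdicts['hia_verdict']}, BBB {verdicts['bbb_verdict']}")
    pd.DataFrame(rows).to_csv(out / "candidate_screening.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
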