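"""Apply the total-agreement label filter to the shipped MEEI rating
table and recompute the published-table metrics.

The packaged CSV transcribes the per-file Grade/Roughness ratings of
the MEEI sustained-vowel recordings (three assessments by two speech
therapists). Keeping only files rated identically in all three passes
yields the 87-file Grade and 85-file Roughness agreement subsets.
"""

from importlib import resources

import numpy as np

from msmorph import (ConfusionMatrix, agreement_subset, altman,
                     cohens_kappa, efficiency, load_label_table)

path = resources.files("msmorph.data") / "meei_grbas_ratings.csv"
table = load_label_table(str(path))
print(f"rating table: {len(table)} files")

for trait in ("G", "R"):
    sub = agreement_subset(table, trait)
    counts = sub["label"].value_counts().sort_index()
    print(f"  trait {trait}: {len(sub)} files in total agreement; "
          f"per level {counts.to_dict()}")

# the best-configuration confusion matrix reported for the Grade subset
grade_cm = ConfusionMatrix(np.array([[28, 1, 0, 1], [3, 3, 1, 0],
                                     [1, 1, 11, 1], [3, 0, 4, 29]]))
eff, ci = efficiency(grade_cm)
kap = cohens_kappa(grade_cm)
print(f"\nreference Grade confusion matrix: efficiency {eff:.1f}% "
      f"+/- {ci:.1f}, kappa {kap:.2f} ({altman(kap)})")
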