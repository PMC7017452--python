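"""Cross-study fold-change concordance and the demographic cohort table.

Compares two fold-change vectors by Spearman correlation and direction
agreement, and reproduces a clinical characteristics table with Welch t /
Fisher exact p-values.
"""

import numpy as np
import pandas as pd

from amniotx import CohortConfig, fisher_exact_2x2, fold_change_concordance, generate_cohort
from amniotx.concordance import cohort_table

rng = np.random.default_rng(8)
fc = rng.normal(0, 1, 400)
res = fold_change_concordance(
    pd.DataFrame({"log2fc_a": fc, "log2fc_b": fc + rng.normal(0, 0.6, 400)})
)
print(f"cross-study: Spearman R = {res.spearman_r:.2f}, "
      f"direction agreement = {100 * res.direction_agreement:.0f}% (n = {res.n})")

# Published demographic contingency tables for the midtrimester/term cohort:
for name, table in [("parity", [[8, 22], [3, 65]]),
                    ("smoking", [[4, 26], [13, 55]]),
                    ("fetal sex", [[13, 17], [38, 30]])]:
    odds, p = fisher_exact_2x2(table)
    print(f"{name}: OR = {odds:.2f}, Fisher p = {p:.3f}")

_, _, _, sheet, _ = generate_cohort(CohortConfig(n_genes=50, seed=9))
print(cohort_table(sheet.table)[["test", "p"]].to_string())
# Each row compares the two study groups on one clinical variable using the
# test appropriate to its type.
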