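#!/usr/bin/env python
"""Significance-ordered cohort comparison and clinical correlation report.

Reads results/pipeline/ and writes to results/tables/:

* comparisons_ranked.csv — per-category UTUC-vs-ND rank-sum results ordered
  by p-value;
* significant_correlations.csv — clinical covariate vs analyte correlations
  passing the significance threshold and the minimum-patient rule.
"""

from __future__ import annotations

import pandas as pd

from common import PIPELINE_DIR, TABLES_DIR


def main() -> None:
    TABLES_DIR.mkdir(parents=True, exist_ok=True)

    comparisons = pd.read_csv(PIPELINE_DIR / "cohort_comparisons.csv")
    ranked = comparisons.sort_values(["p", "category"]).reset_index(drop=True)
    ranked.to_csv(TABLES_DIR / "comparisons_ranked.csv", index=False,
                  float_format="%.10g")

    correlations = pd.read_csv(PIPELINE_DIR / "clinical_correlations.csv")
    significant = correlations[correlations["significant"]
                               & ~correlations["suppressed"]]
    significant = significant.sort_values(["p", "variable", "analyte"])
    significant.to_csv(TABLES_DIR / "significant_correlations.csv",
                       index=False, float_format="%.10g")

    print("UTUC vs ND, ordered by p:")
    print(ranked.to_string(index=False))
    print(f"\n{len(significant)} significant clinical correlations "
          f"(of {len(correlations)} tested)")
    if len(significant):
        print(significant.to_string(index=False))


if __name__ == "__main__":
    main()
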