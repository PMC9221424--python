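#!/usr/bin/env python
"""Per-cohort enumeration tables from the pipeline bundle.

Reads results/pipeline/ and writes to results/tables/:

* enumeration_medians.csv — per cohort and category: median events/mL and
  prevalence (% of samples with at least one event);
* lev_proximity_split.json — free-floating vs cell-proximal percentages of
  the LEVs that survived the per-frame debris filter in the imaging arm.
"""

from __future__ import annotations

import json

import pandas as pd

from common import PIPELINE_DIR, TABLES_DIR

from liqbio.core import LEV_CLASSES
from liqbio.enumeration import cohort_summary, load_enumerations, proximity_split


def main() -> None:
    TABLES_DIR.mkdir(parents=True, exist_ok=True)
    enums = load_enumerations(PIPELINE_DIR / "enumerations.json")

    medians = cohort_summary(enums)
    medians.to_csv(TABLES_DIR / "enumeration_medians.csv", index=False,
                   float_format="%.10g")

    classified = pd.read_csv(PIPELINE_DIR / "frame_classified.csv")
    lev_names = {c.value for c in LEV_CLASSES}
    levs = classified[classified["event_class"].isin(lev_names)
                      & classified["passed_frame_filter"]]
    split = proximity_split(
        n_free_floating=int((levs["lev_proximity"] == "free_floating").sum()),
        n_cell_proximal=int((levs["lev_proximity"] == "cell_proximal").sum()))
    (TABLES_DIR / "lev_proximity_split.json").write_text(
        json.dumps(split, indent=1, sort_keys=True))

    print(medians.to_string(index=False))
    print("\nLEV proximity split (imaging arm, post-filter):")
    print(json.dumps(split, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
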