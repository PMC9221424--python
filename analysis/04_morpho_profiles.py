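#!/usr/bin/env python
"""Morphometric cluster composition and density-peak summary.

Reads results/pipeline/ and writes to results/tables/:

* cluster_composition.csv — Ward cluster x channel-type class counts over
  the pooled tumor-cohort cellular events;
* density_peaks.csv — copy of the per-class per-feature peak counts from the
  kernel-density profiles.
"""

from __future__ import annotations

import shutil

import pandas as pd

from common import PIPELINE_DIR, TABLES_DIR


def main() -> None:
    TABLES_DIR.mkdir(parents=True, exist_ok=True)

    emb = pd.read_csv(PIPELINE_DIR / "embedding.csv")
    composition = pd.crosstab(emb["cluster"], emb["event_class"])
    composition.to_csv(TABLES_DIR / "cluster_composition.csv")

    shutil.copy(PIPELINE_DIR / "density_peaks.csv",
                TABLES_DIR / "density_peaks.csv")
    peaks = pd.read_csv(TABLES_DIR / "density_peaks.csv")

    print("cluster x class composition (pooled UTUC cellular events):")
    print(composition.to_string())
    print("\nmultimodal feature/class pairs (n_peaks >= 2):")
    multi = peaks[peaks["n_peaks"] >= 2]
    print(multi.to_string(index=False) if len(multi) else "(none)")


if __name__ == "__main__":
    main()
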