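#!/usr/bin/env python
"""Run the full pipeline (simulate -> detect -> classify -> enumerate ->
stats -> cluster) and write the artifact bundle to results/pipeline/."""

from __future__ import annotations

import json
import logging

from common import default_config

from liqbio.pipeline import run_pipeline


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    bundle = run_pipeline(default_config())
    print(json.dumps(bundle.report, indent=1, sort_keys=True))
    print(f"\nartifacts written to {bundle.output_dir}/")


if __name__ == "__main__":
    main()
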