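"""Shared paths and the default configuration for the numbered analyses.

All analysis scripts are thin drivers: every computation lives in the
``liqbio`` package. Run them in order from the repository root::

    python analysis/01_run_pipeline.py
    python analysis/02_enumeration_tables.py
    python analysis/03_significance_ranking.py
    python analysis/04_morpho_profiles.py
"""

from __future__ import annotations

from pathlib import Path

from liqbio.config import ClusterConfig, PipelineConfig, SyntheticConfig

RESULTS = Path("results")
PIPELINE_DIR = RESULTS / "pipeline"
TABLES_DIR = RESULTS / "tables"

ANALYSIS_SEED = 11


def default_config() -> PipelineConfig:
    """Desk-scale run: 6 frames x 60 cells for the imaging arm, a 20-vs-50
    sample cohort for the enumeration/statistics arm."""
    return PipelineConfig(
        seed=ANALYSIS_SEED,
        output_dir=str(PIPELINE_DIR),
        synthetic=SyntheticConfig(
            n_frames=6, cells_per_frame=60, frame_px=256,
            rare_fraction=0.05, n_debris_frames=2, n_utuc=20, n_nd=50),
        cluster=ClusterConfig(k=6, perplexity=30, max_events=2000),
    )
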