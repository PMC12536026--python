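"""Shared settings for the numbered analysis scripts.

One fixed seed and one run directory so the scripts compose into a single
reproducible analysis.  Bulky intermediates (per-subject signal TSVs)
live under scratch/; the tables the analysis reports are copied into
results/.
"""

import shutil
import sys
from pathlib import Path

from glympipe.config import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS_DIR = ROOT / "results"

CONFIG = RunConfig(seed=17)


def publish(*names: str) -> None:
    """Copy selected run artifacts into results/."""
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    for name in names:
        src = RUN_DIR / name
        if not src.exists():
            sys.exit(f"missing artifact {src}; run the earlier scripts first")
        shutil.copy2(src, RESULTS_DIR / name)


def ensure_simulated():
    """Run the simulation stage if its outputs are not present yet."""
    from glympipe.pipeline import stage_simulate

    if not (RUN_DIR / "manifest.csv").exists():
        stage_simulate(CONFIG, RUN_DIR)
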