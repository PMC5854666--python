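"""Shared configuration for the analysis scripts.

One master seed and one run directory: every numbered script reads and
writes the same working directory, so they can be run in order (or any
later script re-run alone once its inputs exist). Bulky per-cell
intermediates stay under scratch/; the small summary tables that scripts
04-05 produce are copied into results/.
"""

from pathlib import Path

from nicheshift.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS_DIR = ROOT / "results"

CONFIG = RunConfig(seed=1)  # the default demo study system
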