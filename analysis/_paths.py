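"""Shared output locations for the analysis scripts."""

from pathlib import Path

RESULTS_DIR = Path(__file__).resolve().parent.parent / "results"
# bulky regenerable inputs (trajectories, config records) live under scratch/
DATA_DIR = Path(__file__).resolve().parent.parent / "scratch" / "data"
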