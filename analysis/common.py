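"""Shared locations and the study design for the analysis scripts.

The scripts run in order (01 → 06); raw image data land under
``scratch/analysis`` (disposable), derived tables under ``results``.
"""

from pathlib import Path

from tismorph.config import load_config

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 20260926


def config():
    cfg = load_config()
    # full NLO design (5 plates x 2 FOVs per condition and time point);
    # QPI kept at 2 dishes x 2 tomograms to stay interactive
    cfg["simulate"]["qpi"]["tomograms_per_dish"] = 2
    return cfg
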