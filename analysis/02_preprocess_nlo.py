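"""Correct the raw NLO rasters: de-serpentine rows, median-filter
1-pixel outliers. Prints the distribution of estimated shifts, which
should match the injected stage artifact."""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import SCRATCH, config  # noqa: E402

from tismorph import io  # noqa: E402
from tismorph.pipeline import stage_preprocess  # noqa: E402


def main():
    manifest = io.read_manifest(SCRATCH / "nlo_raw" / "manifest.csv")
    clean = stage_preprocess(config(), manifest, SCRATCH / "nlo_clean")
    print(f"preprocessed {len(clean)} FOVs -> {SCRATCH / 'nlo_clean'}")
    print("estimated serpentine shifts:")
    print(clean["estimated_shift_px"].value_counts().to_string())


if __name__ == "__main__":
    main()
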