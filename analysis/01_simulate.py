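"""Generate the synthetic control/TIS study: NLO FOVs and RI tomograms.

Emulates the acquisition design — per time point, 5 control and 5
treated plates with two 105 µm fields each (NLO), and 2 dishes per
condition with tomograms (QPI) — with known ground truth per file.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import SCRATCH, SEED, config  # noqa: E402

from tismorph.pipeline import stage_simulate  # noqa: E402


def main():
    manifests = stage_simulate(config(), SCRATCH, SEED)
    for name, manifest in manifests.items():
        by = manifest.groupby(["condition", "time_point"]).size()
        print(f"{name}: {len(manifest)} items -> {SCRATCH / (name + '_raw')}")
        print(by.to_string())


if __name__ == "__main__":
    main()
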