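"""QPI morphometrics per tomogram: volume, mean thickness, dry mass and
lipid content from the refractive-index grids.
Writes results/qpi_metrics.csv and prints condition means."""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, SCRATCH, config  # noqa: E402

from tismorph import io  # noqa: E402
from tismorph.pipeline import stage_quantify_qpi  # noqa: E402


def main():
    manifest = io.read_manifest(SCRATCH / "qpi_raw" / "manifest.csv")
    df = stage_quantify_qpi(config(), manifest, RESULTS / "qpi_metrics.csv")
    print(f"wrote {len(df)} rows -> {RESULTS / 'qpi_metrics.csv'}")
    cols = ["volume_um3", "mean_thickness_um", "dry_mass_pg",
            "lipid_volume_um3", "lipid_dry_mass_pg"]
    print(df.groupby(["condition", "time_point"])[cols].mean().round(2).to_string())


if __name__ == "__main__":
    main()
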