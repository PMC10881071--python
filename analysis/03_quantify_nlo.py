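"""Per-FOV NLO metrics: TPEF area fraction, aggregation index, mean
TPEF, SRS lipid area, quasi-single droplet size and cluster density.
Writes results/nlo_metrics.csv and prints condition means at 0 h / 7 d."""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, SCRATCH, config  # noqa: E402

from tismorph import io  # noqa: E402
from tismorph.pipeline import stage_quantify_nlo  # noqa: E402


def main():
    manifest = io.read_manifest(SCRATCH / "nlo_clean" / "manifest.csv")
    df = stage_quantify_nlo(config(), manifest, RESULTS / "nlo_metrics.csv")
    print(f"wrote {len(df)} rows -> {RESULTS / 'nlo_metrics.csv'}")
    cols = ["tpef_area_pct", "aggregation_index", "srs_area_pct",
            "mean_quasi_single_area_um2", "clusters_per_cell_area"]
    sel = df[df.time_point.isin(["0h", "7d"])]
    print(sel.groupby(["condition", "time_point"])[cols].mean().round(3).to_string())


if __name__ == "__main__":
    main()
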