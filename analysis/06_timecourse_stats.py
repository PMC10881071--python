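"""Time-course statistics: control vs TIS at each time point and each
time point vs the 0 h baseline, two-sided Mann-Whitney with star labels.
Writes results/{nlo,qpi}_tests.csv and _summary.csv and prints the
significant control-vs-TIS contrasts."""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from common import RESULTS, config  # noqa: E402

import pandas as pd  # noqa: E402

from tismorph.pipeline import (  # noqa: E402
    NLO_STAT_METRICS,
    QPI_STAT_METRICS,
    stage_stats,
)


def main():
    tables = {
        "nlo": (pd.read_csv(RESULTS / "nlo_metrics.csv"), NLO_STAT_METRICS),
        "qpi": (pd.read_csv(RESULTS / "qpi_metrics.csv"), QPI_STAT_METRICS),
    }
    out = stage_stats(config(), tables, RESULTS)
    for name, (tests, _) in out.items():
        sig = tests.query("comparison == 'control_vs_tis' and p_two_sided < 0.05")
        print(f"{name}: {len(tests)} tests, {len(sig)} significant control-vs-TIS:")
        print(sig[["metric", "time_point", "p_two_sided", "stars"]].to_string(index=False))


if __name__ == "__main__":
    main()
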