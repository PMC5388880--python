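#!/usr/bin/env python
"""Simulate the two bolus-tracking cohorts used throughout the analysis.

A healthy-like cohort (147 vessels, true network flow change +74%, vessel
reactivities 15/13/15%) and an impaired-like cohort (147 vessels, true
flow change -5.3%, reactivities 8.0/8.4/7.3%) are generated with full
ground truth and written as CSV manifests under results/cohorts/.
"""

from pathlib import Path

from neurovasc.io import write_bolus_cohort_csv
from neurovasc.synthetic import BolusCohortConfig, generate_bolus_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"

COHORTS = {
    "healthy": BolusCohortConfig(seed=101),
    "impaired": BolusCohortConfig(
        flow_change_true=-5.3,
        reactivity_true_by_type={"arteriole": 8.0, "capillary": 8.4, "venule": 7.3},
        genotype="TgF344-AD", seed=202),
}


def main() -> None:
    for name, cfg in COHORTS.items():
        pairs, truth = generate_bolus_cohort(cfg)
        manifest = write_bolus_cohort_csv(pairs, OUT / name, truth)
        print(f"{name}: {len(pairs)} vessel pairs "
              f"(true flow change {cfg.flow_change_true:+.1f}%) -> {manifest}")


if __name__ == "__main__":
    main()
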