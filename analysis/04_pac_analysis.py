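#!/usr/bin/env python
"""Theta-gamma coupling analysis of two simulated cohorts.

Simulates per-electrode LFPs for a strongly coupled cohort (m=0.7) and a
weakly coupled one (m=0.3), computes comodulograms (raw MI, surrogate z,
Bonferroni-corrected significance) and the cohort-level MI summary, and
writes results/pac_report.json.
"""

import json
from pathlib import Path

from neurovasc.pipeline import RunConfig, run_pac_experiment
from neurovasc.synthetic import PacSignalConfig

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(
        experiment="pac", seed=17, electrodes_per_cohort=2,
        pac_cohorts={
            "strong_coupling": PacSignalConfig(coupling_depth=0.7),
            "weak_coupling": PacSignalConfig(coupling_depth=0.3),
        })
    report = run_pac_experiment(cfg)
    for name, entry in report["cohorts"].items():
        sig = [e["n_significant"] for e in entry["electrodes"]]
        print(f"{name} (m={entry['coupling_depth_true']}): "
              f"significant cells per electrode {sig}")
    for row in report["cohort_summary"]:
        print(f"cohort {row['group']}: mean z {row['mean']:.2f} "
              f"+- {row['sem']:.2f} SEM over {row['n_electrodes']} electrodes")
    ROOT.mkdir(parents=True, exist_ok=True)
    out = ROOT / "pac_report.json"
    out.write_text(json.dumps(report, indent=2, default=str))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
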