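#!/usr/bin/env python
"""Fit the gamma-variate transit model to every simulated trace.

Reads the cohort manifests written by 01_simulate_cohorts.py, fits each
(vessel, condition) trace, and writes one row per fit (parameters, TTP,
RMSE, convergence) to results/fits_<cohort>.csv.  Non-converged vessels
are reported.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from neurovasc.bolus import fit_gamma_variate
from neurovasc.io import read_bolus_cohort_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for cohort_dir in sorted((ROOT / "cohorts").iterdir()):
        manifest = cohort_dir / "manifest.csv"
        if not manifest.exists():
            continue
        traces = read_bolus_cohort_csv(manifest)
        rows, n_bad = [], 0
        for tr in traces:
            fit = fit_gamma_variate(tr)
            n_bad += not fit.converged
            rows.append({"vessel_id": tr.vessel_id, "vessel_type": tr.vessel_type,
                         "condition": tr.condition, **dataclasses.asdict(fit)})
        out = ROOT / f"fits_{cohort_dir.name}.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        print(f"{cohort_dir.name}: fitted {len(rows)} traces "
              f"({n_bad} non-converged) -> {out}")


if __name__ == "__main__":
    main()
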