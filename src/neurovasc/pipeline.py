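"""End-to-end experiment orchestration.

Two chains mirror the quantitative arms of a neurovascular-dysfunction
experiment:

* **vascular**: simulate a bolus cohort -> fit every trace -> per-type and
  pooled reactivity summaries and Deming flow-change estimates, compared
  against the generative ground truth;
* **PAC**: simulate per-electrode LFPs for one or more cohorts ->
  preprocess -> comodulograms -> cohort MI summary.

Reports are plain dicts (JSON-serializable) embedding the exact stage
parameters, the global seed and a config hash, so a report is fully
auditable and a (config, seed) pair determines every number in it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import flow as flow_mod
from . import pac as pac_mod
from .bolus import fit_gamma_variate, vascular_reactivity
from .synthetic import (BolusCohortConfig, PacSignalConfig,
                        generate_bolus_cohort, generate_pac_signal)

__all__ = ["RunConfig", "run_vascular_experiment", "run_pac_experiment",
           "cohort_to_records"]

log = logging.getLogger("neurovasc")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    experiment: str = "vascular"
    seed: int = 0
    output_dir: str | None = None
    n_boot: int = 2000
    # vascular stage
    cohorts: Mapping[str, BolusCohortConfig] = field(default_factory=dict)
    # PAC stage
    pac_cohorts: Mapping[str, PacSignalConfig] = field(default_factory=dict)
    electrodes_per_cohort: int = 4
    n_surrogates: int = 50
    alpha: float = 0.05
    correction: str = "rayleigh"


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
    }


def cohort_to_records(pairs, truth=None) -> list[flow_mod.VesselRecord]:
    """Fit every trace pair and assemble vessel records with reactivities.

    Non-converged fits are logged and dropped.  ``truth`` (the generator's
    table) supplies animal/genotype assignments when present.
    """
    meta = {}
    if truth is not None:
        meta = truth.set_index("vessel_id")[["animal_id", "genotype"]].to_dict("index")
    records = []
    n_dropped = 0
    for tr_n, tr_h in pairs:
        fit_n = fit_gamma_variate(tr_n)
        fit_h = fit_gamma_variate(tr_h)
        if not (fit_n.converged and fit_h.converged):
            n_dropped += 1
            log.warning("vessel %s: non-converged fit, dropped", tr_n.vessel_id)
            continue
        m = meta.get(tr_n.vessel_id, {})
        records.append(flow_mod.VesselRecord(
            vessel_id=tr_n.vessel_id,
            animal_id=m.get("animal_id", "a0"),
            genotype=m.get("genotype", ""),
            vessel_type=tr_n.vessel_type,
            ttp_normo=fit_n.ttp, ttp_hyper=fit_h.ttp,
            reactivity=vascular_reactivity(fit_n.ttp, fit_h.ttp),
        ))
    if n_dropped:
        log.info("dropped %d vessels with non-converged fits", n_dropped)
    return records


def run_vascular_experiment(cfg: RunConfig) -> dict:
    """Simulate -> fit -> infer for each configured cohort.

    The report carries a reactivity table (mean +- SEM per genotype and
    vessel type), per-type and pooled flow-change estimates with bootstrap
    CIs, and the generative ground truth for comparison.
    """
    if not cfg.cohorts:
        raise ValueError("no cohorts configured")
    report: dict = {"experiment": cfg.experiment, "provenance": _provenance(cfg),
                    "cohorts": {}}
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.cohorts))
    all_records = []
    for child, (name, ccfg) in zip(children, cfg.cohorts.items()):
        ccfg = dataclasses.replace(ccfg, seed=int(child.generate_state(1)[0] % 2**31))
        log.info("cohort %s: simulating %s vessels",
                 name, sum(ccfg.n_vessels_per_type.values()))
        pairs, truth = generate_bolus_cohort(ccfg)
        records = cohort_to_records(pairs, truth)
        all_records.extend(records)
        entry: dict = {"n_vessels": len(records),
                       "flow_change_true": ccfg.flow_change_true,
                       "flow_change": {}}
        pooled = flow_mod.network_flow_change(
            records, n_boot=cfg.n_boot, seed=cfg.seed)
        entry["flow_change"]["ALL"] = {
            "estimate": pooled.flow_change, "slope": pooled.slope,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high, "n": pooled.n}
        for vtype in ccfg.n_vessels_per_type:
            sub = flow_mod.network_flow_change(
                records, vessel_filter=lambda r, v=vtype: r.vessel_type == v,
                n_boot=cfg.n_boot, seed=cfg.seed)
            entry["flow_change"][vtype] = {
                "estimate": sub.flow_change, "slope": sub.slope,
                "ci_low": sub.ci_low, "ci_high": sub.ci_high, "n": sub.n}
        report["cohorts"][name] = entry
    summary = flow_mod.group_summary(all_records)
    report["reactivity"] = summary.to_dict(orient="records")
    if cfg.output_dir:
        _write_report(report, cfg.output_dir, "vascular_report.json")
    return report


def run_pac_experiment(cfg: RunConfig) -> dict:
    """Simulate per-electrode LFPs, compute comodulograms, summarize cohorts."""
    if not cfg.pac_cohorts:
        raise ValueError("no PAC cohorts configured")
    report: dict = {"experiment": cfg.experiment, "provenance": _provenance(cfg),
                    "cohorts": {}}
    ss = np.random.SeedSequence(cfg.seed)
    comods_by_group: dict[str, list] = {}
    for name, pcfg in cfg.pac_cohorts.items():
        entries = []
        comods = []
        for e in range(cfg.electrodes_per_cohort):
            sig_child, surr_child = ss.spawn(2)
            ecfg = dataclasses.replace(
                pcfg, seed=int(sig_child.generate_state(1)[0] % 2**31))
            rec, _ = generate_pac_signal(ecfg)
            rec = pac_mod.preprocess(rec)
            com = pac_mod.comodulogram(
                rec, n_surrogates=cfg.n_surrogates, alpha=cfg.alpha,
                seed=int(surr_child.generate_state(1)[0] % 2**31),
                correction=cfg.correction)
            comods.append(com)
            entries.append({
                "electrode": e,
                "max_z": float(np.nanmax(com.z_mi)),
                "n_significant": int(com.significant.sum()),
                "raw_mi": com.raw_mi.tolist(),
                "z_mi": com.z_mi.tolist(),
                "significant": com.significant.astype(int).tolist(),
            })
        comods_by_group[name] = comods
        report["cohorts"][name] = {"electrodes": entries,
                                   "coupling_depth_true": pcfg.coupling_depth}
    summary = pac_mod.cohort_mi_summary(comods_by_group)
    report["cohort_summary"] = summary.to_dict(orient="records")
    if cfg.output_dir:
        _write_report(report, cfg.output_dir, "pac_report.json")
    return report


def _write_report(report: dict, outdir: str, fname: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / fname).write_text(json.dumps(report, indent=2, default=str))
    log.info("wrote %s", out / fname)
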