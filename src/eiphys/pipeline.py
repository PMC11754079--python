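"""End-to-end study orchestration: simulate, quantify, test, report.

``run_study`` composes the per-modality pipelines into a synthetic
two-genotype study shaped like the emulated experiments: an oscillating
E/I ratio in the wild type versus a flattened (or reversed) one in the
model line, minis at two time points, drug x time-of-day sIPSC charge,
multi-day sleep recordings and ocular-dominance imaging.  Every stage
writes a tidy CSV and appends its statistical decisions to a run log;
identical config + seed reproduces the bundle byte for byte.

The default problem sizes are scaled for a desk run (minutes, not the
weeks of recording the real study represents); every size is in the
config and can be raised.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import evoked_ei, intrinsic_imaging, io_formats, mini_events, \
    sipsc_charge, sleep_analysis, stats_battery, synthetic

DEFAULT_CONFIG: dict = {
    "stages": ["ei", "minis", "charge", "sleep", "imaging"],
    "ei": {
        "n_cells": 6,
        "zts": [0.0, 6.0, 12.0, 18.0],
        "i_max": 400.0,
        "noise_rms": 5.0,
        "cell_cv": 0.10,
        "cv_limit": 0.2,
        "min_run": 3,
        # genotype -> {phase -> true mean E/I}; "flip" reverses the model line
        "wt_ratio": {"dark": 0.60, "light": 0.40},
        "ko_ratio": {"dark": 0.50, "light": 0.50},
    },
    "minis": {
        "n_cells": 4,
        "duration": 60.0,
        "zts": [0.0, 12.0],
        "rate": {"WT": {0.0: 2.4, 12.0: 1.8}, "KO": {0.0: 2.0, 12.0: 2.0}},
        "amp_mean": 25.0,
        "n_events": 300,
    },
    "charge": {
        "n_cells": 5,
        "duration": 200.0,
        "rate": {"vehicle": {0.0: 14.0, 12.0: 8.0},
                 "WIN": {0.0: 6.0, 12.0: 6.0}},
    },
    "sleep": {
        "n_mice": 4,
        "n_days": 3,
        "epochs_per_day": 900,  # 1 h "days"; 21600 = real 24 h days
        "bin_hours": 0.5,
    },
    "imaging": {
        "n_mice": 4,
        "contra_peak": 1.0,
        "ipsi_peak": 0.5,
        "n_cycles": 6,
    },
}


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(config: dict, seed: int) -> str:
    payload = json.dumps({"config": config, "seed": seed}, sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_ei(cfg: dict, seed: int, log: List[str]) -> Dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    rows = []
    for geno, ratios in (("WT", cfg["wt_ratio"]), ("KO", cfg["ko_ratio"])):
        for zt in cfg["zts"]:
            phase = evoked_ei.PHASE_OF_ZT[float(zt)]
            for c in range(cfg["n_cells"]):
                true_r = ratios[phase] * rng.lognormal(0.0, cfg["cell_cv"])
                pairs, _ = synthetic.gen_evoked_series(
                    e_max=true_r * cfg["i_max"], i_max=cfg["i_max"],
                    noise_rms=cfg["noise_rms"],
                    seed=int(rng.integers(2 ** 31)))
                curve = evoked_ei.compute_ratio_curve(pairs)
                cell = evoked_ei.cell_ei_ratio(
                    curve, cv_limit=cfg["cv_limit"], min_run=cfg["min_run"],
                    zeitgeber_time=float(zt))
                rows.append({"cell_id": f"{geno}_zt{zt:g}_{c}",
                             "genotype": geno, "zt": zt, "phase": phase,
                             "circuit": cell.circuit, "ei_ratio": cell.value,
                             "n_intensities": cell.n_intensities_used})
    df = pd.DataFrame(rows)
    res = stats_battery.anova_two_way(df, "ei_ratio", "genotype", "phase")
    log.append("[ei] two-way ANOVA (genotype x phase, Type III): "
               f"interaction F({res.df[0]},{res.df[1]}) = "
               f"{res.statistic_value:.3f}, p = {res.p_value:.4g}")
    groups = {f"{g}@{p}": sub["ei_ratio"].to_numpy()
              for (g, p), sub in df.groupby(["genotype", "phase"])}
    ph = stats_battery.posthoc_holm_sidak(
        groups, [("WT@dark", "KO@dark"), ("WT@light", "KO@light")])
    for _, r in ph.iterrows():
        log.append(f"[ei] Holm-Sidak {r['contrast']}: t({r['df']:.0f}) = "
                   f"{r['t']:.3f}, adj p = {r['p_adj']:.4g}")
    stats = res.table.reset_index().rename(columns={"index": "effect"})
    return {"ei_cells": df, "ei_anova": stats, "ei_posthoc": ph}


def _stage_minis(cfg: dict, seed: int, log: List[str]) -> Dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed + 1)
    rows = []
    for geno, by_zt in cfg["rate"].items():
        for zt, rate in by_zt.items():
            for c in range(cfg["n_cells"]):
                rec, _ = synthetic.gen_mini_sweep(
                    rate=rate, amp_mean=cfg["amp_mean"],
                    duration=cfg["duration"],
                    seed=int(rng.integers(2 ** 31)),
                    meta={"cell_id": f"{geno}_zt{zt:g}_{c}"})
                s = mini_events.analyze_sweep(rec, "mEPSC",
                                              n_target=cfg["n_events"])
                rows.append({"cell_id": rec.meta["cell_id"], "genotype": geno,
                             "zt": float(zt), "frequency": s.frequency,
                             "amplitude": s.mean_amplitude,
                             "rms": s.rms_noise, "n": s.n_events_used,
                             "qc": s.qc_pass})
    df = pd.DataFrame(rows)
    for zt in sorted(df["zt"].unique()):
        g = {k: sub["frequency"].to_numpy()
             for k, sub in df[df["zt"] == zt].groupby("genotype")}
        names = sorted(g)
        branch, decisions = stats_battery.select_test(g)
        log.extend(f"[minis zt{zt:g}] {d}" for d in decisions)
        if branch == "parametric":
            r = stats_battery.t_test_unpaired(g[names[0]], g[names[1]])
            log.append(f"[minis zt{zt:g}] frequency {names[0]} vs {names[1]}: "
                       f"t({r.df[0]}) = {r.statistic_value:.3f}, "
                       f"p = {r.p_value:.4g}")
        else:
            r = stats_battery.mann_whitney(g[names[0]], g[names[1]])
            log.append(f"[minis zt{zt:g}] frequency {names[0]} vs {names[1]}: "
                       f"U = {r.statistic_value:g}, p = {r.p_value:.4g}")
    return {"mini_cells": df}


def _stage_charge(cfg: dict, seed: int, log: List[str]) -> Dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed + 2)
    rows = []
    for drug, by_zt in cfg["rate"].items():
        for zt, rate in by_zt.items():
            for c in range(cfg["n_cells"]):
                rec, _ = synthetic.gen_sipsc_sweep(
                    rate=rate, duration=cfg["duration"],
                    seed=int(rng.integers(2 ** 31)),
                    meta={"cell_id": f"{drug}_zt{zt:g}_{c}", "drug": drug})
                res = sipsc_charge.unit_charge(rec)
                rows.append({"cell_id": rec.meta["cell_id"], "drug": drug,
                             "zt": float(zt), "unit_charge": res.unit_charge,
                             "duration": res.duration_used})
    df = pd.DataFrame(rows)
    groups = {f"{d}@ZT{zt:g}": sub["unit_charge"].to_numpy()
              for (d, zt), sub in df.groupby(["drug", "zt"])}
    res = sipsc_charge.condition_contrast(groups)
    log.append(f"[charge] Kruskal-Wallis H = {res.statistic_value:.3f}, "
               f"df = {res.df[0]}, p = {res.p_value:.4g}")
    for _, r in res.posthoc.iterrows():
        log.append(f"[charge] Dunn {r['contrast']}: z = {r['z']:.3f}, "
                   f"adj p = {r['p_adj']:.4g}")
    return {"charge_cells": df, "charge_posthoc": res.posthoc}


def _stage_sleep(cfg: dict, seed: int, log: List[str]) -> Dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed + 3)
    arch_rows, spec_rows = [], []
    for geno in ("WT", "KO"):
        for m in range(cfg["n_mice"]):
            days = []
            for d in range(cfg["n_days"]):
                psg, _ = synthetic.gen_polysomnography(
                    n_days=1, epochs_per_day=cfg["epochs_per_day"],
                    seed=int(rng.integers(2 ** 31)),
                    animal_id=f"{geno}_{m}", genotype=geno)
                hyp = sleep_analysis.score_rule_based(psg)
                days.append(sleep_analysis.architecture(
                    hyp, bin_hours=cfg["bin_hours"]))
            avg = sleep_analysis.average_days(days, n_days=cfg["n_days"])
            for b, row in avg.percent_time.iterrows():
                for st, pct in row.items():
                    arch_rows.append({"animal_id": f"{geno}_{m}",
                                      "genotype": geno, "bin": b,
                                      "state": st, "percent_time": pct})
            prof = sleep_analysis.state_spectra(psg, hyp)
            for band in sleep_analysis.DEFAULT_BANDS:
                for st, frac in sleep_analysis.band_power(prof, band).items():
                    if frac is not None:
                        spec_rows.append({"animal_id": f"{geno}_{m}",
                                          "genotype": geno, "state": st,
                                          "band": band, "power_fraction": frac})
    arch = pd.DataFrame(arch_rows)
    spec = pd.DataFrame(spec_rows)
    wake = arch[arch["state"] == "WAKE"].copy()
    res = stats_battery.anova_two_way(wake, "percent_time", "genotype", "bin",
                                      repeated="bin", subject="animal_id")
    log.append("[sleep] wake% two-way RM ANOVA (genotype x bin): interaction "
               f"F({res.df[0]},{res.df[1]}) = {res.statistic_value:.3f}, "
               f"p = {res.p_value:.4g}")
    return {"sleep_architecture": arch, "sleep_spectra": spec}


def _stage_imaging(cfg: dict, seed: int, log: List[str]) -> Dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed + 4)
    rows = []
    for geno in ("WT", "KO"):
        for m in range(cfg["n_mice"]):
            truth = synthetic.make_imaging_truth(
                contra_peak=cfg["contra_peak"], ipsi_peak=cfg["ipsi_peak"])
            contra, ipsi = synthetic.gen_imaging_stack(
                truth, n_cycles=cfg["n_cycles"],
                seed=int(rng.integers(2 ** 31)))
            res = intrinsic_imaging.odi_pipeline(contra, ipsi)
            rows.append({"animal_id": f"{geno}_{m}", "genotype": geno,
                         "odi": res.odi,
                         "responsive_pixels": res.responsive_pixel_count})
    df = pd.DataFrame(rows)
    g = {k: sub["odi"].to_numpy() for k, sub in df.groupby("genotype")}
    r = stats_battery.t_test_unpaired(g["WT"], g["KO"])
    log.append(f"[imaging] ODI WT vs KO: t({r.df[0]}) = "
               f"{r.statistic_value:.3f}, p = {r.p_value:.4g}")
    return {"odi": df}


_STAGES = {"ei": _stage_ei, "minis": _stage_minis, "charge": _stage_charge,
           "sleep": _stage_sleep, "imaging": _stage_imaging}


def run_study(config: Optional[dict] = None, outdir="study_out",
              seed: int = 0) -> Dict[str, pd.DataFrame]:
    """Run the configured stages and write the report bundle.

    Outputs one CSV per table, ``stats_log.txt`` with every statistical
    decision, and ``config_used.yaml`` embedding the config hash and
    seed.  A stage failure aborts with a stage-named error; tables
    already written are retained.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: List[str] = [f"config_hash: {config_hash(cfg, seed)}", f"seed: {seed}"]
    tables: Dict[str, pd.DataFrame] = {}
    for stage in cfg["stages"]:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage: {stage!r}")
        try:
            out = _STAGES[stage](cfg[stage], seed, log)
        except Exception as exc:
            (outdir / "stats_log.txt").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
            tables[name] = df
    (outdir / "stats_log.txt").write_text("\n".join(log) + "\n")
    (outdir / "config_used.yaml").write_text(
        yaml.safe_dump({"config": cfg, "seed": seed,
                        "config_hash": config_hash(cfg, seed)}))
    return tables


def make_fixtures(seed: int = 0, outdir="fixtures") -> dict:
    """Write a small synthetic dataset covering every reader.

    Deterministic in ``seed``; ground truth is saved alongside as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_json: dict = {"seed": seed}

    recs = []
    mini_truths = []
    for i in range(3):
        rec, tr = synthetic.gen_mini_sweep(duration=30.0, seed=seed + i,
                                           meta={"cell_id": f"cell{i}"})
        recs.append(rec)
        mini_truths.append({"cell_id": f"cell{i}", "rate": tr.true_rate,
                            "n_events": int(tr.event_times.size)})
    io_formats.write_sweeps(recs, outdir / "mini_sweeps.h5")
    truth_json["minis"] = mini_truths

    rec, tr = synthetic.gen_sipsc_sweep(duration=200.0, seed=seed,
                                        meta={"cell_id": "sipsc0"})
    io_formats.write_sweeps([rec], outdir / "sipsc_sweeps.h5")
    truth_json["sipsc_total_charge_nAs"] = tr.total_charge

    psg, hyp = synthetic.gen_polysomnography(n_days=1, epochs_per_day=150,
                                             seed=seed, animal_id="m0")
    io_formats.write_polysomnography(psg, outdir / "psg.edf")
    io_formats.write_hypnogram(hyp, outdir / "hypnogram.tsv")

    truth = synthetic.make_imaging_truth(shape=(16, 16))
    contra, ipsi = synthetic.gen_imaging_stack(truth, n_cycles=4, seed=seed)
    io_formats.write_image_stack(contra, outdir / "contra.tif")
    io_formats.write_image_stack(ipsi, outdir / "ipsi.tif")
    truth_json["imaging_true_odi"] = truth.true_odi

    # clean reference series: no sub-threshold recruitment jitter, so the
    # plateau is unambiguous in a bundle meant for smoke tests and demos
    pairs, ev_truth = synthetic.gen_evoked_series(seed=seed,
                                                  threshold_jitter=0.0)
    ev_recs = []
    for p in pairs:
        for role, tr_ in (("excitatory", p.excitatory_trace),
                          ("inhibitory", p.inhibitory_trace)):
            tr_.meta.update({"intensity": p.intensity, "role": role,
                             "stim_onset": p.stim_onset, "cell_id": "ei0"})
            ev_recs.append(tr_)
    io_formats.write_sweeps(ev_recs, outdir / "evoked_sweeps.h5")
    truth_json["evoked_true_ratio"] = ev_truth.true_ratio

    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    return truth_json


def sweeps_to_pairs(recs) -> list:
    """Group evoked sweeps (meta: intensity, role, stim_onset) into
    :class:`~eiphys.evoked_ei.EvokedPair` objects."""
    by_intensity: dict = {}
    for r in recs:
        by_intensity.setdefault(float(r.meta["intensity"]), {})[
            r.meta["role"]] = r
    pairs = []
    for s in sorted(by_intensity):
        d = by_intensity[s]
        if "excitatory" not in d or "inhibitory" not in d:
            raise ValueError(f"intensity {s}: missing one holding potential")
        pairs.append(evoked_ei.EvokedPair(
            intensity=s, excitatory_trace=d["excitatory"],
            inhibitory_trace=d["inhibitory"],
            stim_onset=float(d["excitatory"].meta.get("stim_onset", 0.05))))
    return pairs
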