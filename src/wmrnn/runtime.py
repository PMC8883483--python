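"""Experiment orchestration: config, seeding, output files, summary report.

A run trains an ensemble of networks from a single YAML/dict config, records
their behavior, executes every unit-level analysis, and writes CSV/JSON/HDF5
artifacts to an output directory.  All randomness descends from one master
seed through named substreams (train / eval / analysis), so re-running the
same config reproduces every numeric output bitwise, and the config hash and
seed are embedded in each artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py

import numpy as np
import pandas as pd

from . import behavior, task_suite, trainer, unit_analysis
from .rnn_core import NetworkParams, run_batch
from .task_suite import RingCode

ANALYSIS_STREAM = 3_000_000  # substream tag offsets under the master seed


DEFAULT_CONFIG = {
    "seed": 0,
    "ensemble": 1,
    "tasks": "odr",              # "odr", "default", or explicit task list
    "delay_s": 1.5,
    "trainer": {"n_rec": 128, "max_steps": 3000, "batch_size": 64,
                "eta": 1e-3, "eval_every": 100, "eval_trials": 80,
                "delay_mode": "fixed"},
    "analysis": {"trials_per_loc": 40, "fano_trials": 16, "window_s": 1.0,
                 "min_trials": 8},
}


def merge_config(cfg: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def build_registry(cfg: dict):
    if cfg["tasks"] == "odr":
        return task_suite.odr_registry(cfg.get("delay_s", 1.5)), RingCode()
    if cfg["tasks"] == "default":
        return task_suite.default_registry(cfg.get("delay_s", 1.5)), RingCode()
    return task_suite.registry_from_config({"tasks": cfg["tasks"],
                                            "ring": cfg.get("ring", {})})


def _write_csv(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as f:
        f.write(f"# {header}\n")
        df.to_csv(f, index=False)


def train_ensemble(cfg: dict, out: Path) -> list[trainer.TrainResult]:
    """Train ``ensemble`` networks with seeds derived from the master seed."""
    registry, ring = build_registry(cfg)
    results = []
    for k in range(cfg["ensemble"]):
        tc = trainer.TrainConfig(seed=int(np.random.SeedSequence(
            [cfg["seed"], 7, k]).generate_state(1)[0] % (2 ** 31)),
            **cfg["trainer"])
        res = trainer.train(tc, registry, ring)
        trainer.checkpoint(res.params, trainer.adam_init(res.params),
                           res.record, out / f"checkpoint_{k}.h5",
                           step=int(res.record["step"].iloc[-1]), seed=tc.seed)
        _write_csv(res.record, out / f"train_record_{k}.csv",
                   f"config_hash={config_hash(cfg)} seed={cfg['seed']} network={k}")
        results.append(res)
    return results


def record_network(params: NetworkParams, cfg: dict, network: int):
    """Run the analysis trial battery through a trained network.

    Returns (ActivityRecord, behavior table) on a balanced batch of the first
    registry task with ``trials_per_loc`` repeats of each cue location.
    """
    registry, ring = build_registry(cfg)
    spec = registry[0]
    rng = np.random.default_rng([cfg["seed"], ANALYSIS_STREAM, network])
    batch = task_suite.analysis_batch(spec, cfg["analysis"]["trials_per_loc"],
                                      rng, ring, n_rules=len(registry))
    rec = run_batch(params, batch.inputs, rng, batch.meta)
    table = behavior.score_record(rec)
    return rec, table


def analyze_ensemble(cfg: dict, params_list: list[NetworkParams], out: Path) -> dict:
    """All unit-level analyses, pooled across the ensemble; writes tables."""
    w = cfg["analysis"]["window_s"]
    hdr = f"config_hash={config_hash(cfg)} seed={cfg['seed']}"
    tables, curves_r, curves_ff, cells_r, cells_ff = [], [], [], [], []
    pooled = (np.array([]), np.array([]))
    diag_stats = []
    n_delay_units = 0
    for k, params in enumerate(params_list):
        rec, table = record_network(params, cfg, k)
        table["network"] = k
        tables.append(table)
        sel = unit_analysis.select_delay_units(rec, window_s=None)
        n_delay_units += len(sel.units)
        if len(sel.units) == 0:
            continue
        corr = unit_analysis.rate_behavior_correlation(
            rec, table, sel.units, window_s=w,
            min_trials=cfg["analysis"]["min_trials"])
        ff = unit_analysis.fano_factor(rec, table, sel.units,
                                       n_trials=cfg["analysis"]["fano_trials"],
                                       window_s=w)
        contrast = unit_analysis.compare_correct_error(rec, table, sel.units,
                                                       window_s=w,
                                                       pooled=pooled)
        pooled = (contrast["correct_obs"], contrast["error_obs"])
        prof = unit_analysis.tuning_profile(rec, window_s=w,
                                            trials=table["correct"].to_numpy())
        try:
            mats, diag = unit_analysis.weight_structure(params,
                                                        prof.preferred_deg)
            diag_stats.append(diag)
        except ValueError:
            mats = None    # degenerate preference layout (immature network)
        heat = unit_analysis.heatmap_matrix(rec, sel.units, window_s=w)
        mode = "w" if k == 0 or not (out / "matrices.h5").exists() else "a"
        with h5py.File(out / "matrices.h5", mode) as f:
            f.attrs["config_hash"] = config_hash(cfg)
            f.attrs["seed"] = cfg["seed"]
            g = f.create_group(f"network_{k}")
            g.create_dataset("heatmap", data=heat)
            if mats is not None:
                for name, m in mats.items():
                    g.create_dataset(name + "_sorted", data=m)
        curves_r.append(corr.curve)
        curves_ff.append(ff.curve)
        cells_r.append(corr.per_cell)
        cells_ff.append(ff.per_cell)

    beh = pd.concat(tables, ignore_index=True)
    _write_csv(beh, out / "behavior.csv", hdr)

    summary = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
               "n_networks": len(params_list), "n_delay_units": n_delay_units,
               "percent_correct": float(100.0 * beh["correct"].mean())}
    if cells_r:
        all_r = np.vstack(cells_r)
        all_ff = np.vstack(cells_ff)
        rcells = all_r[np.isfinite(all_r)]
        from scipy import stats as _st
        tt = _st.ttest_1samp(rcells, 0.0) if len(rcells) > 1 else None
        try:
            F, dfb, dfw, p_anova = unit_analysis.anova_fano_by_location(all_ff)
            anova = {"F": F, "df": [dfb, dfw], "p": p_anova}
        except ValueError:
            anova = None   # too few defined Fano cells (immature network)
        offsets = (np.arange(all_r.shape[1]) - all_r.shape[1] // 2) * 45.0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _write_csv(pd.DataFrame({"offset_deg": offsets,
                                     "mean_r": np.nanmean(all_r, axis=0),
                                     "mean_fano": np.nanmean(all_ff, axis=0)}),
                       out / "rotated_curves.csv", hdr)
        ffcells = all_ff[np.isfinite(all_ff)]
        summary.update(
            mean_r=float(rcells.mean()) if len(rcells) else None,
            mean_r_t=float(tt.statistic) if tt else None,
            mean_r_p=float(tt.pvalue) if tt else None,
            mean_fano=float(ffcells.mean()) if len(ffcells) else None,
            fano_anova=anova,
            correct_error={k: (None if isinstance(v, float) and not np.isfinite(v)
                               else v)
                           for k, v in contrast.items()
                           if k in ("mean_correct", "mean_error", "n_correct",
                                    "n_error", "t", "p", "df")},
            weight_diagonality=[float(d) for d in diag_stats],
        )
    with open(out / "analysis.json", "w") as f:
        json.dump(summary, f, indent=2, default=float)
    return summary


def run_experiment(cfg: dict | None, out_dir) -> Path:
    """Train, record, and analyze an ensemble end to end.

    Writes checkpoints, training records, the pooled behavior table, rotated
    correlation/Fano curves, and ``analysis.json`` to ``out_dir``.  A status
    marker in ``config.json`` flags crashed runs as incomplete.
    """
    cfg = merge_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "config_hash": config_hash(cfg),
                "status": "incomplete"}
    with open(out / "config.json", "w") as f:
        json.dump(manifest, f, indent=2)
    results = train_ensemble(cfg, out)
    analyze_ensemble(cfg, [r.params for r in results], out)
    manifest["status"] = "complete"
    manifest["stages"] = [r.record["stage"].iloc[-1] for r in results]
    with open(out / "config.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return out


def report(out_dir) -> dict:
    """Schema-stable JSON summary of a completed run directory.

    Raises FileNotFoundError listing any missing artifact; values are read
    back from the files the run wrote (and therefore match them).
    """
    out = Path(out_dir)
    required = ["config.json", "analysis.json", "behavior.csv"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing artifacts in {out}: {missing}")
    with open(out / "config.json") as f:
        manifest = json.load(f)
    with open(out / "analysis.json") as f:
        analysis = json.load(f)
    perf = analysis.get("percent_correct")
    return {
        "status": manifest.get("status"),
        "config_hash": manifest.get("config_hash"),
        "stages": manifest.get("stages"),
        "percent_correct": perf,
        "stage": trainer.classify_stage(perf) if perf is not None else None,
        "mean_r": analysis.get("mean_r"),
        "mean_r_p": analysis.get("mean_r_p"),
        "mean_fano": analysis.get("mean_fano", "unavailable"),
        "fano_anova": analysis.get("fano_anova", "unavailable"),
        "correct_error": analysis.get("correct_error", "unavailable"),
        "weight_diagonality": analysis.get("weight_diagonality"),
    }
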