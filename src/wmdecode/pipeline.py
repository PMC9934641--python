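"""Seeded end-to-end orchestration: simulate -> preprocess -> decode -> stats.

`run_pipeline` executes the enabled stages in order on a TOML config,
writes tidy result tables, and records a manifest (config snapshot,
master seed, package version, SHA-256 of every result file) so a rerun
with the same config and seed reproduces hash-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig, load_config
from .decode import decode_timeavg_all, temporal_generalization
from .exceptions import ConfigurationError
from .preprocess import apply_exclusions, preprocess_subject
from .stats import (
    age_regression,
    paired_sensory_delay,
    permutation_test,
    sensory_delay_correlation,
    ttest_vs_chance,
)
from .synth import SessionConfig, SignalModel, simulate_cohort, synthesize_subject, SubjectSpec

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "decode", "tempgen", "stats")

FIXTURES = {
    "null_cohort": dict(
        n_subjects=5,
        session=dict(n_trials_per_category=30, fs_raw_hz=250.0),
        signal=dict(amp_sensory=0.0, artifact_rate=0.0),
    ),
    "strong_signal": dict(
        n_subjects=1,
        session=dict(n_trials_per_category=60, fs_raw_hz=250.0),
        signal=dict(amp_sensory=30.0, noise_sd=10.0, subject_snr_sd=0.0, artifact_rate=0.0),
    ),
    "rotating_pattern": dict(
        n_subjects=1,
        session=dict(n_trials_per_category=60, fs_raw_hz=250.0),
        signal=dict(
            amp_sensory=30.0,
            noise_sd=10.0,
            subject_snr_sd=0.0,
            artifact_rate=0.0,
            rotate_at_offset=True,
            delay_decay_tau_ms=1e9,
        ),
    ),
    "artifact_heavy": dict(
        n_subjects=2,
        session=dict(n_trials_per_category=30, fs_raw_hz=250.0),
        signal=dict(artifact_rate=0.4),
    ),
}

__all__ = ["run_pipeline", "make_fixture", "STAGES", "FIXTURES"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _windows_for(cfg: RunConfig) -> dict[str, tuple[float, float]]:
    w0 = cfg.preprocess.epoch_window_ms[0]
    sens = float(cfg.session.sensory_ms)
    delay_end = sens + float(cfg.session.delay_ms)
    return {"Baseline": (w0, 0.0), "Sensory": (0.0, sens), "Delay": (sens, delay_end)}


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    n_subjects: int | None = None,
    stage: str = "stats",
    write_raw: bool = True,
) -> dict:
    """Run the pipeline through ``stage`` (inclusive) and return the manifest.

    ``seed`` / ``n_subjects`` override the config's cohort section.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg = load_config(config_path)
    if seed is not None:
        cfg.seed = int(seed)
    if n_subjects is not None:
        cfg.n_subjects = int(n_subjects)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    last = STAGES.index(stage)
    result_files: list[Path] = []
    logger.info("run_pipeline: seed=%d, n_subjects=%d, stage<=%s", cfg.seed, cfg.n_subjects, stage)

    # --- simulate -----------------------------------------------------
    cohort = simulate_cohort(
        cfg.n_subjects,
        cfg.session,
        cfg.signal,
        age_effect=cfg.age_effect,
        seed=cfg.seed,
        age_range_months=cfg.age_range_months,
    )
    sim_dir = out / "subjects"
    for sub in cohort:
        if write_raw:
            io.save_subject(sim_dir, sub)
        else:
            sim_dir.mkdir(parents=True, exist_ok=True)
            io.save_events_tsv(sim_dir / f"{sub.subject.subject_id}_events.tsv", sub.trials)
    logger.info("simulate: %d subjects, %d trials each", len(cohort), len(cohort[0].trials))

    epochsets = None
    if last >= STAGES.index("preprocess"):
        scored = []
        rej_rows = []
        for sub in cohort:
            ep, rej_log, acc = preprocess_subject(sub, cfg.preprocess)
            scored.append((ep, acc))
            rej_log = rej_log.assign(subject_id=sub.subject.subject_id)
            rej_rows.append(rej_log)
            logger.info(
                "preprocess: %s kept %d trials (accuracy %.2f)",
                sub.subject.subject_id, ep.n_trials, acc,
            )
        epochsets, report = apply_exclusions(scored, cfg.preprocess)
        epo_dir = out / "epochs"
        epo_dir.mkdir(parents=True, exist_ok=True)
        for ep in epochsets:
            io.save_epochs(epo_dir / ep.subject_meta.subject_id, ep)
        rej_path = out / "rejection_log.csv"
        pd.concat(rej_rows, ignore_index=True).to_csv(rej_path, index=False)
        rep_path = out / "exclusion_report.csv"
        report.to_csv(rep_path, index=False)
        result_files += [rej_path, rep_path]

    results = None
    windows = _windows_for(cfg)
    if last >= STAGES.index("decode"):
        rows = []
        results = []
        for i, ep in enumerate(epochsets):
            cv = replace(cfg.cv, seed=cfg.seed + 1000 + i)
            res = decode_timeavg_all(ep, cv, windows=windows)
            results.append(res)
            for wname, r in res.items():
                for it, acc in enumerate(r.per_iteration_accuracy):
                    rows.append(
                        {
                            "subject_id": ep.subject_meta.subject_id,
                            "analysis": "timeavg",
                            "window": wname,
                            "iteration": it,
                            "accuracy": acc,
                        }
                    )
        acc_path = out / "accuracy_long.csv"
        pd.DataFrame(rows).to_csv(acc_path, index=False, float_format="%.6f")
        result_files.append(acc_path)
        # grand confusion matrices
        for wname in windows:
            grand = sum(r[wname].confusion for r in results) / len(results)
            p = out / f"confusion_{wname}.csv"
            grand.to_csv(p, float_format="%.6f")
            result_files.append(p)

    if last >= STAGES.index("tempgen") and cfg.run_tempgen:
        for i, ep in enumerate(epochsets):
            cv = replace(cfg.cv, seed=cfg.seed + 2000 + i)
            gm = temporal_generalization(ep, cfg.bin_width_ms, cv)
            p = out / f"tempgen_{ep.subject_meta.subject_id}.csv"
            gm.to_frame().to_csv(p, float_format="%.6f")
            result_files.append(p)

    if last >= STAGES.index("stats") and results is not None:
        means = {
            w: np.array([r[w].mean_accuracy for r in results]) for w in windows
        }
        n_tests = len(windows) if cfg.correction == "bonferroni" else 1
        stats_rows = [
            dataclasses.asdict(ttest_vs_chance(means[w], n_tests=n_tests, test_name=w))
            for w in windows
        ]
        summary = {
            "n_subjects_analyzed": len(results),
            "mean_accuracy": {w: float(means[w].mean()) for w in windows},
        }
        if "Sensory" in windows and "Delay" in windows:
            paired = paired_sensory_delay(means["Sensory"], means["Delay"])
            stats_rows.append(dataclasses.asdict(paired))
            if len(results) >= 3:
                r, pval = sensory_delay_correlation(means["Sensory"], means["Delay"])
                summary["sensory_delay_pearson"] = {"r": r, "p": pval}
        ages = np.array([ep.subject_meta.age_months for ep in epochsets])
        if len(set(ages.tolist())) > 1 and len(ages) >= 3:
            summary["age_regression"] = {
                w: age_regression(ages, means[w], window=w) for w in windows
            }
        if cfg.n_permutations > 0:
            perm_cv = replace(
                cfg.cv, n_iterations=cfg.permutation_cv_iterations, seed=cfg.seed + 77
            )
            perm = permutation_test(
                epochsets,
                windows["Sensory"],
                n_perm=cfg.n_permutations,
                seed=cfg.seed + 88,
                cv=perm_cv,
            )
            summary["permutation_sensory"] = {
                "observed": perm.observed_group_stat,
                "p_perm": perm.p_perm,
                "n_permutations": perm.n_permutations,
                "cv_iterations_used": perm.cv_iterations_used,
            }
        stats_path = out / "group_stats.csv"
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False, float_format="%.8g")
        sum_path = out / "summary.json"
        sum_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        result_files += [stats_path, sum_path]

    manifest = {
        "package": "wmdecode",
        "version": __version__,
        "config_path": str(config_path),
        "config_snapshot": Path(config_path).read_text(),
        "master_seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "stage": stage,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "result_hashes": {p.name: _sha256(p) for p in result_files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_fixture(name: str, out_dir: str | Path, seed: int = 0) -> list[dict]:
    """Write one of the documented deterministic test datasets.

    Known fixtures: null_cohort, strong_signal, rotating_pattern,
    artifact_heavy.  Returns the per-subject file maps.
    """
    if name not in FIXTURES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; options: {sorted(FIXTURES)}"
        )
    spec = FIXTURES[name]
    session = SessionConfig(**spec["session"])
    signal = SignalModel(**spec["signal"])
    out = Path(out_dir) / name
    paths = []
    for i in range(spec["n_subjects"]):
        sub = synthesize_subject(
            session,
            signal,
            SubjectSpec(subject_id=f"sub-{i + 1:03d}"),
            seed=seed + i,
        )
        paths.append(io.save_subject(out, sub))
    return paths
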