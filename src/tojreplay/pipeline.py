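"""End-to-end orchestration: filter -> label -> LATER -> RSA -> GLM -> metrics.

The pipeline consumes either a trial-table CSV or a synthetic-generator
configuration, runs the full analysis chain and writes tidy tables, JSON
summaries and plot-ready data to an output directory, together with a
manifest recording the configuration hash, seed and library versions so
any stage can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, TojReplayError
from .later import LaterModel
from .metrics import (
    clip_rt_contrast,
    compression_factor,
    inverse_efficiency,
    rt_span_from_table,
    sliding_accuracy,
    trial_type_anova,
)
from .regression import polynomial_trend_test, slope_test
from .rsa import ReplayRSA
from .synthetic import DesignSpec, GeneratorParams, generate_cohort
from .trial_data import TrialTable, filter_rt, load_trials, write_trials

log = logging.getLogger("tojreplay.pipeline")

DEFAULT_SEGMENTS = (8,)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _get_table(config: dict, seed: int | None) -> TrialTable:
    if "input" in config and config["input"]:
        return load_trials(config["input"])
    if "generator" in config or "design" in config:
        spec = DesignSpec(**config.get("design", {}))
        params = GeneratorParams(**config.get("generator", {}))
        n_subjects = int(config.get("subjects", 6))
        if seed is None:
            seed = params.seed
        return generate_cohort(n_subjects, spec, params, seed=seed)
    raise ConfigError("config must provide 'input' (CSV path) or a 'generator'/'design' section")


def run_pipeline(
    config: dict,
    out_dir,
    seed: int | None = None,
    segments=DEFAULT_SEGMENTS,
) -> dict:
    """Run all analysis stages; returns the manifest dictionary.

    A failing stage halts the pipeline with the stage named; outputs from
    completed stages are retained on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "segments": list(segments),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    timings = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except TojReplayError:
                raise
            except Exception as exc:  # annotate which stage broke
                raise TojReplayError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.2fs", name, timings[name])
            manifest["stages"][name] = {"seconds": timings[name]}
            return result

        return wrap

    table = stage("load")(lambda: _get_table(config, seed))
    write_trials(table, out / "trials_raw.csv")

    table = stage("filter")(lambda: filter_rt(table))
    write_trials(table, out / "trials_filtered.csv")

    def _later():
        comparison = LaterModel.from_table(table).fit()
        comparison.to_json(out / "later_comparison.json")
        return comparison

    later_cmp = stage("later")(_later)

    def _rsa():
        results = {}
        for n_seg in segments:
            rsa = ReplayRSA(table, n_segments=n_seg)
            fit = rsa.fit(n_iter=int(config.get("rsa_iterations", 100)), seed=seed)
            results[n_seg] = fit
            fit.vs_zero_table().to_csv(out / f"rsa_{n_seg}seg_models.csv", index=False)
            fit.pairwise_table().to_csv(out / f"rsa_{n_seg}seg_contrasts.csv", index=False)
            rsa.data_rdm().to_text(out / f"rdm_data_{n_seg}seg.txt")
            rsa.offset_sweep().to_csv(out / f"rsa_{n_seg}seg_offset_sweep.csv", index=False)
        return results

    rsa_fits = stage("rsa")(_rsa)

    def _glm():
        slopes = slope_test(table)
        slopes.to_csv(out / "slopes_by_subject.csv", index=False)
        trends = polynomial_trend_test(table)
        trends.to_csv(out / "polynomial_trends.csv", index=False)
        return slopes, trends

    slopes, trends = stage("glm")(_glm)

    def _metrics():
        span = rt_span_from_table(table)
        scan, factor = compression_factor(span)
        contrast = clip_rt_contrast(table)
        anova = trial_type_anova(table)
        ies = inverse_efficiency(table)
        sliding_accuracy(table).to_csv(out / "sliding_accuracy.csv", index=False)
        sliding_accuracy(table, measure="promptness").to_csv(
            out / "sliding_promptness.csv", index=False
        )
        summary = {
            "rt_span_s": span,
            "scan_ms_per_video_s": scan,
            "compression_factor": factor,
            "clip_contrast": {
                "mean_rt_clip1": contrast.mean_rt_clip1,
                "mean_rt_clip2": contrast.mean_rt_clip2,
                "t": contrast.t,
                "df": contrast.df,
                "p_one_tailed": contrast.p,
                "cohens_d": contrast.cohens_d,
                "ci_upper": contrast.ci_upper,
            },
            "trial_type_anova": {k: v for k, v in anova.items() if k != "excluded_subjects"},
            "inverse_efficiency_anova": {
                "F": ies["F"], "df": [ies["df_between"], ies["df_within"]], "p": ies["p"],
            },
            "overall_accuracy_pct": 100.0 * float(table.df["correct"].mean()),
        }
        (out / "metrics.json").write_text(json.dumps(summary, indent=2))
        ies["ies"].to_csv(out / "inverse_efficiency.csv", index=False)
        return summary

    metrics_summary = stage("metrics")(_metrics)

    manifest["winning_later_variant"] = later_cmp.best_variant
    manifest["rsa_best_model"] = {
        n: max(fit.mean_r, key=fit.mean_r.get) for n, fit in rsa_fits.items()
    }
    manifest["n_trials"] = len(table)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
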