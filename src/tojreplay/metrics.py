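"""Derived behavioral statistics for TOJ replay analyses.

Compression factor (how much faster replay runs than perception), the
clip-1 vs clip-2 reaction-time contrast, the trial-type ANOVA, sliding-
window accuracy/promptness curves and inverse efficiency scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .trial_data import TrialTable, add_derived_columns

__all__ = [
    "compression_factor",
    "rt_span_from_table",
    "clip_rt_contrast",
    "ClipContrast",
    "trial_type_anova",
    "sliding_accuracy",
    "inverse_efficiency",
]

#: Nominal video duration (s) used for compression arithmetic: the design mean
#: of two 4-6 s clips.
NOMINAL_VIDEO_DURATION_S = 10.0


def compression_factor(
    rt_span_s: float, video_duration_s: float = NOMINAL_VIDEO_DURATION_S
) -> tuple[float, float]:
    """Replay scan rate and compression factor from a first-to-last RT span.

    ``rt_span_s`` is the RT difference between choosing the very first and
    the very last frame of the video (estimated from the fitted linear RT /
    chosen-frame-location relationship, or supplied directly).  Returns
    ``(scan_ms_per_s, factor)`` where ``scan = 1000 * span / duration`` is
    milliseconds of replay per second of video and ``factor = duration /
    span``; a factor above 1 means replay runs faster than perception.
    """
    if not rt_span_s > 0:
        raise ValueError("rt_span_s must be > 0 (no forward compression interpretable)")
    scan_ms_per_s = 1000.0 * rt_span_s / video_duration_s
    factor = video_duration_s / rt_span_s
    return scan_ms_per_s, factor


def rt_span_from_table(table: TrialTable) -> float:
    """First-to-last-frame RT span from a linear fit of RT on chosen location.

    Chosen-frame location is normalized to [0, 1], so the fitted slope *is*
    the span in seconds.  Uses within-context trials.
    """
    df = add_derived_columns(table.df)
    df = df.loc[df["boundary_condition"] != "across"]
    slope, _ = np.polyfit(df["chosen_location"].to_numpy(), df["rt_s"].to_numpy(), 1)
    return float(slope)


@dataclass
class ClipContrast:
    """Paired clip-1 vs clip-2 RT contrast over subjects."""

    mean_rt_clip1: float
    mean_rt_clip2: float
    t: float
    df: int
    p: float  # one-tailed, alternative clip1 < clip2
    cohens_d: float
    ci_upper: float  # one-sided 95% CI upper bound on the mean difference
    per_subject: pd.DataFrame
    excluded_subjects: list
    log_rt: "ClipContrast | None" = None


def _paired_onetailed(diffs: np.ndarray) -> tuple[float, int, float, float, float]:
    n = diffs.size
    if n < 2:
        raise InsufficientDataError("need >= 2 subjects for a paired contrast")
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    df = n - 1
    if sd == 0:  # all paired differences identical
        if mean == 0:
            return 0.0, df, 0.5, 0.0, 0.0
        t = -np.inf if mean < 0 else np.inf
        return float(t), df, (0.0 if mean < 0 else 1.0), float(np.sign(mean) * np.inf), float(mean)
    se = sd / np.sqrt(n)
    t = mean / se
    p = stats.t.cdf(t, df)  # alternative: mean difference < 0
    d = mean / sd
    ci_upper = mean + stats.t.ppf(0.95, df) * se
    return float(t), df, float(p), float(d), float(ci_upper)


def _oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """scipy one-way ANOVA with the zero-variance corner cases defined."""
    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_within == 0:
        return (0.0, 1.0) if np.isclose(ss_between, 0) else (np.inf, 0.0)
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def clip_rt_contrast(table: TrialTable, with_log: bool = True) -> ClipContrast:
    """Do clip-1 frames come back faster than clip-2 frames?

    Within-context trials grouped by the chosen frame's clip; per-subject
    mean RTs enter a one-tailed paired t-test (alternative: clip1 < clip2)
    with Cohen's d and a one-sided CI.  A log(RT) variant is attached.
    Subjects lacking trials in either clip are excluded and listed.
    """
    df = add_derived_columns(table.df)
    df = df.loc[df["boundary_condition"] != "across"]
    per = df.groupby(["subject_id", "chosen_clip"])["rt_s"].mean().unstack("chosen_clip")
    excluded = per.index[per.isna().any(axis=1)].tolist()
    per = per.dropna()
    diffs = (per[1] - per[2]).to_numpy()
    t, dof, p, d, ci = _paired_onetailed(diffs)
    log_part = None
    if with_log:
        per_log = (
            df.assign(log_rt=np.log(df["rt_s"]))
            .groupby(["subject_id", "chosen_clip"])["log_rt"]
            .mean()
            .unstack("chosen_clip")
            .dropna()
        )
        ld = (per_log[1] - per_log[2]).to_numpy()
        lt, ldof, lp, lds, lci = _paired_onetailed(ld)
        log_part = ClipContrast(
            float(per_log[1].mean()), float(per_log[2].mean()), lt, ldof, lp, lds, lci,
            per_log.reset_index(), excluded,
        )
    return ClipContrast(
        float(per[1].mean()), float(per[2].mean()), t, dof, p, d, ci,
        per.reset_index(), excluded, log_part,
    )


def trial_type_anova(table: TrialTable) -> dict:
    """One-way ANOVA of subject-level mean RT over the three trial types.

    Groups are across / within_clip1 / within_clip2 subject means laid out
    as between cells, so 6 subjects x 3 conditions gives df = (2, 15).
    Subjects missing a condition are excluded (listed in the result).
    """
    df = table.df
    per = df.groupby(["subject_id", "boundary_condition"])["rt_s"].mean().unstack()
    excluded = per.index[per.isna().any(axis=1)].tolist()
    per = per.dropna()
    if len(per) < 2:
        raise InsufficientDataError("need >= 2 subjects with all three conditions")
    groups = [per[c].to_numpy() for c in ("across", "within_clip1", "within_clip2")]
    f, p = _oneway(groups)
    k, n = len(groups), sum(len(g) for g in groups)
    return {
        "F": float(f),
        "df_between": k - 1,
        "df_within": n - k,
        "p": float(p),
        "group_means": {c: float(per[c].mean()) for c in per.columns},
        "excluded_subjects": excluded,
    }


def sliding_accuracy(
    table: TrialTable,
    window_frames: int = 25,
    step_frames: int = 1,
    measure: str = "accuracy",
) -> pd.DataFrame:
    """Sliding-window curves over frame location.

    ``measure='accuracy'`` averages correctness by *target* (earlier probe)
    frame location; ``measure='promptness'`` averages reciprocal latency by
    *chosen* frame location.  Returns a frame-indexed DataFrame with window
    centre, mean, n, the 0.5 chance level and the mean boundary location;
    empty windows yield NaN (gaps are not interpolated).
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    df = table.df
    if measure == "accuracy":
        loc = df["probe_early_frame"].to_numpy()
        val = df["correct"].to_numpy(dtype=float)
    elif measure == "promptness":
        loc = df["chosen_frame"].to_numpy()
        val = 1.0 / df["rt_s"].to_numpy()
    else:
        raise ValueError("measure must be 'accuracy' or 'promptness'")
    lo, hi = int(loc.min()), int(loc.max())
    half = window_frames / 2.0
    centers = np.arange(lo, hi + 1, step_frames)
    means = np.full(centers.shape, np.nan)
    ns = np.zeros(centers.shape, dtype=int)
    for i, c in enumerate(centers):
        mask = (loc >= c - half) & (loc <= c + half)
        ns[i] = int(mask.sum())
        if ns[i]:
            means[i] = val[mask].mean()
    out = pd.DataFrame({"center_frame": centers, "mean": means, "n": ns})
    out.attrs["chance"] = 0.5
    out.attrs["mean_boundary_frame"] = float(df["boundary_frame"].mean())
    return out


def inverse_efficiency(table: TrialTable, n_segments: int = 4) -> dict:
    """Inverse efficiency score (IES) per video segment, with a one-way ANOVA.

    Each clip is split into ``n_segments // 2`` equal parts by *target*
    frame location (two per clip by default); IES = mean RT (ms) / percent
    correct (0-100 scale) per segment per subject.  The ANOVA treats
    subject x segment cells as independent groups, so 6 subjects x 4
    segments gives df = (3, 20).  Zero-accuracy segments yield NaN IES and
    are flagged.
    """
    if n_segments % 2:
        raise ValueError("n_segments must be even (segments split within clips)")
    per_clip = n_segments // 2
    df = table.df
    tgt = df["probe_early_frame"].to_numpy()
    bnd = df["boundary_frame"].to_numpy()
    nfr = df["n_frames"].to_numpy()
    in_clip2 = tgt >= bnd
    frac = np.where(in_clip2, (tgt - bnd) / (nfr - bnd), tgt / bnd)
    seg_in_clip = np.minimum((frac * per_clip).astype(int), per_clip - 1)
    segment = seg_in_clip + per_clip * in_clip2 + 1  # 1..n_segments
    work = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "segment": segment,
            "rt_ms": df["rt_s"] * 1000.0,
            "correct": df["correct"].astype(float),
        }
    )
    agg = work.groupby(["subject_id", "segment"]).agg(
        rt_ms=("rt_ms", "mean"), pct_correct=("correct", lambda v: 100.0 * v.mean())
    )
    agg["ies"] = np.where(agg["pct_correct"] > 0, agg["rt_ms"] / agg["pct_correct"], np.nan)
    flagged = agg.index[agg["pct_correct"] == 0].tolist()
    wide = agg["ies"].unstack("segment")
    complete = wide.dropna()
    groups = [complete[s].to_numpy() for s in sorted(complete.columns)]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        f, p = _oneway(groups)
    else:  # too few cells for an ANOVA; per-cell scores still returned
        f, p = np.nan, np.nan
    k, n = len(groups), sum(len(g) for g in groups)
    return {
        "ies": agg.reset_index(),
        "F": float(f),
        "df_between": k - 1,
        "df_within": n - k,
        "p": float(p),
        "undefined_cells": flagged,
    }
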