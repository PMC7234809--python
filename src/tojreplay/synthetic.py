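"""Synthetic TOJ trial generator with a replay-based latency mechanism.

The generator reproduces the factorial structure of the behavioral study it
emulates — 50 daily sessions of 100 trials crossing Boundary (within vs.
across the clip junction), Play order (forward vs. reverse), Temporal
distance (25 levels, 25 frames + 3 frames per step at 25 fps) and Exposure
(5 repetitions; 2 in the human variant) — and draws reaction times from a
rise-to-threshold ("LATER"-style) promptness process whose mean latency
scans forward through the encoded video at a compressed rate:

    mean_rt = t0 + scan_rate * t(chosen frame) + replay_offset * [chosen in Clip 2]

With ``replay_offset = 0`` the agent replays the video strictly forward; a
negative offset models skipping (globally compressing) Clip 1 when the
probes sit in Clip 2.  A full reset, ``replay_offset = -scan_rate *
clip1_duration``, makes the first frame of Clip 2 as fast as the first
frame of Clip 1.

Choices come from a chance-floored logistic in temporal similarity and the
across-context indicator.  This choice rule is synthetic scaffolding shaped
only to reproduce the qualitative accuracy pattern (better across-context,
worse near TS -> 1); it is not a claim about any animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import DesignInfeasibleError
from .trial_data import RETENTION_DELAY_S, TRIAL_COLUMNS, TrialTable

__all__ = [
    "DesignSpec",
    "GeneratorParams",
    "build_design",
    "replay_mean_rt",
    "simulate_rt",
    "simulate_choice",
    "generate_dataset",
    "generate_cohort",
    "drop_sessions",
    "offset_seconds",
    "HUMAN_SPEC",
]

#: Promptness draws at or below this rate (s^-1) are rejected and redrawn,
#: guaranteeing finite positive RTs (<= 20 s) with negligible tail distortion
#: relative to the 0.7-10 s analysis window.
MIN_PROMPTNESS = 0.05

#: Dead time between trials not spent watching/responding (reward, feedback,
#: self-paced start); only used to give elapsed_time_s a realistic scale.
_TRIAL_OVERHEAD_S = 9.0


@dataclass
class DesignSpec:
    """Factorial design of a TOJ session series.

    Defaults reproduce the macaque protocol: ``50 sessions x 100 trials``
    crossing 2 (boundary) x 2 (play order) x 25 (temporal distance) x 5
    (exposure).  The human variant (see :data:`HUMAN_SPEC`) runs 20 sessions
    with 2 exposures, i.e. 2000 trials.
    """

    n_sessions: int = 50
    trials_per_session: int = 100
    exposures: int = 5
    td_levels: int = 25
    td_min_frames: int = 25
    td_step_frames: int = 3
    frame_rate_hz: float = 25.0
    clip_len_range_s: tuple[float, float] = (4.0, 6.0)
    boundary_levels: tuple[str, ...] = ("within", "across")
    play_orders: tuple[str, ...] = ("forward", "reverse")
    categories: tuple[str, ...] = ("primate", "nonprimate")

    def __post_init__(self) -> None:
        if self.n_sessions % self.exposures:
            raise ValueError("n_sessions must divide evenly into exposure blocks")
        if self.clip_len_range_s[0] > self.clip_len_range_s[1]:
            raise ValueError("clip_len_range_s must be (lo, hi) with lo <= hi")

    @property
    def td_max_frames(self) -> int:
        return self.td_min_frames + self.td_step_frames * (self.td_levels - 1)

    @property
    def total_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    def td_frames(self, level) -> np.ndarray:
        """Probe separation in frames for TD level(s) 1..td_levels."""
        return self.td_min_frames + self.td_step_frames * (np.asarray(level) - 1)


#: Human-style variant: 20 sessions, 2 exposures -> 2000 trials.
HUMAN_SPEC = DesignSpec(n_sessions=20, exposures=2)


@dataclass
class GeneratorParams:
    """Parameters of the replay + rise-to-threshold generative mechanism.

    ``scan_rate_s_per_s`` is replay time per second of encoded video (the
    compression-defining slope; 0.0942 corresponds to scanning each second of
    video in 94.2 ms).  ``replay_offset_s`` shifts Clip-2 latencies (0 =
    strict forward; negative = partial/global compression of Clip 1).
    ``t0_s`` is the non-replay base latency.  ``promptness_sd`` is the SD of
    the Gaussian promptness (1/RT) noise and ``context_rate_gain`` the
    additive promptness-mean increase on across-context trials (boundary
    facilitation of the rate of rise).  ``choice_*`` are the chance-floored
    logistic accuracy coefficients.
    """

    replay_offset_s: float = 0.0
    scan_rate_s_per_s: float = 0.0942
    t0_s: float = 0.9
    promptness_sd: float = 0.15
    context_rate_gain: float = 0.10
    choice_intercept: float = 0.2
    choice_ts_weight: float = 1.5
    choice_across_weight: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.scan_rate_s_per_s > 0:
            raise ValueError("scan_rate_s_per_s must be > 0")
        if not self.promptness_sd > 0:
            raise ValueError("promptness_sd must be > 0")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def build_design(spec: DesignSpec = DesignSpec(), seed=None, subject_id: str = "S1") -> TrialTable:
    """Lay out the balanced factorial design and per-trial video geometry.

    The four factors are fully crossed and balanced within each exposure
    block; trials are permuted (seeded) into sessions, mimicking blocked
    exposure scheduling.  Probe frames are placed uniformly subject to each
    trial's TD level and boundary condition; clip lengths are uniform on
    ``clip_len_range_s``.  Choice and RT columns are left unset (``chosen_frame
    = -1``, ``rt_s = NaN``): :func:`generate_dataset` fills them in.
    """
    rng = _as_rng(seed)
    sessions_per_block = spec.n_sessions // spec.exposures
    block_trials = sessions_per_block * spec.trials_per_session

    cells = [
        (b, p, td)
        for b in spec.boundary_levels
        for p in spec.play_orders
        for td in range(1, spec.td_levels + 1)
    ]
    n_cells = len(cells)

    frames = []
    for block in range(spec.exposures):
        reps, extra = divmod(block_trials, n_cells)
        idx = np.repeat(np.arange(n_cells), reps)
        if extra:
            idx = np.concatenate([idx, rng.choice(n_cells, size=extra, replace=False)])
        rng.shuffle(idx)
        b = np.array([cells[i][0] for i in idx])
        p = np.array([cells[i][1] for i in idx])
        td = np.array([cells[i][2] for i in idx])
        session_in_block = np.arange(block_trials) // spec.trials_per_session
        # alternate category lists across sessions within the block
        cat_of_session = np.array(
            [spec.categories[s % len(spec.categories)] for s in range(sessions_per_block)]
        )
        frames.append(
            pd.DataFrame(
                {
                    "session_index": block * sessions_per_block + session_in_block + 1,
                    "trial_index": np.arange(block_trials) % spec.trials_per_session + 1,
                    "boundary_level": b,
                    "play_order": p,
                    "td_level": td,
                    "exposure": block + 1,
                    "category": cat_of_session[session_in_block],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    n = len(df)

    td_frames = spec.td_frames(df["td_level"].to_numpy())
    lo, hi = spec.clip_len_range_s
    rate = spec.frame_rate_hz

    c1 = np.empty(n)
    c2 = np.empty(n)
    early = np.full(n, -1, dtype=np.int64)
    pending = np.arange(n)
    is_across = (df["boundary_level"] == "across").to_numpy()
    which_clip = rng.integers(1, 3, size=n)  # clip used by within trials

    for _attempt in range(20):
        if pending.size == 0:
            break
        m = pending.size
        c1[pending] = rng.uniform(lo, hi, size=m)
        c2[pending] = rng.uniform(lo, hi, size=m)
        b_frames = np.round(c1[pending] * rate).astype(np.int64)
        n_frames = np.round((c1[pending] + c2[pending]) * rate).astype(np.int64)
        td = td_frames[pending]
        acr = is_across[pending]
        clip1 = ~acr & (which_clip[pending] == 1)
        clip2 = ~acr & (which_clip[pending] == 2)
        start = np.where(clip2, b_frames, 0)
        end = np.where(clip1, b_frames, n_frames)  # across: any early < b works, cap later
        # feasible early range:
        #   within:  [start, end - td)  so that late stays inside the clip
        #   across:  [b - td, b)        so that early < b <= late < n_frames
        lo_e = np.where(acr, b_frames - td, start)
        hi_e = np.where(acr, b_frames, end - td)
        hi_e = np.minimum(hi_e, n_frames - td)  # late = early + td <= n_frames - 1 + 1
        lo_e = np.maximum(lo_e, 0)
        feasible = hi_e > lo_e
        draw = lo_e + np.floor(rng.random(m) * (hi_e - lo_e)).astype(np.int64)
        early[pending[feasible]] = draw[feasible]
        pending = pending[~feasible]
    if pending.size:
        i = int(pending[0])
        raise DesignInfeasibleError(
            f"could not place probes for trial row {i} "
            f"(td_level={df['td_level'].iloc[i]}, boundary={df['boundary_level'].iloc[i]})"
        )

    boundary_frame = np.round(c1 * rate).astype(np.int64)
    n_frames = np.round((c1 + c2) * rate).astype(np.int64)
    late = early + td_frames
    cond = np.where(
        (early < boundary_frame) & (boundary_frame <= late),
        "across",
        np.where(late < boundary_frame, "within_clip1", "within_clip2"),
    )

    duration = n_frames / rate
    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_index": df["session_index"],
            "trial_index": df["trial_index"],
            "video_duration_s": duration,
            "boundary_frame": boundary_frame,
            "n_frames": n_frames,
            "frame_rate_hz": rate,
            "probe_early_frame": early,
            "probe_late_frame": late,
            "chosen_frame": np.int64(-1),
            "correct": False,
            "rt_s": np.nan,
            "boundary_condition": cond,
            "play_order": df["play_order"],
            "td_level": df["td_level"],
            "exposure": df["exposure"],
            "category": df["category"],
            "touch_side": "left",
            "elapsed_time_s": 0.0,
        }
    )
    # elapsed time accumulates video + delay + overhead within each session
    per_trial = pd.Series(duration + RETENTION_DELAY_S + _TRIAL_OVERHEAD_S, index=out.index)
    out["elapsed_time_s"] = per_trial.groupby(out["session_index"]).cumsum() - per_trial
    return TrialTable(out[TRIAL_COLUMNS])


def replay_mean_rt(
    chosen_frame, boundary_frame, frame_rate_hz, params: GeneratorParams
):
    """Mean latency of the replay mechanism for the chosen frame.

    ``t0 + scan_rate * t(chosen) + replay_offset * [chosen >= boundary]``.
    Strictly increasing in chosen-frame time within a clip.
    """
    t_chosen = np.asarray(chosen_frame) / np.asarray(frame_rate_hz)
    in_clip2 = np.asarray(chosen_frame) >= np.asarray(boundary_frame)
    mean = params.t0_s + params.scan_rate_s_per_s * t_chosen + params.replay_offset_s * in_clip2
    if np.any(np.asarray(mean) <= 0):
        raise ValueError("replay parameters produce non-positive mean RT (offset too negative)")
    return mean


def simulate_rt(mean_rt, params: GeneratorParams, rng, across=False):
    """Draw reaction times from the Gaussian-promptness (LATER-style) process.

    Promptness ``p ~ Normal(1/mean_rt + context_rate_gain * across,
    promptness_sd)`` is rejected-and-redrawn until ``p > 0.05 s^-1``; the
    returned RT is ``1/p``.
    """
    mean_rt = np.atleast_1d(np.asarray(mean_rt, dtype=float))
    if np.any(mean_rt <= 0):
        raise ValueError("mean_rt must be > 0")
    across = np.broadcast_to(np.atleast_1d(across), mean_rt.shape)
    mu = 1.0 / mean_rt + params.context_rate_gain * across
    p = rng.normal(mu, params.promptness_sd)
    bad = p <= MIN_PROMPTNESS
    while np.any(bad):
        p[bad] = rng.normal(mu[bad], params.promptness_sd)
        bad = p <= MIN_PROMPTNESS
    return 1.0 / p


def simulate_choice(ts, across, params: GeneratorParams, rng):
    """Bernoulli correctness from the chance-floored logistic accuracy rule.

    ``P(correct) = clip(logistic(c0 + c1 * (1 - TS) + c2 * across), 0.5, 1)``
    — the agent is never below chance, accuracy degrades as temporal
    similarity approaches one and improves across a context boundary.
    """
    ts = np.asarray(ts, dtype=float)
    across = np.asarray(across)
    p = expit(
        params.choice_intercept
        + params.choice_ts_weight * (1.0 - ts)
        + params.choice_across_weight * across
    )
    p = np.clip(p, 0.5, 1.0)
    return rng.random(ts.shape) < p


def generate_dataset(
    spec: DesignSpec = DesignSpec(),
    params: GeneratorParams = GeneratorParams(),
    seed=None,
    subject_id: str = "S1",
) -> TrialTable:
    """Build a design and fill in choices and reaction times.

    Deterministic for a fixed seed.  The returned table passes all trial
    invariants and is ready for the analysis pipeline.
    """
    if seed is None:
        seed = params.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    design_rng, choice_rng, rt_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    table = build_design(spec, seed=design_rng, subject_id=subject_id)
    df = table.df
    rate = df["frame_rate_hz"].to_numpy()
    test_time = df["video_duration_s"].to_numpy() + RETENTION_DELAY_S
    delay1 = test_time - df["probe_early_frame"].to_numpy() / rate
    delay2 = test_time - df["probe_late_frame"].to_numpy() / rate
    ts = delay2 / delay1
    across = (df["boundary_condition"] == "across").to_numpy()

    correct = simulate_choice(ts, across, params, choice_rng)
    chosen = np.where(correct, df["probe_early_frame"], df["probe_late_frame"])
    mean_rt = replay_mean_rt(chosen, df["boundary_frame"].to_numpy(), rate, params)
    rt = simulate_rt(mean_rt, params, rt_rng, across=across)

    df = df.copy()
    df["chosen_frame"] = chosen.astype(np.int64)
    df["correct"] = correct
    df["rt_s"] = rt
    df["touch_side"] = np.where(choice_rng.random(len(df)) < 0.5, "left", "right")
    return TrialTable(df, list(table.filter_log))


def generate_cohort(
    n_subjects: int,
    spec: DesignSpec = DesignSpec(),
    params: GeneratorParams = GeneratorParams(),
    seed=None,
    subject_prefix: str = "M",
) -> TrialTable:
    """Independent subjects from the same generator, concatenated into one table."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    tables = [
        generate_dataset(spec, params, seed=child, subject_id=f"{subject_prefix}{i + 1}")
        for i, child in enumerate(children)
    ]
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return TrialTable(df)


def drop_sessions(table: TrialTable, sessions: Sequence[int]) -> TrialTable:
    """Remove whole sessions (e.g. lost to apparatus failure), with a log entry."""
    from .trial_data import FilterRecord

    n = len(table)
    mask = ~table.df["session_index"].isin(list(sessions))
    kept = table.df.loc[mask].reset_index(drop=True)
    log = list(table.filter_log)
    removed = n - len(kept)
    log.append(FilterRecord(f"sessions_dropped:{sorted(set(sessions))}", removed, removed / n if n else 0.0))
    return TrialTable(kept, log)


def offset_seconds(
    offset_slope_units: float,
    params: GeneratorParams,
    spec: DesignSpec = DesignSpec(),
    n_segments: int = 8,
) -> float:
    """Convert a model-family offset (slope units per segment) to seconds.

    One slope unit is the mean RT increment across one video segment,
    ``scan_rate * mean_video_duration / n_segments``.  Used to generate data
    at a grid offset of the hypothetical replay-model family.
    """
    mean_duration = sum(spec.clip_len_range_s)  # two clips, mean of uniform = midpoint
    return offset_slope_units * params.scan_rate_s_per_s * mean_duration / n_segments


def spec_params_to_dict(spec: DesignSpec, params: GeneratorParams) -> dict:
    """JSON/YAML-serializable configuration of a generator run."""
    return {"design": asdict(spec), "generator": asdict(params)}
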