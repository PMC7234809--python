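"""Trial-level data model for temporal-order-judgement (TOJ) experiments.

A *trial* is one judgement: the subject watched a two-clip video (8-12 s,
two 4-6 s clips joined at a context boundary), waited through a retention
delay, and then chose which of two probe frames appeared earlier.  This
module defines the trial schema, delimited-text I/O, the reaction-time
exclusion filter, condition labelling (within clip 1 / within clip 2 /
across the boundary) and the temporal-similarity index used as a
discriminability regressor.

Tables are held as :class:`pandas.DataFrame` objects wrapped in a
:class:`TrialTable` that records the provenance of applied filters.
Frame indices are 0-based internally; I/O offers a ``one_based`` flag for
interoperating with ordinal-numbered exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateTrialError,
    InvariantViolation,
    RowParseError,
    SchemaError,
)

__all__ = [
    "Trial",
    "TrialTable",
    "FilterRecord",
    "TRIAL_COLUMNS",
    "load_trials",
    "write_trials",
    "filter_rt",
    "label_condition",
    "label_conditions",
    "temporal_similarity",
    "add_derived_columns",
]

BOUNDARY_CONDITIONS = ("within_clip1", "within_clip2", "across")
PLAY_ORDERS = ("forward", "reverse")
CATEGORIES = ("primate", "nonprimate")
TOUCH_SIDES = ("left", "right")

#: Canonical column order for delimited-text trial tables.
TRIAL_COLUMNS = [
    "subject_id",
    "session_index",
    "trial_index",
    "video_duration_s",
    "boundary_frame",
    "n_frames",
    "frame_rate_hz",
    "probe_early_frame",
    "probe_late_frame",
    "chosen_frame",
    "correct",
    "rt_s",
    "boundary_condition",
    "play_order",
    "td_level",
    "exposure",
    "category",
    "touch_side",
    "elapsed_time_s",
]

_FRAME_COLUMNS = ("boundary_frame", "probe_early_frame", "probe_late_frame", "chosen_frame")

#: Retention delay between video offset and the order judgement (seconds).
RETENTION_DELAY_S = 2.0


@dataclass
class Trial:
    """A single temporal-order-judgement trial.

    Frame indices are 0-based.  ``boundary_frame`` is the first frame of
    Clip 2.  ``correct`` is true iff the chosen probe is the earlier one.
    """

    subject_id: str
    session_index: int
    trial_index: int
    video_duration_s: float
    boundary_frame: int
    n_frames: int
    frame_rate_hz: float
    probe_early_frame: int
    probe_late_frame: int
    chosen_frame: int
    correct: bool
    rt_s: float
    boundary_condition: str
    play_order: str
    td_level: int
    exposure: int
    category: str
    touch_side: str
    elapsed_time_s: float

    def validate(self) -> list[str]:
        """Return a list of invariant-violation messages (empty when valid)."""
        errs: list[str] = []
        if not (0 <= self.probe_early_frame < self.probe_late_frame < self.n_frames):
            errs.append(
                f"probe frames ({self.probe_early_frame}, {self.probe_late_frame}) "
                f"must satisfy 0 <= early < late < n_frames ({self.n_frames})"
            )
        expected = int(round(self.video_duration_s * self.frame_rate_hz))
        if self.n_frames != expected:
            errs.append(f"n_frames {self.n_frames} != round(duration * rate) = {expected}")
        is_across = self.probe_early_frame < self.boundary_frame <= self.probe_late_frame
        if (self.boundary_condition == "across") != is_across:
            errs.append(
                f"boundary_condition '{self.boundary_condition}' inconsistent with "
                f"probes ({self.probe_early_frame}, {self.probe_late_frame}) vs "
                f"boundary {self.boundary_frame}"
            )
        if self.chosen_frame not in (self.probe_early_frame, self.probe_late_frame):
            errs.append(f"chosen_frame {self.chosen_frame} is not one of the probes")
        if bool(self.correct) != (self.chosen_frame == self.probe_early_frame):
            errs.append("correct flag inconsistent with chosen_frame")
        if not self.rt_s > 0:
            errs.append(f"rt_s must be > 0 (got {self.rt_s})")
        if self.boundary_condition not in BOUNDARY_CONDITIONS:
            errs.append(f"unknown boundary_condition '{self.boundary_condition}'")
        if self.play_order not in PLAY_ORDERS:
            errs.append(f"unknown play_order '{self.play_order}'")
        return errs


@dataclass
class FilterRecord:
    """Provenance entry for one applied exclusion rule."""

    rule: str
    n_removed: int
    fraction_removed: float


@dataclass
class TrialTable:
    """Ordered collection of trials plus a log of applied filters."""

    df: pd.DataFrame
    filter_log: list[FilterRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(missing)
        self.df = self.df.reset_index(drop=True)

    def iter_trials(self) -> Iterator[Trial]:
        for row in self.df.itertuples(index=False):
            yield Trial(**{c: getattr(row, c) for c in TRIAL_COLUMNS})

    def validate(self) -> None:
        """Check every trial's invariants; raise :class:`InvariantViolation` listing rows."""
        violations: list[tuple[int, str]] = []
        for i, trial in enumerate(self.iter_trials()):
            for msg in trial.validate():
                violations.append((i, msg))
        if violations:
            raise InvariantViolation(violations)

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.df["subject_id"]))

    def subset(self, mask) -> "TrialTable":
        """Row subset sharing this table's filter log (log is copied, not extended)."""
        return TrialTable(self.df.loc[mask].reset_index(drop=True), list(self.filter_log))

    def within_context(self) -> "TrialTable":
        return self.subset(self.df["boundary_condition"] != "across")

    def across_context(self) -> "TrialTable":
        return self.subset(self.df["boundary_condition"] == "across")


def _coerce_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        raise RowParseError(column, np.flatnonzero(bad.to_numpy()).tolist())
    return coerced


def load_trials(path, one_based: bool = False, validate: bool = True) -> TrialTable:
    """Read a delimited-text (CSV, ``.`` decimal, UTF-8) trial table.

    Parameters
    ----------
    path : str or Path
        CSV file with a header naming all trial fields.
    one_based : bool
        If true, frame-index columns in the file are 1-based ordinals and are
        shifted to the package's 0-based convention on read.
    validate : bool
        Check per-row trial invariants and raise :class:`InvariantViolation`
        naming offending rows.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    df = df[TRIAL_COLUMNS].copy()
    for col in ("rt_s", "video_duration_s", "frame_rate_hz", "elapsed_time_s"):
        df[col] = _coerce_numeric(df, col)
    for col in _FRAME_COLUMNS + ("n_frames", "session_index", "trial_index", "td_level", "exposure"):
        df[col] = _coerce_numeric(df, col).astype(np.int64)
    if one_based:
        for col in _FRAME_COLUMNS:
            df[col] = df[col] - 1
    df["correct"] = df["correct"].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    table = TrialTable(df)
    sidecar = Path(path).with_suffix(".filters.json")
    if sidecar.exists():
        entries = json.loads(sidecar.read_text())
        table.filter_log = [FilterRecord(**e) for e in entries]
    if validate:
        table.validate()
    return table


def write_trials(table: TrialTable, path, one_based: bool = False) -> None:
    """Write a trial table as CSV plus a ``.filters.json`` sidecar with the filter log."""
    df = table.df[TRIAL_COLUMNS].copy()
    if one_based:
        for col in _FRAME_COLUMNS:
            df[col] = df[col] + 1
    df.to_csv(path, index=False, encoding="utf-8")
    sidecar = Path(path).with_suffix(".filters.json")
    sidecar.write_text(json.dumps([asdict(r) for r in table.filter_log], indent=2))


def filter_rt(table: TrialTable, lo_s: float = 0.7, hi_s: float = 10.0) -> TrialTable:
    """Exclude implausibly fast and slow responses.

    Retains trials with ``lo_s <= rt_s <= hi_s`` (bounds inclusive).  Appends
    two provenance entries, ``rt_slow`` (rt > hi) and ``rt_fast`` (rt < lo),
    with counts and fractions relative to the input size.  Defaults follow
    the convention of dropping responses slower than 10 s or faster than
    0.7 s.  Idempotent.
    """
    if not lo_s < hi_s:
        raise ValueError(f"lo_s ({lo_s}) must be < hi_s ({hi_s})")
    n = len(table)
    rt = table.df["rt_s"]
    slow = rt > hi_s
    fast = rt < lo_s
    kept = table.df.loc[~(slow | fast)].reset_index(drop=True)
    log = list(table.filter_log)
    for rule, removed in (("rt_slow", int(slow.sum())), ("rt_fast", int(fast.sum()))):
        log.append(FilterRecord(rule, removed, removed / n if n else 0.0))
    return TrialTable(kept, log)


def label_condition(trial: Trial) -> str:
    """Classify a trial by where its probes sit relative to the clip boundary.

    ``across`` iff the boundary lies strictly after the early probe and at or
    before the late probe; ``within_clip1`` iff both probes precede the
    boundary; ``within_clip2`` otherwise.
    """
    if trial.probe_early_frame == trial.probe_late_frame:
        raise DegenerateTrialError("probe frames are equal; condition undefined")
    if trial.probe_early_frame < trial.boundary_frame <= trial.probe_late_frame:
        return "across"
    if trial.probe_late_frame < trial.boundary_frame:
        return "within_clip1"
    return "within_clip2"


def label_conditions(df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`label_condition` over a trial DataFrame."""
    early, late, bnd = (df[c].to_numpy() for c in ("probe_early_frame", "probe_late_frame", "boundary_frame"))
    if np.any(early == late):
        raise DegenerateTrialError("probe frames are equal in at least one row")
    out = np.where(
        (early < bnd) & (bnd <= late),
        "across",
        np.where(late < bnd, "within_clip1", "within_clip2"),
    )
    return pd.Series(out, index=df.index, name="boundary_condition")


def temporal_similarity(trial: Trial, test_time_s: float | None = None) -> float:
    """Temporal similarity (TS) of the two probe frames at test.

    TS = delay2 / delay1 where delay_i is the retention interval between a
    probe frame's occurrence in the video and the moment of testing
    (delay2 < delay1, so TS is strictly inside (0, 1)).  The closer TS is to
    one, the harder the two memory traces are to discriminate.

    ``test_time_s`` is measured from video onset; by default the judgement is
    taken to occur at ``video_duration_s + 2 s`` (the retention delay).
    """
    if trial.probe_early_frame == trial.probe_late_frame:
        raise DegenerateTrialError("equal probe frames: temporal similarity undefined")
    if test_time_s is None:
        test_time_s = trial.video_duration_s + RETENTION_DELAY_S
    t_early = trial.probe_early_frame / trial.frame_rate_hz
    t_late = trial.probe_late_frame / trial.frame_rate_hz
    if test_time_s <= t_late:
        raise ValueError(
            f"test_time_s ({test_time_s}) must fall strictly after both probes (late at {t_late})"
        )
    return (test_time_s - t_late) / (test_time_s - t_early)


def chosen_frame_location(df: pd.DataFrame) -> pd.Series:
    """Chosen-frame location normalized to [0, 1] (frame / (n_frames - 1)).

    Normalization makes slopes comparable across 8-12 s videos.
    """
    return df["chosen_frame"] / (df["n_frames"] - 1)


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the derived regressor columns used downstream.

    Adds ``chosen_location`` and ``target_location`` (normalized to [0, 1]),
    ``temporal_similarity``, ``td_s`` (probe separation, seconds),
    ``chosen_clip`` (1 or 2) and ``across`` (0/1 indicator).
    """
    out = df.copy()
    out["chosen_location"] = chosen_frame_location(df)
    out["target_location"] = df["probe_early_frame"] / (df["n_frames"] - 1)
    rate = df["frame_rate_hz"]
    test_time = df["video_duration_s"] + RETENTION_DELAY_S
    delay1 = test_time - df["probe_early_frame"] / rate
    delay2 = test_time - df["probe_late_frame"] / rate
    out["temporal_similarity"] = delay2 / delay1
    out["td_s"] = (df["probe_late_frame"] - df["probe_early_frame"]) / rate
    out["chosen_clip"] = np.where(df["chosen_frame"] >= df["boundary_frame"], 2, 1)
    out["across"] = (df["boundary_condition"] == "across").astype(int)
    return out
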