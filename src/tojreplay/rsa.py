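"""Reaction-time representational similarity analysis (RSA) of replay models.

Within-context trials are binned into equal-width video segments by
chosen-frame location; the per-segment mean RTs define a representational
dissimilarity matrix (RDM) whose entries are pairwise distances between
segment means, rank-transformed and linearly scaled to [0, 1].  Data RDMs
are compared against a parametric family of hypothetical replay models,

    value(i) = slope * i + offset * slope * [i >= boundary_segment],

whose ``offset`` (in slope units) spans a symmetric grid from the
full-reset Global-compression model (offset = -(boundary_segment - 1)) to
its mirror image, with the Strict-forward model (offset = 0) at the
centre.  Model fit is the Spearman correlation between model and
group-averaged data RDMs over bootstrap iterations (trials resampled with
replacement within subject); paired model contrasts use the two-sided
Wilcoxon signed-rank test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptySegmentError
from .trial_data import TrialTable, chosen_frame_location

__all__ = [
    "SegmentProfile",
    "RDM",
    "ReplayModelSpec",
    "segment_profile",
    "rdm_from_profile",
    "model_rt_pattern",
    "model_rdm",
    "offset_model_family",
    "spearman_model_fit",
    "compare_models",
    "fdr_adjust",
    "ReplayRSA",
    "RSAResults",
    "strict_forward_spec",
    "global_compression_spec",
]

DEFAULT_N_SEGMENTS = 8
DEFAULT_BOUNDARY_SEGMENT = 5  # first Clip-2 segment when 8 segments span two equal clips


@dataclass
class SegmentProfile:
    """Per-segment mean RT and trial counts for one subject/table."""

    means: np.ndarray
    counts: np.ndarray
    subject_id: str | None = None

    @property
    def n_segments(self) -> int:
        return len(self.means)


@dataclass
class RDM:
    """Symmetric rank-scaled dissimilarity matrix (zero diagonal, [0,1] off-diagonal)."""

    values: np.ndarray
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_text(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.6f")


@dataclass
class ReplayModelSpec:
    """Hypothetical replay RT pattern: constant slope plus a Clip-2 offset.

    ``offset`` is expressed in slope units (one unit = the RT increment per
    segment); ``offset = -(boundary_segment - 1)`` is the full-reset
    Global-compression model and ``offset = 0`` the Strict-forward model.
    """

    slope: float = 1.0
    offset: float = 0.0
    boundary_segment: int = DEFAULT_BOUNDARY_SEGMENT

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not 2 <= self.boundary_segment:
            raise ValueError("boundary_segment must be >= 2")


def strict_forward_spec(boundary_segment: int = DEFAULT_BOUNDARY_SEGMENT) -> ReplayModelSpec:
    return ReplayModelSpec(offset=0.0, boundary_segment=boundary_segment)


def global_compression_spec(boundary_segment: int = DEFAULT_BOUNDARY_SEGMENT) -> ReplayModelSpec:
    return ReplayModelSpec(offset=-(boundary_segment - 1), boundary_segment=boundary_segment)


def _locations_bins(df: pd.DataFrame, n_segments: int) -> np.ndarray:
    loc = chosen_frame_location(df).to_numpy()
    return np.minimum((loc * n_segments).astype(int), n_segments - 1)


def segment_profile(table: TrialTable, n_segments: int = DEFAULT_N_SEGMENTS) -> SegmentProfile:
    """Mean RT per equal-width chosen-frame-location segment (within-context trials).

    Raises :class:`EmptySegmentError` naming the first empty bin; callers may
    retry with fewer segments (8, 10 and 14 are the conventional choices).
    """
    df = table.df
    df = df.loc[df["boundary_condition"] != "across"]
    bins = _locations_bins(df, n_segments)
    counts = np.bincount(bins, minlength=n_segments)
    if np.any(counts == 0):
        raise EmptySegmentError(int(np.flatnonzero(counts == 0)[0]), n_segments)
    sums = np.bincount(bins, weights=df["rt_s"].to_numpy(), minlength=n_segments)
    subj = df["subject_id"].iloc[0] if df["subject_id"].nunique() == 1 else None
    return SegmentProfile(sums / counts, counts, subject_id=subj)


def _rank_scale_offdiag(dist: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rank-transform the upper triangle (average ranks for ties), scale to [0,1]."""
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = dist[iu]
    ranks = stats.rankdata(vals, method="average")
    span = ranks.max() - ranks.min()
    degenerate = span == 0
    scaled = np.full_like(ranks, 0.5) if degenerate else (ranks - ranks.min()) / span
    out = np.zeros_like(dist, dtype=float)
    out[iu] = scaled
    out = out + out.T
    return out, bool(degenerate)


def rdm_from_profile(profile) -> RDM:
    """RDM of pairwise distances between segment mean RTs.

    For scalar segment means the Euclidean distance reduces to the absolute
    difference ``|mean_i - mean_j|``.  Off-diagonal entries are replaced by
    their rank in the distribution of all (upper-triangle) entries and
    linearly scaled to [0, 1]; an all-tied matrix maps to 0.5 everywhere
    with the ``degenerate`` flag set.
    """
    means = np.asarray(profile.means if isinstance(profile, SegmentProfile) else profile, dtype=float)
    dist = np.abs(means[:, None] - means[None, :])
    values, degenerate = _rank_scale_offdiag(dist)
    return RDM(values, degenerate)


def model_rt_pattern(spec: ReplayModelSpec, n_segments: int = DEFAULT_N_SEGMENTS) -> np.ndarray:
    """Hypothetical per-segment RT values for a replay model spec."""
    i = np.arange(1, n_segments + 1, dtype=float)
    return spec.slope * i + spec.offset * spec.slope * (i >= spec.boundary_segment)


def model_rdm(spec: ReplayModelSpec, n_segments: int = DEFAULT_N_SEGMENTS) -> RDM:
    return rdm_from_profile(model_rt_pattern(spec, n_segments))


def offset_model_family(
    n_models: int = 11,
    n_segments: int = DEFAULT_N_SEGMENTS,
    boundary_segment: int = DEFAULT_BOUNDARY_SEGMENT,
    slope: float = 1.0,
) -> list[tuple[ReplayModelSpec, RDM]]:
    """The symmetric offset grid of hypothetical replay models.

    Offsets run uniformly from ``-(boundary_segment - 1)`` (full reset,
    Global compression) through 0 (Strict forward, the centre model) to
    ``+(boundary_segment - 1)``; ``n_models`` must be odd so the zero-offset
    model sits exactly in the middle (model 6 of 11 by default).
    """
    if n_models % 2 == 0:
        raise ValueError("n_models must be odd so that offset 0 is the centre model")
    extreme = float(boundary_segment - 1)
    offsets = np.linspace(-extreme, extreme, n_models)
    offsets[(n_models - 1) // 2] = 0.0  # exact centre
    out = []
    for off in offsets:
        spec = ReplayModelSpec(slope=slope, offset=float(off), boundary_segment=boundary_segment)
        out.append((spec, model_rdm(spec, n_segments)))
    return out


def _spearman_upper(rdm_a: RDM, rdm_b: RDM) -> float:
    r, _ = stats.spearmanr(rdm_a.upper(), rdm_b.upper())
    return float(r)


def _group_rdm_bootstrap(subject_data, n_segments, rng):
    """One bootstrap draw: within-subject trial resample -> averaged group RDM.

    Returns None if any subject's resample leaves a segment empty.
    """
    rdms = []
    for bins, rts in subject_data:
        idx = rng.integers(0, len(rts), size=len(rts))
        b = bins[idx]
        counts = np.bincount(b, minlength=n_segments)
        if np.any(counts == 0):
            return None
        means = np.bincount(b, weights=rts[idx], minlength=n_segments) / counts
        rdms.append(rdm_from_profile(means).values)
    return RDM(np.mean(rdms, axis=0))


def _subject_data(table: TrialTable, n_segments: int):
    df = table.df
    df = df.loc[df["boundary_condition"] != "across"]
    out = []
    for _, sub in df.groupby("subject_id", sort=True):
        out.append((_locations_bins(sub, n_segments), sub["rt_s"].to_numpy()))
    return out


def spearman_model_fit(
    table: TrialTable,
    model: RDM,
    n_iter: int = 100,
    rng=None,
    n_segments: int = DEFAULT_N_SEGMENTS,
    max_redraws: int = 1000,
):
    """Bootstrap Spearman correlation between data and one model RDM.

    Per iteration, trials are resampled with replacement within each subject,
    per-subject RDMs rebuilt and averaged into a group RDM, and the Spearman
    correlation over the upper triangle computed against the model.  Returns
    ``(mean_r, sem, rs)`` over ``n_iter`` iterations; iterations that leave a
    segment empty are redrawn (the redraw count is not part of the result).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if model.n != n_segments:
        raise ValueError(f"model RDM is {model.n}x{model.n} but n_segments={n_segments}")
    data = _subject_data(table, n_segments)
    rs = np.empty(n_iter)
    redraws = 0
    for i in range(n_iter):
        group = _group_rdm_bootstrap(data, n_segments, rng)
        while group is None:
            redraws += 1
            if redraws > max_redraws:
                raise EmptySegmentError(0, n_segments)
            group = _group_rdm_bootstrap(data, n_segments, rng)
        rs[i] = _spearman_upper(group, model)
    return float(np.mean(rs)), float(np.std(rs, ddof=1) / np.sqrt(n_iter)), rs


def compare_models(rs_a: Sequence[float], rs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-iteration correlations."""
    rs_a = np.asarray(rs_a, dtype=float)
    rs_b = np.asarray(rs_b, dtype=float)
    if rs_a.shape != rs_b.shape:
        raise ValueError("paired iteration vectors must have equal length")
    diffs = rs_a - rs_b
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(rs_a, rs_b, alternative="two-sided").pvalue)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


class ReplayRSA:
    """RSA of a trial table against replay-model RDMs (Model/Results API).

    Parameters
    ----------
    table : TrialTable
        Trials (within-context rows are used; others are ignored).
    n_segments : int
        Equal-width chosen-frame-location segments (8, 10 or 14 typical).
    boundary_segment : int
        First Clip-2 segment of the hypothetical models.
    """

    def __init__(
        self,
        table: TrialTable,
        n_segments: int = DEFAULT_N_SEGMENTS,
        boundary_segment: int | None = None,
    ):
        self.table = table
        self.n_segments = n_segments
        if boundary_segment is None:
            # scale the default (5 of 8) to the segment count
            boundary_segment = n_segments // 2 + 1
        self.boundary_segment = boundary_segment

    def data_rdm(self) -> RDM:
        """Group RDM without resampling: per-subject RDMs averaged."""
        rdms = []
        for bins, rts in _subject_data(self.table, self.n_segments):
            counts = np.bincount(bins, minlength=self.n_segments)
            if np.any(counts == 0):
                raise EmptySegmentError(int(np.flatnonzero(counts == 0)[0]), self.n_segments)
            means = np.bincount(bins, weights=rts, minlength=self.n_segments) / counts
            rdms.append(rdm_from_profile(means).values)
        return RDM(np.mean(rdms, axis=0))

    def fit(
        self,
        models: Sequence[tuple[str, ReplayModelSpec]] | None = None,
        n_iter: int = 100,
        seed=None,
    ) -> "RSAResults":
        """Bootstrap-correlate the data RDM with each candidate model RDM."""
        if models is None:
            models = [
                ("strict_forward", strict_forward_spec(self.boundary_segment)),
                ("global_compression", global_compression_spec(self.boundary_segment)),
            ]
        rng = np.random.default_rng(seed)
        rows = {}
        for name, spec in models:
            mrdm = model_rdm(spec, self.n_segments)
            mean_r, sem, rs = spearman_model_fit(
                self.table, mrdm, n_iter=n_iter, rng=rng, n_segments=self.n_segments
            )
            rows[name] = {"spec": spec, "rdm": mrdm, "mean_r": mean_r, "sem": sem, "rs": rs}
        return RSAResults(self, rows)

    def offset_sweep(
        self, n_models: int = 11, slope: float = 1.0
    ) -> pd.DataFrame:
        """Point-estimate Spearman r of the data RDM against the offset grid."""
        data = self.data_rdm()
        records = []
        for spec, mrdm in offset_model_family(
            n_models, self.n_segments, self.boundary_segment, slope
        ):
            records.append({"offset": spec.offset, "r": _spearman_upper(data, mrdm)})
        return pd.DataFrame(records)


def argmax_offsets(sweep: pd.DataFrame, tol: float = 1e-9) -> np.ndarray:
    """All offsets attaining the maximum sweep correlation (exact ties).

    Large same-sign offsets can yield *identical* rank-transformed RDMs (the
    rank structure saturates once every cross-clip distance exceeds every
    within-clip one), so several grid models may tie bit-for-bit; all of them
    are equally valid argmaxes.
    """
    r = sweep["r"].to_numpy()
    return sweep["offset"].to_numpy()[r >= r.max() - tol]


@dataclass
class RSAResults:
    """Bootstrap RSA fit of candidate replay models."""

    model: ReplayRSA
    rows: dict  # name -> {spec, rdm, mean_r, sem, rs}

    @property
    def mean_r(self) -> dict:
        return {k: v["mean_r"] for k, v in self.rows.items()}

    def iterations(self, name: str) -> np.ndarray:
        return self.rows[name]["rs"]

    def compare(self, name_a: str, name_b: str) -> float:
        """Wilcoxon signed-rank p for the paired contrast of two models."""
        return compare_models(self.rows[name_a]["rs"], self.rows[name_b]["rs"])

    def pairwise_table(self) -> pd.DataFrame:
        """All pairwise model contrasts with BH-FDR-adjusted p-values."""
        names = list(self.rows)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        pvals = [self.compare(a, b) for a, b in pairs]
        adj = fdr_adjust(pvals) if pvals else np.array([])
        return pd.DataFrame(
            {
                "model_a": [a for a, _ in pairs],
                "model_b": [b for _, b in pairs],
                "p": pvals,
                "p_fdr": adj,
            }
        )

    def vs_zero_table(self) -> pd.DataFrame:
        """Each model's iteration distribution tested against zero (Wilcoxon)."""
        records = []
        pvals = []
        for name, row in self.rows.items():
            rs = row["rs"]
            p = 1.0 if np.all(rs == 0) else float(stats.wilcoxon(rs).pvalue)
            pvals.append(p)
            records.append({"model": name, "mean_r": row["mean_r"], "sem": row["sem"], "p": p})
        df = pd.DataFrame(records)
        df["p_fdr"] = fdr_adjust(pvals) if pvals else np.nan
        return df

    def summary(self) -> str:
        lines = [f"RSA over {self.model.n_segments} segments "
                 f"({len(next(iter(self.rows.values()))['rs'])} bootstrap iterations)"]
        for name, row in self.rows.items():
            lines.append(
                f"  {name:<20} offset={row['spec'].offset:+.2f}  "
                f"r = {row['mean_r']:.3f} +/- {row['sem']:.3f}"
            )
        tab = self.pairwise_table()
        for rec in tab.itertuples(index=False):
            lines.append(
                f"  {rec.model_a} vs {rec.model_b}: Wilcoxon p = {rec.p:.3g} (FDR {rec.p_fdr:.3g})"
            )
        return "\n".join(lines)
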