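"""LATER (Linear Approach to Threshold with Ergodic Rate) latency modelling.

Under LATER, a decision signal rises linearly from a start level to a
threshold at a rate drawn per trial from a Gaussian with mean ``mu`` and SD
``sigma1``; with start-to-threshold distance ``theta``, the latency is
``theta / rate`` and the *promptness* 1/RT is Gaussian with mean
``m = mu / theta`` and SD ``s = sigma1 / theta``.  Only the promptness-scale
pair (m, s) is identified by latency data; reported (mu, sigma1, theta) use
the convention ``sigma1 = 1``.

Condition effects are adjudicated between four variants by BIC:

``null``
    one (m, s) shared by both conditions — no effect of the manipulation;
``shift``
    the rate mean changes (free m per condition, shared s) — parallel
    reciprobit lines translated along the promptness axis;
``swivel``
    the threshold changes (shared m/s ratio, free s per condition) —
    reciprobit lines pivoting on the infinite-time intercept;
``two_fits``
    all parameters free per condition.

BIC = -2 logL + k ln(n); a BIC difference above 2 is positive evidence and
above 6 strong evidence for the lower-BIC variant.

The module offers both a statsmodels-flavoured object API
(:class:`LaterModel` -> :class:`LaterResults` / :class:`LaterComparison`)
and the underlying functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    InsufficientDataError,
)

__all__ = [
    "LaterModel",
    "LaterResults",
    "LaterComparison",
    "VARIANTS",
    "promptness_loglik",
    "fit_condition_mle",
    "fit_variant",
    "compare_bic",
    "reciprobit_points",
    "bic",
]

VARIANTS = ("null", "shift", "swivel", "two_fits")

#: free-parameter count per variant for two conditions
N_PARAMS = {"null": 2, "shift": 3, "swivel": 3, "two_fits": 4}

_OPT_MAXITER = 10_000
_OPT_RTOL = 1e-8


def promptness_loglik(rts: Sequence[float], m: float, s: float) -> float:
    """Gaussian log-likelihood of the promptness (1/RT) sample at (m, s).

    The density is taken on the promptness scale — the scale on which LATER
    predicts normality — with no Jacobian back to seconds; all model
    variants are compared on this same scale, so the choice cancels in
    every BIC difference.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise InsufficientDataError("empty RT sample")
    if not s > 0:
        raise ValueError("s must be > 0")
    ll = float(np.sum(stats.norm.logpdf(1.0 / rts, loc=m, scale=s)))
    if not np.isfinite(ll):
        raise DegenerateDataError("non-finite log-likelihood")
    return ll


def fit_condition_mle(rts: Sequence[float], min_n: int = 3) -> tuple[float, float]:
    """Exact Gaussian MLE of promptness: sample mean and divide-by-n SD."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} observations, got {rts.size}")
    p = 1.0 / rts
    m = float(np.mean(p))
    s = float(np.std(p))  # ddof=0: the MLE
    if s == 0:
        raise DegenerateDataError("zero promptness variance (identical RTs)")
    return m, s


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``-2 logL + k ln(n)``."""
    return -2.0 * loglik + n_params * np.log(n_obs)


@dataclass
class LaterFit:
    """Fitted LATER variant: per-condition (m, s), log-likelihood, complexity."""

    variant: str
    params: dict  # condition -> (m, s)
    loglik: float
    n_params: int
    n_obs: int
    converged: bool = True

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.n_params, self.n_obs)

    def theta_mu_sigma(self, condition: str) -> tuple[float, float, float]:
        """(theta, mu, sigma1) under the sigma1 = 1 identifiability convention."""
        m, s = self.params[condition]
        theta = 1.0 / s
        return theta, m * theta, 1.0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": {c: list(ms) for c, ms in self.params.items()},
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "converged": self.converged,
        }


def _joint_loglik(p_by_cond: dict, params: dict) -> float:
    return sum(
        float(np.sum(stats.norm.logpdf(p, loc=m, scale=s)))
        for (p, (m, s)) in ((p_by_cond[c], params[c]) for c in p_by_cond)
    )


def _minimize(fun, x0, variant):
    f0 = abs(fun(x0)) or 1.0
    res = optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": _OPT_MAXITER,
            "fatol": _OPT_RTOL * f0,
            "xatol": 1e-10,
        },
    )
    if not res.success:
        raise ConvergenceError(variant, res.nit)
    return res


def fit_variant(rts_by_condition: Mapping[str, Sequence[float]], variant: str, min_n: int = 10) -> LaterFit:
    """Maximum-likelihood fit of one model variant over two conditions.

    Constrained variants (shift, swivel) are solved numerically (derivative-
    free simplex) starting from the unconstrained per-condition solution;
    null and two_fits use the closed-form Gaussian MLE.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant '{variant}'; expected one of {VARIANTS}")
    conds = list(rts_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    p_by_cond = {}
    for c in conds:
        rts = np.asarray(rts_by_condition[c], dtype=float)
        if rts.size < min_n:
            raise InsufficientDataError(f"condition '{c}' has {rts.size} < {min_n} observations")
        p_by_cond[c] = 1.0 / rts
    n_obs = sum(p.size for p in p_by_cond.values())
    free = {c: fit_condition_mle(rts_by_condition[c], min_n=min_n) for c in conds}

    if variant == "two_fits":
        params = free
    elif variant == "null":
        pooled = np.concatenate(list(p_by_cond.values()))
        m, s = float(np.mean(pooled)), float(np.std(pooled))
        if s == 0:
            raise DegenerateDataError("zero pooled promptness variance")
        params = {c: (m, s) for c in conds}
    elif variant == "shift":
        # free m per condition, shared s
        def negll(x):
            m1, m2, log_s = x
            s = np.exp(log_s)
            return -_joint_loglik(p_by_cond, {conds[0]: (m1, s), conds[1]: (m2, s)})

        s0 = np.sqrt(np.mean([free[c][1] ** 2 for c in conds]))
        res = _minimize(negll, [free[conds[0]][0], free[conds[1]][0], np.log(s0)], variant)
        m1, m2, log_s = res.x
        s = float(np.exp(log_s))
        params = {conds[0]: (float(m1), s), conds[1]: (float(m2), s)}
    else:  # swivel: shared ratio k = m/s (infinite-time intercept), free s
        def negll(x):
            k, log_s1, log_s2 = x
            s1, s2 = np.exp(log_s1), np.exp(log_s2)
            return -_joint_loglik(
                p_by_cond, {conds[0]: (k * s1, s1), conds[1]: (k * s2, s2)}
            )

        k0 = np.mean([free[c][0] / free[c][1] for c in conds])
        res = _minimize(
            negll, [k0, np.log(free[conds[0]][1]), np.log(free[conds[1]][1])], variant
        )
        k, log_s1, log_s2 = res.x
        s1, s2 = float(np.exp(log_s1)), float(np.exp(log_s2))
        params = {conds[0]: (float(k * s1), s1), conds[1]: (float(k * s2), s2)}

    ll = _joint_loglik(p_by_cond, params)
    return LaterFit(variant, params, ll, N_PARAMS[variant], n_obs)


#: Evidence thresholds on a BIC difference.
_EVIDENCE = ((6.0, "strong"), (2.0, "positive"))


def _evidence_label(delta: float) -> str:
    for thresh, label in _EVIDENCE:
        if delta > thresh:
            return label
    return "weak"


@dataclass
class LaterComparison:
    """BIC adjudication among fitted LATER variants."""

    fits: dict  # variant -> LaterFit

    def __post_init__(self) -> None:
        ns = {f.n_obs for f in self.fits.values()}
        if len(ns) > 1:
            raise ValueError(f"fits disagree on n_obs: {sorted(ns)} — not the same data")

    @property
    def bics(self) -> dict:
        return {v: f.bic for v, f in self.fits.items()}

    @property
    def best_variant(self) -> str:
        return min(self.bics, key=self.bics.get)

    @property
    def delta_bic(self) -> dict:
        best = min(self.bics.values())
        return {v: b - best for v, b in self.bics.items()}

    @property
    def evidence(self) -> dict:
        return {v: _evidence_label(d) for v, d in self.delta_bic.items()}

    def delta(self, variant_a: str, variant_b: str) -> float:
        """BIC(variant_a) - BIC(variant_b); negative favours variant_a."""
        return self.bics[variant_a] - self.bics[variant_b]

    def to_dict(self) -> dict:
        return {
            "best_variant": self.best_variant,
            "fits": {v: f.to_dict() for v, f in self.fits.items()},
            "delta_bic": self.delta_bic,
            "evidence": self.evidence,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"{'variant':<10} {'k':>3} {'logL':>12} {'BIC':>12} {'dBIC':>10}  evidence",
        ]
        for v in VARIANTS:
            if v not in self.fits:
                continue
            f = self.fits[v]
            mark = " <- best" if v == self.best_variant else ""
            lines.append(
                f"{v:<10} {f.n_params:>3} {f.loglik:>12.3f} {f.bic:>12.3f} "
                f"{self.delta_bic[v]:>10.3f}  {self.evidence[v]}{mark}"
            )
        return "\n".join(lines)


def compare_bic(fits: Sequence[LaterFit]) -> LaterComparison:
    """Rank fitted variants by BIC with evidence labels for each difference."""
    return LaterComparison({f.variant: f for f in fits})


def reciprobit_points(rts: Sequence[float]) -> np.ndarray:
    """Empirical reciprobit coordinates: (promptness, probit of cum. prob.).

    Promptness values are sorted ascending and assigned Hazen plotting
    positions ``(i - 0.5)/n``; ties collapse to a single point carrying their
    pooled mass.  Under LATER the points fall on a line of slope ``1/s`` and
    promptness-axis intercept ``m``.
    """
    rts = np.asarray(rts, dtype=float)
    p = np.sort(1.0 / rts)
    values, counts = np.unique(p, return_counts=True)
    if values.size < 2:
        raise DegenerateDataError("need >= 2 distinct RTs for a reciprobit line")
    n = p.size
    cum = np.cumsum(counts)
    positions = (cum - 0.5 * counts) / n
    z = stats.norm.ppf(positions)
    return np.column_stack([values, z])


class LaterModel:
    """LATER model over two latency conditions (statsmodels-style entry point).

    Parameters
    ----------
    rts_by_condition : mapping of condition name -> 1-D array of RTs (s)
        Exactly two conditions (e.g. within- vs. across-context trials).

    Examples
    --------
    >>> model = LaterModel({"within": rts_w, "across": rts_a})
    >>> comparison = model.fit()          # all four variants + BIC table
    >>> print(comparison.summary())
    """

    def __init__(self, rts_by_condition: Mapping[str, Sequence[float]]):
        self.rts_by_condition = {
            c: np.asarray(v, dtype=float) for c, v in rts_by_condition.items()
        }
        if len(self.rts_by_condition) != 2:
            raise ValueError("LaterModel requires exactly two conditions")

    @classmethod
    def from_table(cls, table, split: str = "context") -> "LaterModel":
        """Build from a :class:`~tojreplay.trial_data.TrialTable`.

        ``split='context'`` contrasts within- vs. across-context trials.
        """
        if split != "context":
            raise ValueError("only the 'context' split is defined")
        df = table.df
        across = df["boundary_condition"] == "across"
        return cls(
            {"within": df.loc[~across, "rt_s"].to_numpy(), "across": df.loc[across, "rt_s"].to_numpy()}
        )

    def fit_variant(self, variant: str) -> "LaterResults":
        return LaterResults(self, fit_variant(self.rts_by_condition, variant))

    def fit(self) -> LaterComparison:
        """Fit all four variants and return their BIC comparison."""
        return compare_bic([fit_variant(self.rts_by_condition, v) for v in VARIANTS])


@dataclass
class LaterResults:
    """One fitted variant bound to its model, with plotting helpers."""

    model: LaterModel
    fit: LaterFit

    @property
    def params(self) -> dict:
        return self.fit.params

    @property
    def llf(self) -> float:
        return self.fit.loglik

    @property
    def bic(self) -> float:
        return self.fit.bic

    def summary(self) -> str:
        lines = [f"LATER fit, variant '{self.fit.variant}' "
                 f"(logL={self.fit.loglik:.3f}, BIC={self.fit.bic:.3f}, n={self.fit.n_obs})"]
        for c, (m, s) in self.fit.params.items():
            theta, mu, sigma1 = self.fit.theta_mu_sigma(c)
            lines.append(
                f"  {c:<10} m={m:.4f}  s={s:.4f}   (theta={theta:.3f}, mu={mu:.4f}, sigma1={sigma1:g})"
            )
        return "\n".join(lines)

    def plot_reciprobit(self, ax=None):
        """Empirical reciprobit points per condition with the fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, rts in self.model.rts_by_condition.items():
            pts = reciprobit_points(rts)
            ax.plot(pts[:, 0], pts[:, 1], ".", label=f"{c} (data)", alpha=0.5)
            m, s = self.fit.params[c]
            grid = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 50)
            ax.plot(grid, (grid - m) / s, "--", label=f"{c} (fit)")
        ax.set_xlabel("promptness 1/RT (s$^{-1}$)")
        ax.set_ylabel("z (probit of cumulative probability)")
        ax.legend()
        return ax
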