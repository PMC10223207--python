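"""Median lethal dose estimation by the (trimmed) Spearman-Karber method.

Dose-group mortality proportions are first made monotone by pooled-adjacent-
violators (PAVA) isotonic regression weighted by group sizes, then treated
as a piecewise-linear tolerance distribution on the log10-dose scale.  The
Spearman-Karber estimator is the mean of that distribution,

    log10 LD50 = sum_i (p_{i+1} - p_i) * (x_i + x_{i+1}) / 2,

optionally after symmetric trimming of both tails at ``trim_percent`` and
rescaling the central part of the curve.  When the smoothed curve does not
reach 0 at the bottom or 1 at the top, virtual anchor doses one log-step
outside the tested range complete the distribution (the convention of the
classical trimmed Spearman-Karber program); they carry no binomial
uncertainty.  The variance of the log-LD50 follows the delta method,
Var = sum_i (dL/dp_i)^2 p_i (1-p_i) / (n_i - 1), which for trim 0 reduces
to the textbook closed form with weights ((x_{i+1} - x_{i-1}) / 2)^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import norm

from .errors import InvalidInputError, NonBracketingError, ValidationError

__all__ = [
    "DoseResponseSeries",
    "LD50Estimate",
    "pava_monotone",
    "spearman_karber_ld50",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """Mortality counts per dose group (doses in ug venom / g body weight)."""

    doses: tuple[float, ...]
    n_subjects: tuple[int, ...]
    deaths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.doses) < 2:
            raise ValidationError("need at least two dose groups")
        if not (len(self.doses) == len(self.n_subjects) == len(self.deaths)):
            raise ValidationError("doses, n_subjects, deaths must align")
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be positive")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValidationError("doses must be strictly increasing")
        if any(n <= 0 for n in self.n_subjects):
            raise ValidationError("group sizes must be positive")
        if any(k < 0 or k > n for k, n in zip(self.deaths, self.n_subjects)):
            raise ValidationError("deaths must lie in [0, n_subjects]")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.deaths, float) / np.asarray(self.n_subjects, float)

    @classmethod
    def read_csv(cls, path) -> "DoseResponseSeries":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ValidationError(f"cannot read dose CSV {path}: {exc}") from exc
        required = {"dose", "n", "deaths"}
        if missing := required - set(df.columns):
            raise ValidationError(f"dose CSV missing columns: {sorted(missing)}")
        return cls(
            tuple(float(d) for d in df["dose"]),
            tuple(int(n) for n in df["n"]),
            tuple(int(k) for k in df["deaths"]),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"dose": self.doses, "n": self.n_subjects, "deaths": self.deaths}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class LD50Estimate:
    """LD50 point estimate with 95% confidence limits (log10-scale SE)."""

    ld50: float
    ci_low: float
    ci_high: float
    trim_percent: float
    log10_ld50: float
    se_log10: float
    log_base: int = 10


def pava_monotone(
    props: Sequence[float], weights: Sequence[float] | None = None
) -> np.ndarray:
    """Nondecreasing sequence minimizing the weighted squared error
    (weights default to equal; group sizes in the LD50 pipeline)."""
    y = np.asarray(props, dtype=float)
    if y.size == 0:
        raise InvalidInputError("empty proportion list")
    w = None if weights is None else np.asarray(weights, dtype=float)
    return isotonic_regression(y, weights=w, increasing=True).x.copy()


def _trimmed_mean(x: np.ndarray, p: np.ndarray, alpha: float) -> float:
    """Mean of the piecewise-linear tolerance curve (x, p) after trimming
    both tails at level alpha and rescaling to [0, 1]."""
    if alpha > 0:
        lo, hi = alpha, 1.0 - alpha
        x_lo = float(np.interp(lo, p, x))
        x_hi = float(np.interp(hi, p, x))
        inside = (p > lo) & (p < hi)
        xs = np.concatenate(([x_lo], x[inside], [x_hi]))
        ps = np.concatenate(([lo], p[inside], [hi]))
        ps = (ps - alpha) / (1.0 - 2.0 * alpha)
    else:
        xs, ps = x, p
    return float(np.sum(np.diff(ps) * (xs[:-1] + xs[1:]) / 2.0))


def spearman_karber_ld50(
    series: DoseResponseSeries,
    trim_percent: float = 0.0,
    confidence: float = 0.95,
) -> LD50Estimate:
    """Spearman-Karber LD50 with confidence limits on the dose scale.

    ``trim_percent`` in [0, 50) trims both tails of the smoothed mortality
    curve (0 = classical untrimmed estimator, the default).
    """
    if not 0.0 <= trim_percent < 50.0:
        raise InvalidInputError("trim_percent must be in [0, 50)")
    alpha = trim_percent / 100.0
    x_obs = np.log10(np.asarray(series.doses, float))
    n = np.asarray(series.n_subjects, float)
    p_obs = pava_monotone(series.proportions, weights=n)

    if p_obs.max() < 0.5 or p_obs.min() > 0.5:
        raise NonBracketingError(
            "smoothed mortality never brackets 50%; cannot estimate LD50"
        )

    # virtual anchors one log-step outside the tested range complete the
    # tolerance curve; they are exact (no binomial variance contribution)
    x = x_obs.copy()
    p = p_obs.copy()
    observed = np.ones(x.size, dtype=bool)
    step_lo = x_obs[1] - x_obs[0]
    step_hi = x_obs[-1] - x_obs[-2]
    if p[0] > 0.0:
        x = np.concatenate(([x_obs[0] - step_lo], x))
        p = np.concatenate(([0.0], p))
        observed = np.concatenate(([False], observed))
    if p[-1] < 1.0:
        x = np.concatenate((x, [x_obs[-1] + step_hi]))
        p = np.concatenate((p, [1.0]))
        observed = np.concatenate((observed, [False]))

    if x.size < 2:
        raise InvalidInputError("fewer than two informative groups after trimming")

    mu = _trimmed_mean(x, p, alpha)

    # delta-method variance over the observed (binomial) groups; the PAVA
    # pooling is held fixed, so for trim 0 the derivative at interior group i
    # is (x_{i+1} - x_{i-1}) / 2
    var = 0.0
    h = 1e-6
    obs_idx = np.where(observed)[0]
    for i, ni in zip(obs_idx, n):
        pq = p[i] * (1.0 - p[i])
        if pq == 0.0:
            continue
        p_hi = p.copy()
        p_lo = p.copy()
        p_hi[i] = min(p[i] + h, 1.0)
        p_lo[i] = max(p[i] - h, 0.0)
        dmu = (_trimmed_mean(x, p_hi, alpha) - _trimmed_mean(x, p_lo, alpha)) / (
            p_hi[i] - p_lo[i]
        )
        denom = ni - 1.0 if ni > 1 else ni
        var += dmu * dmu * pq / denom

    se = float(np.sqrt(var))
    z = float(norm.ppf(0.5 + confidence / 2.0))
    return LD50Estimate(
        ld50=float(10.0 ** mu),
        ci_low=float(10.0 ** (mu - z * se)),
        ci_high=float(10.0 ** (mu + z * se)),
        trim_percent=trim_percent,
        log10_ld50=float(mu),
        se_log10=se,
    )
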