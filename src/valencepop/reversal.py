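"""Trial-by-trial reversal-learning trajectories.

The per-trial neural measure is the Mahalanobis distance of each trial's
population CS response from the pre-reversal reference block; behavioural
measures are per-trial licking and blinking scalars. Each series is
normalised by its median and mean-centred (sign-flipped so learning goes
low -> high), fitted with a sigmoidal Weibull function of trial number,
and searched for change points on its cumulative record.

The Weibull used for fitting is the rise form
``f(x) = u - (u - l) * exp(-(x/alpha)^beta)`` — monotone from the lower
asymptote ``l`` to the upper asymptote ``u`` with latency ``alpha``
(trials) and abruptness ``beta``. The historically printed variant
``u + (1 - l) * exp(-(x/alpha)^beta)`` is retained as ``form="printed"``
for fidelity although its asymptotes are inconsistent with the stated
roles of u and l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NormalizedSeries",
    "WeibullFit",
    "ChangePointResult",
    "normalize_series",
    "weibull",
    "fit_weibull",
    "neural_behavior_correlation",
    "detect_change_points",
    "change_point_lags",
]


@dataclass
class NormalizedSeries:
    values: np.ndarray
    flipped: bool
    source: str = ""  # neural MD | licking | blinking | combined


@dataclass
class WeibullFit:
    u: float
    l: float
    alpha: float
    beta: float
    r_squared: float
    form: str = "rise"
    converged: bool = True
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return weibull(x, self.u, self.l, self.alpha, self.beta, self.form)


@dataclass
class ChangePointResult:
    change_points: np.ndarray  # 1-based first trial of each new regime
    statistics: np.ndarray  # confirmation p-value per accepted point
    alpha: float

    @property
    def first(self) -> int | None:
        return int(self.change_points[0]) if self.change_points.size else None


def normalize_series(
    series: np.ndarray,
    flip: str | bool = "auto",
    split: int | None = None,
    source: str = "",
) -> NormalizedSeries:
    """Median-normalise and mean-centre a per-trial response series.

    x -> x / median(x) - mean(x / median(x)). With flip="auto" the series
    is multiplied by -1 when its mean before `split` (defaults to the
    series midpoint) exceeds the mean after, so learning curves always run
    low -> high.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d series of >= 2 trials")
    med = np.median(x)
    if med == 0:
        med = np.median(np.abs(x)) + 1e-12
        warnings.warn("zero median; falling back to median(|x|) + eps",
                      stacklevel=2)
    y = x / med
    y = y - y.mean()
    if split is None:
        split = x.size // 2
    if flip == "auto":
        do_flip = y[:split].mean() > y[split:].mean()
    else:
        do_flip = bool(flip)
    if do_flip:
        y = -y
    return NormalizedSeries(y, bool(do_flip), source)


def weibull(
    x: np.ndarray,
    u: float,
    l: float,
    alpha: float,
    beta: float,
    form: str = "rise",
) -> np.ndarray:
    """Sigmoidal Weibull learning curve.

    form="rise" (default): u - (u - l) * exp(-(x/alpha)^beta), running
    from l at x = 0 to u as x -> inf. form="printed" evaluates
    u + (1 - l) * exp(-(x/alpha)^beta) verbatim.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    decay = np.exp(-np.power(x / alpha, beta))
    if form == "rise":
        return u - (u - l) * decay
    if form == "printed":
        return u + (1.0 - l) * decay
    raise ValueError("form must be 'rise' or 'printed'")


def fit_weibull(
    series: NormalizedSeries | np.ndarray,
    form: str = "rise",
) -> WeibullFit:
    """Least-squares Weibull fit over (u, l, alpha, beta).

    Deterministic multi-start: a 3x3x3x3 grid of initial values spanning
    the series' range, alpha in (0, 10 n] and beta in (0, 50], refined
    with bounded least squares; the best start by SSE wins. r^2 is
    1 - SS_res / SS_tot; a constant series is flagged degenerate with
    r^2 = 0.
    """
    y = np.asarray(series.values if isinstance(series, NormalizedSeries)
                   else series, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 trials to fit")
    x = np.arange(n, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return WeibullFit(y[0], y[0], 1.0, 1.0, 0.0, form,
                          converged=False, degenerate=True)

    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    bounds = ([lo - 10 * span, lo - 10 * span, 1e-6, 1e-3],
              [hi + 10 * span, hi + 10 * span, 10.0 * n, 50.0])

    def resid(theta: np.ndarray) -> np.ndarray:
        return weibull(x, *theta, form=form) - y

    best, best_sse, converged = None, np.inf, False
    us = (hi, hi - 0.25 * span, lo + 0.5 * span)
    ls = (lo, lo + 0.25 * span, lo + 0.5 * span)
    alphas = (0.25 * n, 0.5 * n, 0.9 * n)
    betas = (1.0, 4.0, 12.0)
    for u0 in us:
        for l0 in ls:
            for a0 in alphas:
                for b0 in betas:
                    theta0 = np.clip(
                        [u0, l0, a0, b0],
                        np.asarray(bounds[0]) + 1e-12,
                        np.asarray(bounds[1]) - 1e-12)
                    try:
                        res = optimize.least_squares(
                            resid, theta0, bounds=bounds, method="trf",
                            max_nfev=400)
                    except Exception:
                        continue
                    sse = float(np.sum(res.fun ** 2))
                    if sse < best_sse:
                        best, best_sse = res.x, sse
                        converged = res.status > 0
    if best is None:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, 0.0, form,
                          converged=False)
    r2 = 1.0 - best_sse / ss_tot
    return WeibullFit(float(best[0]), float(best[1]), float(best[2]),
                      float(best[3]), float(r2), form, converged=converged)


def neural_behavior_correlation(
    neural: NormalizedSeries | np.ndarray,
    behavior: NormalizedSeries | np.ndarray,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between trial-by-trial series."""
    a = np.asarray(neural.values if isinstance(neural, NormalizedSeries)
                   else neural, dtype=float)
    b = np.asarray(behavior.values if isinstance(behavior, NormalizedSeries)
                   else behavior, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must share length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def detect_change_points(
    series: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ChangePointResult:
    """Change points of a per-trial series via its cumulative record.

    On each segment: form the cumulative sum, take the index with maximal
    vertical deviation from the chord joining the record's endpoints as
    the candidate split, and confirm it with a two-sided rank-sum test on
    the observations before vs after the split. Because the candidate is
    the most extreme of n - 1 possible splits, the confirmation is tested
    at alpha / (n - 1) (Bonferroni) so the family false-alarm rate on an
    exchangeable series stays <= alpha; correction="none" tests at raw
    alpha. An accepted split is reported 1-based as the first trial of
    the new regime and the search recurses into both resulting segments,
    so earlier (smaller) changes are still found after a dominant one.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-d series of >= 5 trials")
    points: list[int] = []
    pvals: list[float] = []

    def split(seg: np.ndarray, offset: int) -> None:
        n = seg.size
        if n < 5:
            return
        cum = np.cumsum(seg)
        chord = np.arange(1, n + 1) * cum[-1] / n
        dev = np.abs(cum - chord)[: n - 1]
        k = int(np.argmax(dev)) + 1  # trials 1..k belong to the old regime
        if dev[k - 1] == 0:
            return
        before, after = seg[:k], seg[k:]
        if np.all(seg == seg[0]):
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.mannwhitneyu(
                before, after, alternative="two-sided").pvalue)
        if not np.isfinite(p):
            return
        level = alpha / (n - 1) if correction == "bonferroni" else alpha
        if p >= level:
            return
        points.append(offset + k + 1)  # 1-based first trial of new regime
        pvals.append(p)
        split(before, offset)
        split(after, offset + k)

    split(x, 0)
    order = np.argsort(points)
    return ChangePointResult(np.asarray(points, dtype=int)[order],
                             np.asarray(pvals)[order], alpha)


def change_point_lags(
    neural_cp: int | None, behavior_cp: int | None
) -> float:
    """neural - behavioural change-point trial; negative = neural leads."""
    if neural_cp is None or behavior_cp is None:
        warnings.warn("missing change point; lag undefined", stacklevel=2)
        return float("nan")
    return float(neural_cp - behavior_cp)
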