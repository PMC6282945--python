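"""Accuracy and two-sample power experiments for survey protocols.

``accuracy_experiment`` repeats a protocol many times on one fixed marked
population and reports the probability that the pooled prevalence estimate
lands within a tolerance of the population's realized (true) prevalence.  The
tolerance can be absolute (a margin on the proportion scale) or relative (a
fraction of the true prevalence).

``power_experiment`` draws random pairs of those surveys and, for each pair,
computes the achieved (post-hoc) power of a two-sided two-proportion z test at
the observed pooled estimates and pooled colony counts, together with Cliff's
delta on the two surveys' per-transect prevalence values as an ordinal effect
size.  ``smooth_power_curve`` fits a monotone power-vs-|delta| trend for
figure-style output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .disease import MarkedPattern
from .pointprocess import as_rng
from .survey import Protocol, SurveyResult, run_survey

__all__ = [
    "AccuracySummary",
    "PowerPoint",
    "PowerCurve",
    "power_two_proportions",
    "cliffs_delta",
    "accuracy_experiment",
    "power_experiment",
    "smooth_power_curve",
    "accuracy_to_csv",
    "power_to_csv",
]


@dataclass(eq=False)
class AccuracySummary:
    """Outcome of repeated surveying of one marked population."""

    protocol: Protocol
    n_surveys: int
    true_prevalence: float
    tolerance: float
    tolerance_mode: str
    prob_within_tolerance: float
    estimates: np.ndarray
    within_tolerance: np.ndarray
    surveys: list
    n_undefined: int = 0

    @property
    def margin(self) -> float:
        """The tolerance expressed on the proportion scale."""
        if self.tolerance_mode == "absolute":
            return self.tolerance
        return self.tolerance * self.true_prevalence


@dataclass(frozen=True)
class PowerPoint:
    """One two-sample comparison: ordinal effect size and achieved power."""

    effect_size: float
    achieved_power: float
    n1: int
    n2: int
    p1: float
    p2: float
    pair: tuple = (0, 0)


def power_two_proportions(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Normal-approximation power of the two-sided two-proportion test.

    Uses pooled variance under the null and unpooled under the alternative,
    without continuity correction, with the harmonic mean of the two sample
    sizes as the effective per-group n (it reduces to n for equal groups).
    Both rejection tails are included, so the power at zero effect equals
    ``alpha`` exactly.
    """
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError("proportions must be in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("counts must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = abs(p1 - p2)
    pbar = (p1 + p2) / 2.0
    sd_null = np.sqrt(2.0 * pbar * (1.0 - pbar))
    sd_alt = np.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    if sd_alt == 0:
        return alpha if d == 0 else 1.0
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n_eff = 2.0 / (1.0 / n1 + 1.0 / n2)
    root_n = np.sqrt(n_eff)
    upper = stats.norm.cdf((d * root_n - z * sd_null) / sd_alt)
    lower = stats.norm.cdf((-d * root_n - z * sd_null) / sd_alt)
    return float(upper + lower)


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    xa = np.asarray(x, dtype=float).reshape(-1)
    ya = np.asarray(y, dtype=float).reshape(-1)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = np.sign(xa[:, None] - ya[None, :])
    return float(diff.sum() / (xa.size * ya.size))


def accuracy_experiment(
    marked: MarkedPattern,
    protocol: Protocol,
    n_surveys: int = 100,
    tolerance: float = 0.05,
    tolerance_mode: str = "absolute",
    seed=None,
) -> AccuracySummary:
    """Repeat the protocol ``n_surveys`` times on one marked population.

    Each survey draws fresh station and transect placements; the population
    and hence its realized ("true") prevalence stay fixed.  Surveys that
    counted no colonies keep an undefined (NaN) estimate and count as outside
    tolerance.
    """
    if n_surveys < 1:
        raise ValueError("n_surveys must be >= 1")
    if tolerance_mode not in ("absolute", "relative"):
        raise ValueError("tolerance_mode must be 'absolute' or 'relative'")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    rng = as_rng(seed)
    true_prev = marked.prevalence
    margin = tolerance if tolerance_mode == "absolute" else tolerance * true_prev
    surveys: list[SurveyResult] = []
    estimates = np.empty(n_surveys)
    for i in range(n_surveys):
        res = run_survey(marked, protocol, seed=rng)
        surveys.append(res)
        estimates[i] = res.prevalence_estimate
    defined = np.isfinite(estimates)
    within = defined & (np.abs(estimates - true_prev) <= margin)
    return AccuracySummary(
        protocol=protocol,
        n_surveys=n_surveys,
        true_prevalence=true_prev,
        tolerance=tolerance,
        tolerance_mode=tolerance_mode,
        prob_within_tolerance=float(within.mean()),
        estimates=estimates,
        within_tolerance=within,
        surveys=surveys,
        n_undefined=int((~defined).sum()),
    )


def power_experiment(
    summary: AccuracySummary, n_pairs: int = 100, alpha: float = 0.05, seed=None
) -> list[PowerPoint]:
    """Achieved power and Cliff's delta for random pairs of surveys.

    Each of ``n_pairs`` draws picks two distinct surveys (pairs with an
    undefined estimate are redrawn); power is evaluated at the two pooled
    prevalence estimates with the pooled colony counts as sample sizes, and
    the effect size is Cliff's delta on the per-transect prevalence values.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = as_rng(seed)
    ok = [
        i
        for i, s in enumerate(summary.surveys)
        if s.prevalence_defined and s.unique_total >= 2
    ]
    if len(ok) < 2:
        raise ValueError("need at least 2 surveys with defined estimates")
    ok = np.asarray(ok)
    points: list[PowerPoint] = []
    for _ in range(n_pairs):
        i, j = rng.choice(ok, size=2, replace=False)
        a, b = summary.surveys[i], summary.surveys[j]
        power = power_two_proportions(
            a.prevalence_estimate, b.prevalence_estimate,
            a.unique_total, b.unique_total, alpha,
        )
        pa = a.transect_prevalences
        pb = b.transect_prevalences
        delta = cliffs_delta(pa[np.isfinite(pa)], pb[np.isfinite(pb)])
        points.append(
            PowerPoint(
                effect_size=delta,
                achieved_power=power,
                n1=a.unique_total,
                n2=b.unique_total,
                p1=a.prevalence_estimate,
                p2=b.prevalence_estimate,
                pair=(int(i), int(j)),
            )
        )
    return points


@dataclass(eq=False)
class PowerCurve:
    """Monotone fitted curve: predicted power as a function of |delta|."""

    x_: np.ndarray
    y_: np.ndarray

    def __call__(self, grid) -> np.ndarray:
        g = np.atleast_1d(np.asarray(grid, dtype=float))
        out = np.interp(g, self.x_, self.y_)
        return np.clip(out, 1e-9, 1.0 - 1e-9)


def smooth_power_curve(points) -> PowerCurve:
    """Monotone (isotonic) smoother of achieved power on |Cliff's delta|.

    Predictions are non-decreasing in |delta| and clamped to (0, 1).
    """
    from sklearn.isotonic import IsotonicRegression

    if len(points) < 10:
        raise ValueError("need at least 10 power points to fit a curve")
    x = np.asarray([abs(p.effect_size) for p in points], dtype=float)
    y = np.asarray([p.achieved_power for p in points], dtype=float)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip")
    iso.fit(x, y)
    order = np.argsort(x)
    xs = x[order]
    ys = iso.predict(xs)
    return PowerCurve(xs, ys)


def accuracy_to_csv(summary: AccuracySummary, path) -> None:
    rows = []
    for i, s in enumerate(summary.surveys):
        rows.append(
            {
                "survey": i,
                "estimate": s.prevalence_estimate,
                "lower": s.prevalence_interval.lower if s.prevalence_interval else np.nan,
                "upper": s.prevalence_interval.upper if s.prevalence_interval else np.nan,
                "n_total": s.unique_total,
                "n_diseased": s.unique_diseased,
                "within_tolerance": int(summary.within_tolerance[i]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def power_to_csv(points, path) -> None:
    pd.DataFrame(
        [
            {
                "pair": i,
                "delta": p.effect_size,
                "power": p.achieved_power,
                "n1": p.n1,
                "n2": p.n2,
                "p1": p.p1,
                "p2": p.p2,
            }
            for i, p in enumerate(points)
        ]
    ).to_csv(path, index=False, float_format="%.6f")
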