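"""Disease marking of colony patterns.

Two transmission modes are modeled:

* random (water-borne): every colony is diseased independently with the
  same probability, i.i.d. Bernoulli(prevalence);
* contagious: a colony's disease probability decreases with its
  nearest-neighbor distance.  The nearest-neighbor distances are cut into
  strata at empirical quantiles (default levels 0.5, 0.7, 0.8, 0.9, 0.99),
  each stratum carries a relative weight that decreases with distance, and a
  single calibration constant scales the weights so that the mean per-point
  probability equals the target prevalence exactly.

Both modes are single-pass markings (no iterative epidemic): contagion uses
the distance to the nearest neighbor of any disease status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .pointprocess import Frame, PointPattern, as_rng, nearest_neighbor_distances

__all__ = [
    "MarkedPattern",
    "ContagionSpec",
    "CalibrationError",
    "DEFAULT_CONTAGION_SPEC",
    "mark_random",
    "mark_contagious",
    "contagion_probabilities",
    "write_marked_csv",
    "read_marked_csv",
]


class CalibrationError(ValueError):
    """Target prevalence cannot be met by the contagion weight profile."""


@dataclass(frozen=True, eq=False)
class MarkedPattern:
    """A point pattern plus a boolean diseased flag per point."""

    pattern: PointPattern
    diseased: np.ndarray

    def __post_init__(self) -> None:
        flags = np.asarray(self.diseased, dtype=bool).reshape(-1)
        if flags.shape[0] != self.pattern.n:
            raise ValueError("diseased flags must match the point count")
        object.__setattr__(self, "diseased", flags)

    @property
    def n(self) -> int:
        return self.pattern.n

    @property
    def n_diseased(self) -> int:
        return int(self.diseased.sum())

    @property
    def prevalence(self) -> float:
        """Realized prevalence, diseased count / total count."""
        return self.n_diseased / self.n if self.n else float("nan")


@dataclass(frozen=True)
class ContagionSpec:
    """Nearest-neighbor-distance contagion profile.

    percentile_breaks : strictly increasing quantile levels in (0, 1) of the
        NN-distance distribution; they bound ``len(breaks) + 1`` strata.
    stratum_weights   : positive relative disease-probability weights, one per
        stratum, decreasing with distance.
    target_prevalence : desired mean per-point disease probability.
    """

    percentile_breaks: tuple = (0.5, 0.7, 0.8, 0.9, 0.99)
    stratum_weights: tuple = (0.99, 0.9, 0.8, 0.7, 0.5, 0.25)
    target_prevalence: float = 0.162

    def __post_init__(self) -> None:
        b = np.asarray(self.percentile_breaks, dtype=float)
        w = np.asarray(self.stratum_weights, dtype=float)
        if b.ndim != 1 or np.any(b <= 0) or np.any(b >= 1) or np.any(np.diff(b) <= 0):
            raise ValueError("percentile_breaks must be strictly increasing in (0, 1)")
        if w.shape[0] != b.shape[0] + 1:
            raise ValueError("need one weight per stratum (len(breaks) + 1)")
        if np.any(w <= 0):
            raise ValueError("stratum weights must be positive")
        if not 0 <= self.target_prevalence <= 1:
            raise ValueError("target_prevalence must be in [0, 1]")


DEFAULT_CONTAGION_SPEC = ContagionSpec()


def mark_random(pattern: PointPattern, prevalence: float, seed=None) -> MarkedPattern:
    """Mark colonies i.i.d. Bernoulli(prevalence)."""
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    rng = as_rng(seed)
    flags = rng.random(pattern.n) < prevalence
    return MarkedPattern(pattern, flags)


def contagion_probabilities(pattern: PointPattern, spec: ContagionSpec) -> np.ndarray:
    """Calibrated per-point disease probabilities under the contagion spec.

    The mean of the returned probabilities equals ``spec.target_prevalence``
    (to numerical precision).  If the uncapped linear calibration would push
    any probability above 1, the scale constant is re-solved with capping at
    1 so the mean still matches the target.
    """
    nn = nearest_neighbor_distances(pattern)
    breaks = np.quantile(nn, spec.percentile_breaks)
    # side="left": a distance exactly on a boundary joins the lower (closer) stratum
    strata = np.searchsorted(breaks, nn, side="left")
    w = np.asarray(spec.stratum_weights, dtype=float)[strata]
    target = spec.target_prevalence
    if target == 0:
        return np.zeros_like(w)
    if target > 1:
        raise CalibrationError("target prevalence above 1 is infeasible")
    c = target / w.mean()
    if c * w.max() <= 1.0:
        return c * w

    # capped calibration: mean(min(1, c w)) = target, solved by root finding
    def gap(cc: float) -> float:
        return np.minimum(1.0, cc * w).mean() - target

    hi = 1.0 / w.min()
    if gap(hi) < 0:
        raise CalibrationError(
            f"target prevalence {target} is infeasible for this weight profile"
        )
    c = brentq(gap, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    return np.minimum(1.0, c * w)


def mark_contagious(pattern: PointPattern, spec: ContagionSpec, seed=None) -> MarkedPattern:
    """Mark colonies with NN-distance-dependent probabilities (single pass)."""
    rng = as_rng(seed)
    p = contagion_probabilities(pattern, spec)
    flags = rng.random(pattern.n) < p
    return MarkedPattern(pattern, flags)


def write_marked_csv(marked: MarkedPattern, path) -> None:
    """Write ``x,y,diseased`` (coordinates to 6 dp, diseased in {0,1})."""
    frame = marked.pattern.frame
    with open(path, "w") as fh:
        fh.write(f"# frame: {frame.width!r} {frame.height!r}\n")
        df = pd.DataFrame(marked.pattern.points, columns=["x", "y"])
        df["diseased"] = marked.diseased.astype(int)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_marked_csv(path, frame: Frame | None = None) -> MarkedPattern:
    if frame is None:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# frame:"):
            w, h = first.split(":", 1)[1].split()
            frame = Frame(float(w), float(h))
        else:
            raise ValueError("no frame header in CSV; pass frame= explicitly")
    df = pd.read_csv(path, comment="#")
    if not {"x", "y", "diseased"}.issubset(df.columns):
        raise ValueError("marked CSV must have columns x,y,diseased")
    pattern = PointPattern(frame, df[["x", "y"]].to_numpy(dtype=float))
    return MarkedPattern(pattern, df["diseased"].to_numpy(dtype=int).astype(bool))
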