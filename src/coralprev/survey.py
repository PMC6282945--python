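"""Virtual belt-transect surveys.

A survey deploys square stations (default 100 x 100 m) uniformly at random in
the frame, then axis-aligned belt-transects uniformly at random inside each
station (independent placements; overlap is permitted).  Colonies are counted
by the center-in rule with half-open transect edges, so abutting transects
partition points.  Counts are pooled across transects for the density and
prevalence estimates; when transects overlap, each colony contributes to every
transect it falls in for the per-transect bookkeeping, but the pooled
prevalence is computed on distinct colonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .disease import MarkedPattern
from .inference import BinomialInterval, wilson_interval
from .pointprocess import Frame, as_rng

__all__ = [
    "Station",
    "Transect",
    "Protocol",
    "TransectCount",
    "SurveyResult",
    "InfeasibleGeometryError",
    "FIGURE_PROTOCOLS",
    "FIELD_PROTOCOL",
    "place_stations",
    "place_transects",
    "count_in_transect",
    "run_survey",
    "survey_to_csv",
]


class InfeasibleGeometryError(RuntimeError):
    """Requested survey geometry cannot be realized in the frame."""


@dataclass(frozen=True)
class Station:
    """Square survey site; ``(x, y)`` is the lower-left origin (m)."""

    x: float
    y: float
    side: float = 100.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.side / 2.0, self.y + self.side / 2.0)


@dataclass(frozen=True)
class Transect:
    """Axis-aligned belt-transect; long side along x by convention."""

    x: float
    y: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("transect dimensions must be positive")

    @property
    def area(self) -> float:
        return self.length * self.width


@dataclass(frozen=True)
class Protocol:
    """Survey protocol: stations per survey and transects per station."""

    n_stations: int
    transects_per_station: int
    transect_length: float
    transect_width: float
    station_side: float = 100.0
    min_station_separation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.transects_per_station < 1:
            raise ValueError("station and transect counts must be >= 1")
        if self.transect_length <= 0 or self.transect_width <= 0:
            raise ValueError("transect dimensions must be positive")

    @property
    def sampled_area(self) -> float:
        return (
            self.n_stations
            * self.transects_per_station
            * self.transect_length
            * self.transect_width
        )


# The four single-station, five-transect protocols most common in the
# disease-survey literature, and the 4-station x 6-transect field protocol.
FIGURE_PROTOCOLS = {
    "10x1": Protocol(1, 5, 10.0, 1.0),
    "10x2": Protocol(1, 5, 10.0, 2.0),
    "25x2": Protocol(1, 5, 25.0, 2.0),
    "50x2": Protocol(1, 5, 50.0, 2.0),
}
FIELD_PROTOCOL = Protocol(4, 6, 25.0, 2.0)


@dataclass(frozen=True)
class TransectCount:
    station: int
    transect: int
    n_total: int
    n_diseased: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_diseased <= self.n_total:
            raise ValueError("need 0 <= n_diseased <= n_total")


@dataclass(eq=False)
class SurveyResult:
    """Counts and pooled estimates from one survey.

    ``pooled_total`` / ``pooled_diseased`` are sums of the per-transect
    counts; ``unique_total`` / ``unique_diseased`` deduplicate colonies that
    fall in more than one (overlapping) transect and are the basis of the
    prevalence estimate.  ``prevalence_defined`` is False when no colony was
    counted (the estimate is NaN, not an exception).
    """

    protocol: Protocol
    per_transect: list
    pooled_total: int
    pooled_diseased: int
    unique_total: int
    unique_diseased: int
    density_estimate: float
    prevalence_estimate: float
    prevalence_interval: BinomialInterval | None
    prevalence_defined: bool
    transect_prevalences: np.ndarray = field(default_factory=lambda: np.empty(0))


def place_stations(
    frame: Frame,
    n: int,
    side: float = 100.0,
    min_separation: float = 0.0,
    seed=None,
    max_attempts: int = 10_000,
) -> list[Station]:
    """Uniform random stations, rejection-resampled for center separation.

    Draws all ``n`` origins uniformly over positions keeping the square in
    the frame and redraws the whole set until all pairwise center distances
    reach ``min_separation``, up to ``max_attempts`` redraws.
    """
    if n < 1:
        raise ValueError("need at least one station")
    if side > frame.width or side > frame.height:
        raise InfeasibleGeometryError(
            f"station side {side} does not fit the {frame.width}x{frame.height} frame"
        )
    rng = as_rng(seed)
    for _ in range(max_attempts):
        ox = rng.uniform(0.0, frame.width - side, n)
        oy = rng.uniform(0.0, frame.height - side, n)
        if n > 1 and min_separation > 0:
            centers = np.column_stack([ox + side / 2.0, oy + side / 2.0])
            if pdist(centers).min() < min_separation:
                continue
        return [Station(float(x), float(y), side) for x, y in zip(ox, oy)]
    raise InfeasibleGeometryError(
        f"could not place {n} stations with center separation >= {min_separation} m "
        f"in a {frame.width}x{frame.height} m frame after {max_attempts} attempts"
    )


def place_transects(
    station: Station, n: int, length: float, width: float, seed=None
) -> list[Transect]:
    """Independent uniform transects inside the station (overlap permitted)."""
    if length > station.side or width > station.side:
        raise ValueError("transect does not fit inside the station")
    rng = as_rng(seed)
    ox = station.x + rng.uniform(0.0, station.side - length, n)
    oy = station.y + rng.uniform(0.0, station.side - width, n)
    return [Transect(float(x), float(y), length, width) for x, y in zip(ox, oy)]


def _transect_indices(marked: MarkedPattern, transect: Transect) -> np.ndarray:
    pts = marked.pattern.points
    mask = (
        (pts[:, 0] >= transect.x)
        & (pts[:, 0] < transect.x + transect.length)
        & (pts[:, 1] >= transect.y)
        & (pts[:, 1] < transect.y + transect.width)
    )
    return np.flatnonzero(mask)


def count_in_transect(marked: MarkedPattern, transect: Transect) -> TransectCount:
    """Center-in counts with half-open edges (a point on a shared edge is
    counted in exactly one of two abutting transects)."""
    idx = _transect_indices(marked, transect)
    return TransectCount(0, 0, int(idx.size), int(marked.diseased[idx].sum()))


def run_survey(marked: MarkedPattern, protocol: Protocol, seed=None) -> SurveyResult:
    """Place stations and transects, count colonies, pool the estimates."""
    rng = as_rng(seed)
    stations = place_stations(
        marked.pattern.frame,
        protocol.n_stations,
        protocol.station_side,
        protocol.min_station_separation,
        seed=rng,
    )
    pts = marked.pattern.points
    counts: list[TransectCount] = []
    all_idx: list[np.ndarray] = []
    prevs: list[float] = []
    for si, st in enumerate(stations):
        # pre-filter to the station square so transect masks work on a small subset
        smask = (
            (pts[:, 0] >= st.x)
            & (pts[:, 0] < st.x + st.side)
            & (pts[:, 1] >= st.y)
            & (pts[:, 1] < st.y + st.side)
        )
        sidx = np.flatnonzero(smask)
        spts = pts[sidx]
        transects = place_transects(
            st, protocol.transects_per_station, protocol.transect_length,
            protocol.transect_width, seed=rng,
        )
        for ti, tr in enumerate(transects):
            tmask = (
                (spts[:, 0] >= tr.x)
                & (spts[:, 0] < tr.x + tr.length)
                & (spts[:, 1] >= tr.y)
                & (spts[:, 1] < tr.y + tr.width)
            )
            idx = sidx[tmask]
            n_tot = int(idx.size)
            n_dis = int(marked.diseased[idx].sum())
            counts.append(TransectCount(si, ti, n_tot, n_dis))
            all_idx.append(idx)
            prevs.append(n_dis / n_tot if n_tot else np.nan)

    pooled_total = sum(c.n_total for c in counts)
    pooled_diseased = sum(c.n_diseased for c in counts)
    uniq = np.unique(np.concatenate(all_idx)) if all_idx else np.empty(0, dtype=int)
    unique_total = int(uniq.size)
    unique_diseased = int(marked.diseased[uniq].sum())
    density = pooled_total / protocol.sampled_area
    defined = unique_total > 0
    prevalence = unique_diseased / unique_total if defined else float("nan")
    interval = wilson_interval(unique_diseased, unique_total) if defined else None
    return SurveyResult(
        protocol=protocol,
        per_transect=counts,
        pooled_total=pooled_total,
        pooled_diseased=pooled_diseased,
        unique_total=unique_total,
        unique_diseased=unique_diseased,
        density_estimate=density,
        prevalence_estimate=prevalence,
        prevalence_interval=interval,
        prevalence_defined=defined,
        transect_prevalences=np.asarray(prevs),
    )


def survey_to_csv(result: SurveyResult, path) -> None:
    """One row per transect plus a pooled summary row."""
    rows = [
        {
            "station": c.station,
            "transect": c.transect,
            "n_total": c.n_total,
            "n_diseased": c.n_diseased,
        }
        for c in result.per_transect
    ]
    rows.append(
        {
            "station": "pooled",
            "transect": "",
            "n_total": result.pooled_total,
            "n_diseased": result.pooled_diseased,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
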