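"""Scenario assembly and synthetic field-data fixtures.

A :class:`Scenario` bundles one spatial pattern type (random / clustered /
over-dispersed) with one transmission mode (random / contagious) plus all
generative parameters, mirroring the six study conditions labeled
R/C/D x rt/ct.  ``make_field_fixture`` builds a synthetic per-transect field
table (negative-binomial colony counts, binomial diseased counts) whose
defaults reproduce, in expectation, the reference field survey's summaries:
24 belt-transects over 1,200 m^2, 756 colonies, 16.2% prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disease import (
    DEFAULT_CONTAGION_SPEC,
    ContagionSpec,
    MarkedPattern,
    mark_contagious,
    mark_random,
)
from .pointprocess import (
    DEFAULT_CLUSTER_PARAMS,
    DEFAULT_FRAME,
    DEFAULT_INHIBITION_PARAMS,
    ClusterParams,
    Frame,
    InhibitionParams,
    generate_clustered,
    generate_inhibited,
    generate_poisson,
)

__all__ = [
    "Scenario",
    "FieldTable",
    "FIELD_TOTAL_COLONIES",
    "FIELD_N_TRANSECTS",
    "FIELD_SAMPLED_AREA",
    "FIELD_PREVALENCE",
    "DEFAULT_INTENSITY",
    "density_from_field_summary",
    "build_scenario",
    "default_scenarios",
    "make_field_fixture",
    "load_field_table",
    "save_field_table",
]

# Reference field survey summaries (Orbicella faveolata, yellow-band syndrome):
# 756 colonies in 24 belt-transects of 25 x 2 m (1,200 m^2), prevalence 16.2%.
FIELD_TOTAL_COLONIES = 756
FIELD_N_TRANSECTS = 24
FIELD_SAMPLED_AREA = 1200.0
FIELD_PREVALENCE = 0.162


def density_from_field_summary(
    total_colonies: int = FIELD_TOTAL_COLONIES, sampled_area: float = FIELD_SAMPLED_AREA
) -> float:
    """Colony density implied by a field summary: colonies / sampled area."""
    if sampled_area <= 0:
        raise ValueError("sampled area must be positive")
    return total_colonies / sampled_area


# 756 / 1,200 m^2 = 0.63 colonies per m^2, the simulation intensity.
DEFAULT_INTENSITY = density_from_field_summary()

_PATTERN_CODE = {"random": "R", "clustered": "C", "over-dispersed": "D"}
_TRANSMISSION_CODE = {"random": "rt", "contagious": "ct"}

FieldTable = pd.DataFrame  # columns: station, transect, n_total, n_diseased


@dataclass(frozen=True)
class Scenario:
    """One simulated study condition (pattern type x transmission mode)."""

    pattern_type: str = "random"
    transmission: str = "random"
    intensity: float = DEFAULT_INTENSITY
    target_prevalence: float = FIELD_PREVALENCE
    frame: Frame = DEFAULT_FRAME
    cluster: ClusterParams | None = None
    inhibition: InhibitionParams | None = None
    contagion: ContagionSpec | None = None
    seed: object = 0

    def __post_init__(self) -> None:
        if self.pattern_type not in _PATTERN_CODE:
            raise ValueError(f"unknown pattern_type {self.pattern_type!r}")
        if self.transmission not in _TRANSMISSION_CODE:
            raise ValueError(f"unknown transmission {self.transmission!r}")

    @property
    def label(self) -> str:
        """Short study label, e.g. ``R & rt``."""
        return f"{_PATTERN_CODE[self.pattern_type]} & {_TRANSMISSION_CODE[self.transmission]}"


def _scaled_cluster_params(scenario: Scenario) -> ClusterParams:
    if scenario.cluster is not None:
        return scenario.cluster
    base = DEFAULT_CLUSTER_PARAMS
    # keep the default offspring count and dispersal, rescale parents so the
    # nominal overall intensity matches the scenario intensity
    return ClusterParams(
        scenario.intensity / base.mean_offspring, base.mean_offspring, base.offspring_sd
    )


def build_scenario(scenario: Scenario) -> MarkedPattern:
    """Generate and mark the population a scenario describes.

    Pattern and marking seeds are spawned from ``scenario.seed``, so a fixed
    scenario (including seed) is fully deterministic.
    """
    if isinstance(scenario.seed, np.random.SeedSequence):
        ss = scenario.seed
    else:
        ss = np.random.SeedSequence(scenario.seed)
    pattern_seed, mark_seed = ss.spawn(2)
    if scenario.pattern_type == "random":
        pattern = generate_poisson(scenario.frame, scenario.intensity, pattern_seed)
    elif scenario.pattern_type == "clustered":
        pattern = generate_clustered(scenario.frame, _scaled_cluster_params(scenario), pattern_seed)
    else:
        params = scenario.inhibition or DEFAULT_INHIBITION_PARAMS
        pattern = generate_inhibited(scenario.frame, scenario.intensity, params, pattern_seed)
    if scenario.transmission == "random":
        return mark_random(pattern, scenario.target_prevalence, mark_seed)
    spec = scenario.contagion or ContagionSpec(
        target_prevalence=scenario.target_prevalence
    )
    return mark_contagious(pattern, spec, mark_seed)


def default_scenarios(seed=0, frame: Frame = DEFAULT_FRAME) -> list[Scenario]:
    """The six study conditions (R/C/D x rt/ct) at default parameters."""
    scenarios = []
    for i, pattern_type in enumerate(_PATTERN_CODE):
        for j, transmission in enumerate(_TRANSMISSION_CODE):
            scenarios.append(
                Scenario(
                    pattern_type=pattern_type,
                    transmission=transmission,
                    frame=frame,
                    seed=np.random.SeedSequence(entropy=seed, spawn_key=(i, j)),
                )
            )
    return scenarios


def make_field_fixture(
    n_stations: int = 4,
    transects_per_station: int = 6,
    mean_count: float = FIELD_TOTAL_COLONIES / FIELD_N_TRANSECTS,
    count_dispersion: float = 5.0,
    prevalence: float = FIELD_PREVALENCE,
    seed=None,
) -> FieldTable:
    """Synthetic per-transect field table emulating the reference survey.

    Per-transect totals are negative-binomial (gamma-Poisson) with the given
    mean and shape (``count_dispersion``; larger is closer to Poisson), and
    diseased counts are binomial(total, prevalence).  Defaults give 756
    colonies and 16.2% prevalence in expectation.
    """
    if min(n_stations, transects_per_station) < 1:
        raise ValueError("station and transect counts must be >= 1")
    if mean_count <= 0 or count_dispersion <= 0:
        raise ValueError("mean_count and count_dispersion must be positive")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    p_nb = count_dispersion / (count_dispersion + mean_count)
    for s in range(n_stations):
        totals = rng.negative_binomial(count_dispersion, p_nb, transects_per_station)
        diseased = rng.binomial(totals, prevalence)
        for t in range(transects_per_station):
            rows.append(
                {
                    "station": s + 1,
                    "transect": t + 1,
                    "n_total": int(totals[t]),
                    "n_diseased": int(diseased[t]),
                }
            )
    return pd.DataFrame(rows)


def save_field_table(table: FieldTable, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)


def load_field_table(path) -> FieldTable:
    """Read and validate a ``station,transect,n_total,n_diseased`` CSV."""
    df = pd.read_csv(path, comment="#")
    required = ["station", "transect", "n_total", "n_diseased"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"field table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("field table is empty")
    bad = df.index[df["n_diseased"] > df["n_total"]].tolist()
    if bad:
        raise ValueError(f"n_diseased > n_total in rows {[i + 2 for i in bad]} (1-based file lines)")
    if (df["n_total"] < 0).any() or (df["n_diseased"] < 0).any():
        raise ValueError("counts must be non-negative")
    if df.duplicated(subset=["station", "transect"]).any():
        raise ValueError("station/transect ids must be unique")
    return df[required].copy()
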