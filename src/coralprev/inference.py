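"""Interval estimation and survey-vs-field GLM comparisons.

Prevalence intervals use the Wilson score interval (the score-test inversion
for a binomial proportion, well behaved at boundary counts).  Field-vs-survey
comparisons follow standard practice for this kind of data: per-transect
colony counts are compared with a negative-binomial GLM on group membership,
and per-transect disease fractions with a quasi-binomial GLM (binomial family
with a Pearson-estimated dispersion factor and t-based tests).  Each
comparison carries a validity diagnostic: a residual-deviance overdispersion
test for the count model, and a simulated envelope on standardized deviance
residuals (half-normal plot logic) for the proportion model.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaincc

__all__ = [
    "BinomialInterval",
    "ComparisonResult",
    "ScenarioComparisonSummary",
    "wilson_interval",
    "dispersion_pvalue",
    "compare_counts",
    "compare_prevalence",
    "scenario_table",
]


@dataclass(frozen=True)
class BinomialInterval:
    estimate: float
    lower: float
    upper: float
    confidence: float
    method: str = "wilson"


@dataclass(frozen=True)
class ComparisonResult:
    """Group-effect test between field and simulated transects.

    ``dispersion_ok`` reports the family's validity diagnostic; ``valid`` is
    False when the data were too degenerate to fit at all.
    """

    p_value: float
    dispersion_ok: bool
    family: str
    valid: bool = True
    note: str = ""


@dataclass(frozen=True)
class ScenarioComparisonSummary:
    scenario: str
    pct_density_diff: float
    pct_prevalence_diff: float
    n_trials: int
    n_invalid_density: int = 0
    n_invalid_prevalence: int = 0


def wilson_interval(successes: int, trials: int, confidence: float = 0.95) -> BinomialInterval:
    """Closed-form Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise ValueError("Wilson interval is undefined for zero trials")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n = float(trials)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2.0 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    # boundary counts have exact closed-form endpoints; avoid rounding drift
    lower = 0.0 if successes == 0 else max(0.0, float(center - half))
    upper = 1.0 if successes == trials else min(1.0, float(center + half))
    return BinomialInterval(estimate=phat, lower=lower, upper=upper, confidence=confidence)


def dispersion_pvalue(residual_deviance: float, residual_df: int) -> float:
    """Upper-tail chi-square probability of the residual deviance.

    Values near 0 signal overdispersion relative to the fitted family.
    """
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if residual_deviance < 0:
        raise ValueError("residual deviance must be >= 0")
    return float(gammaincc(residual_df / 2.0, residual_deviance / 2.0))


def _group_design(n_field: int, n_sim: int) -> np.ndarray:
    g = np.concatenate([np.zeros(n_field), np.ones(n_sim)])
    return np.column_stack([np.ones_like(g), g])


def compare_counts(field_counts, sim_counts, alpha: float = 0.05) -> ComparisonResult:
    """Negative-binomial GLM test of a density difference between groups.

    The NB dispersion parameter is estimated by maximum likelihood (with a
    method-of-moments fallback near the Poisson boundary); the group effect
    is a Wald test.  ``dispersion_ok`` is True when the residual-deviance
    overdispersion test is not significant at ``alpha``.
    """
    import statsmodels.api as sm

    y = np.concatenate([np.asarray(field_counts, float), np.asarray(sim_counts, float)])
    n_f, n_s = len(np.atleast_1d(field_counts)), len(np.atleast_1d(sim_counts))
    if n_f < 2 or n_s < 2:
        raise ValueError("each group needs at least 2 transects")
    if y.max() == 0:
        return ComparisonResult(np.nan, False, "negative-binomial", valid=False,
                                note="all counts are zero")
    X = _group_design(n_f, n_s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                nb = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
                alpha_nb = float(nb.params[-1])
            except Exception:
                m, v = y.mean(), y.var(ddof=1)
                alpha_nb = (v - m) / (m * m) if m > 0 else 0.0
            alpha_nb = float(np.clip(alpha_nb, 1e-8, 1e4))
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha_nb)).fit()
    except Exception as exc:  # pragma: no cover - degenerate numerical failure
        return ComparisonResult(np.nan, False, "negative-binomial", valid=False, note=str(exc))
    p = float(res.pvalues[1])
    disp_ok = dispersion_pvalue(float(res.deviance), int(res.df_resid)) > alpha
    return ComparisonResult(p, disp_ok, "negative-binomial")


def _pearson_dispersion(res) -> float:
    """Quasi-likelihood dispersion: Pearson chi-square / residual df."""
    return max(float(res.pearson_chi2) / float(res.df_resid), 1e-12)


def _standardized_deviance_residuals(res) -> np.ndarray:
    """Deviance residuals standardized by leverage, d_i / sqrt(1 - h_ii)."""
    h = np.clip(res.get_hat_matrix_diag(), 0.0, 1.0 - 1e-9)
    return np.asarray(res.resid_deviance, float) / np.sqrt(1.0 - h)


def _quasibinomial_envelope_ok(
    res, totals: np.ndarray, X: np.ndarray, n_sims: int, rng: np.random.Generator,
    max_above_frac: float = 0.2,
) -> bool:
    """Half-normal-plot envelope check on standardized deviance residuals.

    Simulates ``n_sims`` datasets from the fitted binomial model, refits, and
    builds a pointwise min/max envelope of the sorted absolute standardized
    deviance residuals.  Overdispersion inflates the observed residuals, so
    the fit is flagged when more than ``max_above_frac`` of the observed order
    statistics exceed the upper envelope (under a correct binomial model a few
    percent do by chance; moderate overdispersion pushes most of them out).
    """
    import statsmodels.api as sm

    obs = np.sort(np.abs(_standardized_deviance_residuals(res)))
    mu = np.asarray(res.fittedvalues, float)
    sims = np.empty((n_sims, obs.size))
    for s in range(n_sims):
        y = rng.binomial(totals.astype(int), mu)
        endog = np.column_stack([y, totals - y])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        sims[s] = np.sort(np.abs(_standardized_deviance_residuals(r)))
    hi = sims.max(axis=0)
    above = np.mean(obs > hi + 1e-9)
    return bool(above <= max_above_frac)


def compare_prevalence(
    field, sim, alpha: float = 0.05, seed=None, n_envelope_sims: int = 19
) -> ComparisonResult:
    """Quasi-binomial GLM test of a prevalence difference between groups.

    ``field`` and ``sim`` are sequences of ``(diseased, total)`` per transect;
    transects with zero total are dropped.  Standard errors are inflated by
    the Pearson dispersion estimate and the group effect is a t-test on the
    residual degrees of freedom, matching quasi-likelihood practice.
    """
    import statsmodels.api as sm

    from .pointprocess import as_rng

    f = np.asarray(field, dtype=float).reshape(-1, 2)
    s = np.asarray(sim, dtype=float).reshape(-1, 2)
    f = f[f[:, 1] > 0]
    s = s[s[:, 1] > 0]
    if f.shape[0] < 2 or s.shape[0] < 2:
        return ComparisonResult(np.nan, False, "quasibinomial", valid=False,
                                note="fewer than 2 non-empty transects in a group")
    dis = np.concatenate([f[:, 0], s[:, 0]])
    tot = np.concatenate([f[:, 1], s[:, 1]])
    if dis.sum() == 0 or dis.sum() == tot.sum():
        return ComparisonResult(np.nan, False, "quasibinomial", valid=False,
                                note="degenerate prevalence (all 0 or all 1)")
    X = _group_design(f.shape[0], s.shape[0])
    endog = np.column_stack([dis, tot - dis])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover
        return ComparisonResult(np.nan, False, "quasibinomial", valid=False, note=str(exc))
    # quasi-likelihood: inflate the binomial SE by the Pearson dispersion and
    # test the group effect against t on the residual df
    phi = _pearson_dispersion(res)
    bse = float(res.bse[1]) * np.sqrt(phi)
    if bse == 0 or not np.isfinite(bse):
        p = 1.0 if res.params[1] == 0 else 0.0
    else:
        tval = float(res.params[1]) / bse
        p = float(2.0 * stats.t.sf(abs(tval), int(res.df_resid)))
    disp_ok = _quasibinomial_envelope_ok(res, tot, X, n_envelope_sims, as_rng(seed))
    return ComparisonResult(p, disp_ok, "quasibinomial")


def scenario_table(
    field_table,
    scenarios,
    n_trials: int,
    protocol,
    alpha: float = 0.05,
    seed=None,
) -> list[ScenarioComparisonSummary]:
    """Percentage of virtual surveys differing significantly from field data.

    For each scenario: generate the population once, run ``n_trials``
    independent surveys with the given protocol, compare each trial's
    per-transect counts (negative-binomial GLM) and disease fractions
    (quasi-binomial GLM) against the field table, and report the percentage
    of significant results among valid comparisons.
    """
    from .fixtures import build_scenario
    from .survey import run_survey

    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    field_counts = np.asarray(field_table["n_total"], dtype=float)
    field_pairs = np.column_stack(
        [np.asarray(field_table["n_diseased"], float), field_counts]
    )
    if field_counts.size < 2:
        raise ValueError("field table needs at least 2 transects")
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else None) \
        if not isinstance(seed, np.random.SeedSequence) else seed
    summaries = []
    for scenario in scenarios:
        pop_seed, *trial_seeds = ss.spawn(n_trials + 1)
        marked = build_scenario(dataclasses.replace(scenario, seed=pop_seed))
        sig_d = val_d = sig_p = val_p = 0
        for t_seed in trial_seeds:
            result = run_survey(marked, protocol, seed=t_seed)
            sim_counts = [c.n_total for c in result.per_transect]
            sim_pairs = [(c.n_diseased, c.n_total) for c in result.per_transect]
            cc = compare_counts(field_counts, sim_counts, alpha)
            if cc.valid:
                val_d += 1
                sig_d += cc.p_value < alpha
            cp = compare_prevalence(field_pairs, sim_pairs, alpha, seed=t_seed)
            if cp.valid:
                val_p += 1
                sig_p += cp.p_value < alpha
        summaries.append(
            ScenarioComparisonSummary(
                scenario=scenario.label,
                pct_density_diff=100.0 * sig_d / val_d if val_d else float("nan"),
                pct_prevalence_diff=100.0 * sig_p / val_p if val_p else float("nan"),
                n_trials=n_trials,
                n_invalid_density=n_trials - val_d,
                n_invalid_prevalence=n_trials - val_p,
            )
        )
    return summaries
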