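"""Predicted upper limits by resampling, and the equilibrium test.

The predicted upper elevational limit (UELp) of a species is the mean outer
border over repeated HOF fits to stratified subsamples of its
presence/absence-along-elevation series: each of ``n_reps`` (default 100)
replicates draws 25% of the suitable-zone presences and 25% of the
unsuitable-zone absences without replacement, refits the seven-model family
with AIC selection, and extracts the outer border. The spread of those
borders yields a 95% confidence interval; a species whose observed UEL
falls inside the interval is judged to be in climatic equilibrium,
otherwise it sits below (most common) or above its climatic potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hof

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedUEL:
    """Resampling distribution of the outer border for one species."""

    species: str
    ob_samples: np.ndarray
    mean_ob: float
    median_ob: float
    ci_low: float
    ci_high: float
    ci_low_normal: float
    ci_high_normal: float
    n_censored: int
    n_failed: int
    unstable: bool = False


@dataclass(frozen=True)
class EquilibriumResult:
    """Observed vs predicted limit for one species."""

    species: str
    observed_uel: float
    predicted: PredictedUEL
    classification: str  # below | equilibrium | above | undetermined
    delta_std: float


def resample_ob(elev, y_obs, species: str = "", frac: float = 0.25,
                n_reps: int = 100, seed: int = 0, n_starts: int = 10,
                min_presences: int = 5, replace: bool = False) -> PredictedUEL:
    """Resampling distribution of the outer border.

    Each replicate draws ceil(frac * n1) presences and ceil(frac * n0)
    absences, stratified (never a joint subsample, so sparse presences keep
    representation), fits the HOF family and extracts the outer border.
    Censored-at-top borders are retained at the top of the gradient and
    counted rather than dropped (dropping would bias the interval
    downward). If more than half the replicates fail, the species is marked
    unstable and no interval is reported.
    """
    elev = np.asarray(elev, dtype=float)
    y_obs = np.asarray(y_obs, dtype=int)
    pres = np.flatnonzero(y_obs == 1)
    absn = np.flatnonzero(y_obs == 0)
    need = int(np.ceil(1.0 / frac))
    if len(pres) < need or len(absn) < need:
        raise hof.UnfittableSeries(
            f"need at least {need} presences and absences for frac={frac}")
    n1 = int(np.ceil(frac * len(pres)))
    n0 = int(np.ceil(frac * len(absn)))

    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(2**31 - 1))  # shared: same subsample -> same fit
    obs, n_censored, n_failed = [], 0, 0
    for rep in range(n_reps):
        take1 = rng.choice(pres, size=n1, replace=replace)
        take0 = rng.choice(absn, size=n0, replace=replace)
        idx = np.sort(np.concatenate([take1, take0]))
        try:
            fit = hof.select_model(elev[idx], y_obs[idx], n_starts=n_starts,
                                   seed=fit_seed,
                                   min_presences=min(min_presences, n1))
            ob, censored = hof.outer_border(fit)
        except (hof.UnfittableSeries, ValueError) as exc:
            logger.debug("%s replicate %d failed: %s", species, rep, exc)
            n_failed += 1
            continue
        n_censored += int(censored)
        obs.append(ob)

    obs = np.asarray(obs, dtype=float)
    if n_failed > n_reps / 2 or obs.size == 0:
        logger.warning("%s: %d/%d replicates failed; marked unstable",
                       species, n_failed, n_reps)
        return PredictedUEL(species=species, ob_samples=obs,
                            mean_ob=np.nan, median_ob=np.nan,
                            ci_low=np.nan, ci_high=np.nan,
                            ci_low_normal=np.nan, ci_high_normal=np.nan,
                            n_censored=n_censored, n_failed=n_failed,
                            unstable=True)
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
    lo, hi = np.percentile(obs, [2.5, 97.5])
    return PredictedUEL(species=species, ob_samples=obs, mean_ob=mean,
                        median_ob=float(np.median(obs)),
                        ci_low=float(lo), ci_high=float(hi),
                        ci_low_normal=mean - 1.96 * sd,
                        ci_high_normal=mean + 1.96 * sd,
                        n_censored=n_censored, n_failed=n_failed)


def standardized_delta(uelo: float, uelp: float) -> float:
    """|UELo - UELp| / UELp: scale-free observed-vs-predicted mismatch."""
    if not uelp > 0:
        raise ValueError("predicted UEL must be positive")
    return abs(uelo - uelp) / uelp


def classify_equilibrium(observed_uel: float, predicted: PredictedUEL) -> EquilibriumResult:
    """Equilibrium test: is the observed limit inside the predicted 95% CI?

    below / above mean the observed limit falls under / over the interval;
    species without a usable interval are 'undetermined'.
    """
    if predicted.unstable or not np.isfinite(predicted.ci_low):
        return EquilibriumResult(species=predicted.species,
                                 observed_uel=observed_uel, predicted=predicted,
                                 classification="undetermined", delta_std=np.nan)
    if observed_uel < predicted.ci_low:
        cls = "below"
    elif observed_uel > predicted.ci_high:
        cls = "above"
    else:
        cls = "equilibrium"
    return EquilibriumResult(species=predicted.species, observed_uel=observed_uel,
                             predicted=predicted, classification=cls,
                             delta_std=standardized_delta(observed_uel,
                                                          predicted.mean_ob))


def cohort_summary(results: list[EquilibriumResult]) -> pd.DataFrame:
    """Counts and integer percentages per equilibrium class."""
    if not results:
        raise ValueError("no results to summarize")
    counts = {"below": 0, "equilibrium": 0, "above": 0, "undetermined": 0}
    for r in results:
        counts[r.classification] += 1
    determined = sum(v for k, v in counts.items() if k != "undetermined")
    rows = []
    for cls in ("below", "equilibrium", "above"):
        pct = round(100.0 * counts[cls] / determined) if determined else np.nan
        rows.append({"class": cls, "count": counts[cls], "percent": pct})
    if counts["undetermined"]:
        rows.append({"class": "undetermined", "count": counts["undetermined"],
                     "percent": np.nan})
    return pd.DataFrame(rows)


def results_table(results: list[EquilibriumResult]) -> pd.DataFrame:
    """Flat per-species results: observed, predicted, CI, class, delta."""
    rows = []
    for r in results:
        p = r.predicted
        rows.append({
            "species": r.species, "uel_observed": r.observed_uel,
            "uel_predicted": p.mean_ob, "uel_predicted_median": p.median_ob,
            "ci_low": p.ci_low, "ci_high": p.ci_high,
            "ci_low_normal": p.ci_low_normal, "ci_high_normal": p.ci_high_normal,
            "class": r.classification, "delta_std": r.delta_std,
            "n_censored": p.n_censored, "n_failed": p.n_failed,
        })
    return pd.DataFrame(rows)
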