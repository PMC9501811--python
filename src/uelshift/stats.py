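"""Comparative statistics for observed and predicted range limits.

Three analyses: (i) did the observed upper limits change between two survey
epochs (rank-based Wilcoxon tests, exact for small samples); (ii) does the
observed limit track the climatically predicted limit across species (OLS
with a test of slope = 1 — equilibrium predicts the identity line); and
(iii) do species attributes (residence time, dispersal mode, life span)
explain limit changes or the observed-predicted mismatch (sequential
ANOVA on a linear model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

DISPERSAL_MODES = ("wind", "animal", "non-assisted")
LIFE_SPANS = ("annual", "biennial", "perennial")

EXACT_N_MAX = 10  # exact null enumeration up to this sample size


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    se_slope: float
    r2: float
    t_corr: float
    p_corr: float
    t_slope1: float
    p_slope1: float

    @property
    def df(self) -> int:
        return self.n - 2


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for the first sample (R's unpaired W), via midranks."""
    ranks = _midranks(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _signed_rank_statistic(d: np.ndarray) -> float:
    """Sum of ranks of |d| over positive differences (zeros dropped)."""
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = _midranks(np.abs(d))
    return float(ranks[d > 0].sum())


def wilcoxon_uel(uel_a, uel_b, paired: bool = False,
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-based test comparing two epochs of upper limits.

    Unpaired (default): rank-sum / Mann-Whitney, statistic W = U of the
    first sample, matching R's ``wilcox.test(x, y)``. Paired: signed-rank
    on the differences, zeros dropped. Ties get midranks. The null is
    enumerated exactly when both samples have at most 10 observations (and,
    paired, at most 10 nonzero differences); larger samples use the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(uel_a, dtype=float)
    y = np.asarray(uel_b, dtype=float)
    if paired and x.shape != y.shape:
        raise ValueError("paired test needs matched vectors")
    if min(x.size, y.size) < 3:
        raise ValueError("need n >= 3 per sample")

    if paired:
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return 0.0, 1.0
        stat = _signed_rank_statistic(d)
        ranks = _midranks(np.abs(nz))
        n = nz.size
        if n <= EXACT_N_MAX:
            null = np.array([ranks[list(signs)].sum() if signs else 0.0
                             for m in range(n + 1)
                             for signs in combinations(range(n), m)])
            p = _enumerated_p(stat, null, alternative)
        else:
            mu = n * (n + 1) / 4.0
            _, tie_counts = np.unique(ranks, return_counts=True)
            var = (n * (n + 1) * (2 * n + 1) / 24.0
                   - np.sum(tie_counts**3 - tie_counts) / 48.0)
            p = _normal_p(stat, mu, var, alternative)
        return stat, p

    stat = _rank_sum_statistic(x, y)
    n1, n2 = x.size, y.size
    if max(n1, n2) <= EXACT_N_MAX:
        pooled = np.concatenate([x, y])
        ranks = _midranks(pooled)
        offset = n1 * (n1 + 1) / 2.0
        null = np.array([ranks[list(c)].sum() - offset
                         for c in combinations(range(n1 + n2), n1)])
        p = _enumerated_p(stat, null, alternative)
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        nt = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / (nt * (nt - 1))
        var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
        p = _normal_p(stat, mu, var, alternative)
    return stat, p


def _enumerated_p(stat, null, alternative):
    tol = 1e-9
    if alternative == "greater":
        return float(np.mean(null >= stat - tol))
    if alternative == "less":
        return float(np.mean(null <= stat + tol))
    mu = null.mean()
    return min(1.0, float(2.0 * min(np.mean(null >= stat - tol),
                                    np.mean(null <= stat + tol))))


def _normal_p(stat, mu, var, alternative):
    sd = np.sqrt(var)
    if sd == 0:
        return 1.0
    if alternative == "greater":
        z = (stat - mu - 0.5) / sd
        return float(sps.norm.sf(z))
    if alternative == "less":
        z = (stat - mu + 0.5) / sd
        return float(sps.norm.cdf(z))
    z = (abs(stat - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def classify_change(uel_first: float, uel_second: float,
                    stability_threshold: float = 0.0) -> str:
    """'up' / 'down' / 'stable' from the between-epoch elevation change.

    ``stability_threshold`` (m) absorbs survey quantization: changes with
    |delta| <= threshold count as stable. Either epoch missing raises.
    """
    if not (np.isfinite(uel_first) and np.isfinite(uel_second)):
        raise ValueError("both epochs must be observed")
    delta = uel_second - uel_first
    if abs(delta) <= stability_threshold:
        return "stable"
    return "up" if delta > 0 else "down"


def change_summary(uel_table: pd.DataFrame, year_a: int, year_b: int,
                   stability_threshold: float = 0.0) -> pd.DataFrame:
    """Per-species temporal records with change classes; species missing an
    epoch are excluded with a log entry."""
    wide = uel_table.pivot_table(index="species", columns="year",
                                 values="observed_uel", aggfunc="max")
    rows = []
    for species, row in wide.iterrows():
        a, b = row.get(year_a, np.nan), row.get(year_b, np.nan)
        if not (np.isfinite(a) and np.isfinite(b)):
            logger.info("%s missing an epoch; excluded from change analysis",
                        species)
            continue
        rows.append({"species": species, f"uel_{year_a}": a, f"uel_{year_b}": b,
                     "delta": b - a,
                     "change_class": classify_change(a, b, stability_threshold)})
    return pd.DataFrame(rows)


def regress_obs_pred(observed, predicted) -> RegressionResult:
    """OLS of observed on predicted limits, with the slope-vs-1 test.

    t_corr tests r = 0 (is there a relationship at all); t_slope1 =
    (1 - b) / se(b) tests b = 1 (does the observed limit track the
    predicted one one-for-one, as climatic equilibrium requires). Both use
    df = n - 2, two-sided p.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    r2 = float(model.rsquared)
    df = x.size - 2
    r = np.sign(slope) * np.sqrt(r2)
    t_corr = r * np.sqrt(df / max(1.0 - r2, 1e-300))
    # a slope of 1 to machine precision is the null itself: t is exactly 0
    t_slope1 = 0.0 if np.isclose(slope, 1.0, rtol=0, atol=1e-10) else (1.0 - slope) / se
    return RegressionResult(
        n=x.size, slope=slope, intercept=float(model.params[0]), se_slope=se,
        r2=r2, t_corr=float(t_corr),
        p_corr=float(2.0 * sps.t.sf(abs(t_corr), df)),
        t_slope1=float(t_slope1),
        p_slope1=float(2.0 * sps.t.sf(abs(t_slope1), df)))


def trait_model(response, traits: pd.DataFrame, typ: int = 1) -> pd.DataFrame:
    """Sequential ANOVA of a response on residence time, dispersal, life span.

    Fits ``response ~ residence_time + dispersal_mode + life_span`` and
    returns the Type-I (sequential, term order as written — Df pattern
    1/2/2 when all levels occur) ANOVA table; ``typ=2`` gives Type-II sums
    of squares. Rows with missing response or traits are dropped listwise;
    single-level factors are dropped with a warning.
    """
    data = traits.copy()
    data["response"] = np.asarray(response, dtype=float)
    data = data.dropna(subset=["response", "residence_time",
                               "dispersal_mode", "life_span"])
    terms = ["residence_time"]
    for factor in ("dispersal_mode", "life_span"):
        if data[factor].nunique() < 2:
            warnings.warn(f"{factor} has a single level; dropped", stacklevel=2)
        else:
            terms.append(f"C({factor})")
    n_params = 1 + 1 + sum(data[f].nunique() - 1
                           for f in ("dispersal_mode", "life_span")
                           if f"C({f})" in terms)
    if len(data) <= n_params:
        raise ValueError("more parameters than observations")
    model = smf.ols("response ~ " + " + ".join(terms), data=data).fit()
    table = anova_lm(model, typ=typ)
    table.index = [i.replace("C(", "").replace(")", "") for i in table.index]
    return table
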