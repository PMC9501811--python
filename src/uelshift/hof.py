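"""Huisman-Olff-Fresco (HOF) response curves for presence/absence data.

The HOF family is a hierarchy of seven bounded response shapes along an
environmental gradient, built from products of logistic terms: flat (I),
monotone sigmoid (II), sigmoid with a plateau below the maximum (III),
symmetric unimodal (IV), skewed unimodal (V) and bimodal (VI, VII). Here
the gradient is elevation, the response is the probability that a point is
climatically suitable, and fitting is by maximum Bernoulli likelihood with
bounded multi-start quasi-Newton optimization; the best shape is selected
by AIC.

The quantity of interest is the *outer border* (OB): the highest elevation
at which the fitted response still reaches exp(-2) of its maximum — the
predicted upper elevational limit on the descending side of the curve.

All model equations act on the gradient rescaled to [0, 1]. With x_scaling
(x_min, x_max) and u = (x - x_min)/(x_max - x_min):

    I    y = 1 / (1 + e^a)
    II   y = 1 / (1 + e^(a+bu))
    III  y = 1 / (1 + e^(a+bu)) * 1 / (1 + e^c)
    IV   y = 1 / (1 + e^(a+bu)) * 1 / (1 + e^(c-bu))
    V    y = 1 / (1 + e^(a+bu)) * 1 / (1 + e^(c-du))
    VI   y = clip(h(u) + h(u - f), 0, 1),        h = the model-IV hump
    VII  y = clip(h(u) + r * h(u - f), 0, 1)

Published parameterizations of the bimodal types vary; here the second hump
shares the shape parameters of the first, shifted along the gradient by f,
with type VII adding an independent height ratio r. That choice is isolated
in :func:`_hump` / :func:`_response_raw`.

Parameter bounds keep the exponentials finite: b, d in (0, 200] on the unit
gradient, and |a|, |c| <= 250 so a sigmoid at full steepness can place its
inflection anywhere on the gradient (the inflection of type II sits at
u = -a/b, so |a| must be allowed to reach b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import qmc

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII"}
PARAM_NAMES = {
    1: ("a",),
    2: ("a", "b"),
    3: ("a", "b", "c"),
    4: ("a", "b", "c"),
    5: ("a", "b", "c", "d"),
    6: ("a", "b", "c", "f"),
    7: ("a", "b", "c", "f", "r"),
}
#: free-parameter count per type (M is fixed at 1 for presence/absence)
N_PARAMS = {t: len(names) for t, names in PARAM_NAMES.items()}

_A_BOUND = 250.0
_B_MIN, _B_MAX = 1e-3, 200.0
BOUNDS = {
    "a": (-_A_BOUND, _A_BOUND),
    "b": (_B_MIN, _B_MAX),
    "c": (-_A_BOUND, _A_BOUND),
    "d": (_B_MIN, _B_MAX),
    "f": (0.0, 1.0),
    "r": (0.0, 1.0),
}
_EPS = 1e-9


def _sigma(t: np.ndarray) -> np.ndarray:
    """1 / (1 + e^t), overflow-safe."""
    return 1.0 / (1.0 + np.exp(np.clip(t, -500.0, 500.0)))


def _hump(u, a, b, c):
    """The model-IV unimodal hump and its partials (incl. d/du)."""
    y1 = _sigma(a + b * u)
    y3 = _sigma(c - b * u)
    h = y1 * y3
    da = -y1 * (1.0 - y1) * y3
    db = u * h * (y1 - y3)
    dc = -h * (1.0 - y3)
    du = b * h * (y1 - y3)
    return h, da, db, dc, du


def _response_raw(model_type: int, params: np.ndarray, u: np.ndarray):
    """Response y(u) and gradient dy/dparams.

    ``params`` may be a single parameter vector (k,) giving y of shape (n,)
    and gradient (n, k), or a batch (S, k) giving (S, n) and (S, n, k) —
    the batched form lets all multi-start candidates share one objective
    evaluation. The gradient is exact including the [0, 1] clip of the
    bimodal types (zero where the clip is active).
    """
    u = np.asarray(u, dtype=float)
    params = np.asarray(params, dtype=float)
    # pull each parameter as shape (1,) or (S, 1) so it broadcasts against u
    col = (lambda j: params[..., [j]]) if params.ndim == 2 else (lambda j: params[[j]])
    ones = np.ones_like(u)
    if model_type == 1:
        y = _sigma(col(0)) * ones
        grad = (-y * (1.0 - y))[..., None]
        return y, grad
    if model_type == 2:
        a, b = col(0), col(1)
        y = _sigma(a + b * u)
        g = -y * (1.0 - y)
        return y, np.stack([g, u * g], axis=-1)
    if model_type == 3:
        a, b, c = col(0), col(1), col(2)
        y1 = _sigma(a + b * u)
        y2 = _sigma(c) * ones
        y = y1 * y2
        g1 = -y1 * (1.0 - y1) * y2
        return y, np.stack([g1, u * g1, -y1 * y2 * (1.0 - y2)], axis=-1)
    if model_type == 4:
        h, da, db, dc, _ = _hump(u, col(0), col(1), col(2))
        return h, np.stack([da, db, dc], axis=-1)
    if model_type == 5:
        a, b, c, d = col(0), col(1), col(2), col(3)
        y1 = _sigma(a + b * u)
        y3 = _sigma(c - d * u)
        y = y1 * y3
        da = -y1 * (1.0 - y1) * y3
        dc = -y * (1.0 - y3)
        return y, np.stack([da, u * da, dc, -u * dc], axis=-1)
    if model_type in (6, 7):
        a, b, c, f = col(0), col(1), col(2), col(3)
        r = col(4) if model_type == 7 else 1.0
        h1, da1, db1, dc1, _ = _hump(u, a, b, c)
        h2, da2, db2, dc2, du2 = _hump(u - f, a, b, c)
        raw = h1 + r * h2
        y = np.clip(raw, 0.0, 1.0)
        active = (raw < 1.0).astype(float)  # clip only binds at 1; humps >= 0
        cols = [(da1 + r * da2) * active, (db1 + r * db2) * active,
                (dc1 + r * dc2) * active, (-r * du2) * active]
        if model_type == 7:
            cols.append(h2 * active)
        return y, np.stack(cols, axis=-1)
    raise ValueError(f"unknown HOF model type {model_type}")


@dataclass(frozen=True)
class HOFFit:
    """One fitted HOF response model on an elevation gradient."""

    model_type: int
    params: np.ndarray
    x_scaling: tuple[float, float]
    logL: float
    k: int
    aic: float
    y_max: float
    flags: tuple[str, ...] = ()

    @property
    def type_name(self) -> str:
        return ROMAN[self.model_type]

    def param_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.model_type], map(float, self.params)))


def _to_unit(x, x_scaling):
    x_min, x_max = x_scaling
    span = x_max - x_min
    if span <= 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    return (np.asarray(x, dtype=float) - x_min) / span


def response(fit: HOFFit, x) -> np.ndarray:
    """Fitted occurrence probability at elevation(s) x."""
    u = _to_unit(x, fit.x_scaling)
    y, _ = _response_raw(fit.model_type, fit.params, np.atleast_1d(u))
    return y if np.ndim(x) else float(y[0])


def negloglik(model_type: int, params, elev_u: np.ndarray, y_obs: np.ndarray) -> float:
    """Bernoulli negative log-likelihood of a presence/absence series.

    Probabilities are clipped to [1e-9, 1 - 1e-9] so perfect separation
    yields a finite (near-zero) value rather than -inf.
    """
    p, _ = _response_raw(model_type, np.asarray(params, dtype=float), elev_u)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.sum(y_obs * np.log(p) + (1.0 - y_obs) * np.log1p(-p)))


def _nll_and_grad(params, model_type, u, y_obs):
    p_raw, grad = _response_raw(model_type, params, u)
    p = np.clip(p_raw, _EPS, 1.0 - _EPS)
    nll = -np.sum(y_obs * np.log(p) + (1.0 - y_obs) * np.log1p(-p))
    w = (p - y_obs) / (p * (1.0 - p))
    w = np.where(p_raw == p, w, 0.0)  # clip active -> zero gradient
    return float(nll), grad.T @ w


def _stacked_nll_and_grad(flat, model_type, u, y_obs, n_starts, k):
    """Sum of independent per-start NLLs: one L-BFGS-B run polishes every
    start simultaneously (the objective is separable, so each block walks
    to its own local optimum)."""
    P = flat.reshape(n_starts, k)
    p_raw, grad = _response_raw(model_type, P, u)          # (S,n), (S,n,k)
    p = np.clip(p_raw, _EPS, 1.0 - _EPS)
    nll = -np.sum(y_obs * np.log(p) + (1.0 - y_obs) * np.log1p(-p), axis=1)
    w = (p - y_obs) / (p * (1.0 - p))
    w = np.where(p_raw == p, w, 0.0)
    g = np.einsum("sn,snk->sk", w, grad)
    return float(nll.sum()), g.ravel()


class UnfittableSeries(Exception):
    """Raised when a presence/absence series cannot support HOF fitting."""


def _check_series(elev, y_obs, min_presences):
    elev = np.asarray(elev, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if elev.shape != y_obs.shape or elev.ndim != 1 or elev.size == 0:
        raise ValueError("presence/absence series must be matched 1-D vectors")
    n1 = int(y_obs.sum())
    if n1 < min_presences:
        raise UnfittableSeries(f"{n1} presences < minimum {min_presences}")
    return elev, y_obs, n1


def fit_model(model_type: int, elev, y_obs, n_starts: int = 10, seed: int = 0,
              min_presences: int = 5) -> HOFFit:
    """Fit one HOF type by bounded multi-start maximum likelihood.

    Starts are a Latin-hypercube sample of the parameter box (seeded, so
    refits are bit-identical); each start is polished with L-BFGS-B using
    analytic gradients, and the best likelihood wins. A series with fewer
    than ``min_presences`` presences raises :class:`UnfittableSeries`.
    """
    elev, y_obs, n1 = _check_series(elev, y_obs, min_presences)
    flags = []
    if n1 == y_obs.size:
        flags.append("all_presences")
    x_min, x_max = float(elev.min()), float(elev.max())
    u = _to_unit(elev, (x_min, x_max))

    if model_type == 1:
        # closed-form MLE: flat response at the observed prevalence
        p_hat = float(np.clip(y_obs.mean(), _sigma(np.asarray([_A_BOUND]))[0],
                              _sigma(np.asarray([-_A_BOUND]))[0]))
        a_hat = float(np.clip(np.log(1.0 / p_hat - 1.0), -_A_BOUND, _A_BOUND))
        best_x = np.array([a_hat])
        best_nll = negloglik(1, best_x, u, y_obs)
    else:
        names = PARAM_NAMES[model_type]
        lo = np.array([BOUNDS[n][0] for n in names])
        hi = np.array([BOUNDS[n][1] for n in names])
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts = lo + sampler.random(n_starts) * (hi - lo)
        # keep starting points in the informative core of the box: extreme
        # steepness or offset gives a flat likelihood and wasted starts
        for j, n in enumerate(names):
            if n in ("b", "d"):
                starts[:, j] = _B_MIN + (starts[:, j] - _B_MIN) * (60.0 / _B_MAX)
            elif n in ("a", "c"):
                starts[:, j] *= 30.0 / _A_BOUND
        k = len(names)
        res = optimize.minimize(
            _stacked_nll_and_grad, starts.ravel(),
            args=(model_type, u, y_obs, n_starts, k), jac=True,
            method="L-BFGS-B", bounds=list(zip(lo, hi)) * n_starts,
            options={"maxiter": 150, "ftol": 1e-8})
        cand = res.x.reshape(n_starts, k)
        nlls = np.array([negloglik(model_type, c, u, y_obs) for c in cand])
        best = int(np.argmin(nlls))
        best_nll, best_x = float(nlls[best]), cand[best]

    k = N_PARAMS[model_type]
    lattice = np.linspace(0.0, 1.0, 1001)
    y_lat, _ = _response_raw(model_type, best_x, lattice)
    return HOFFit(model_type=model_type, params=np.asarray(best_x, dtype=float),
                  x_scaling=(x_min, x_max), logL=-best_nll, k=k,
                  aic=2.0 * k + 2.0 * best_nll, y_max=float(y_lat.max()),
                  flags=tuple(flags))


def select_model(elev, y_obs, n_starts: int = 10, seed: int = 0,
                 min_presences: int = 5,
                 model_types: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)) -> HOFFit:
    """Fit all seven HOF types and return the minimum-AIC fit.

    AIC ties (difference < 1e-6) go to the model with fewer parameters,
    then the lower type number.
    """
    fits = [fit_model(t, elev, y_obs, n_starts=n_starts, seed=seed + t,
                      min_presences=min_presences) for t in model_types]
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic - 1e-6:
            best = f
        elif abs(f.aic - best.aic) <= 1e-6 and (f.k, f.model_type) < (best.k, best.model_type):
            best = f
    return best


def outer_border(fit: HOFFit, rel_level: float = np.exp(-2.0),
                 lattice_step: float = 1.0,
                 tol: float = 0.1) -> tuple[float, bool]:
    """The predicted upper limit: highest elevation with y >= exp(-2)*y_max.

    The response is scanned on an elevation lattice no coarser than
    ``lattice_step`` (1 m); the descending crossing is then refined by
    bisection to ``tol`` (0.1 m). If the response is still above the
    threshold at the top of the gradient the border is censored there and
    ``(x_max, True)`` is returned.
    """
    if fit.y_max <= 0:
        raise ValueError("degenerate fit: y_max = 0")
    x_min, x_max = fit.x_scaling
    span = x_max - x_min
    n = max(int(np.ceil(span / lattice_step)) + 1, 2)
    xs = np.linspace(x_min, x_max, n)
    y = response(fit, xs)
    thr = rel_level * float(np.max(y))
    above = y >= thr
    if not above.any():
        # numerically possible only when y_max on the 1 m lattice undershoots
        return x_max, True
    i = int(np.flatnonzero(above)[-1])
    if i == n - 1:
        return float(x_max), True
    lo, hi = xs[i], xs[i + 1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if response(fit, np.asarray([mid]))[0] >= thr:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi)), False
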