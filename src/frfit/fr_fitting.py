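"""Maximum-likelihood fitting, model selection and bootstrap intervals.

Consumption counts are modelled as binomial: for a trial offering ``n0``
prey, ``ne ~ Binomial(n0, p)`` with ``p = Ne_hat / n0`` and ``Ne_hat`` the
depletion-corrected prediction of the chosen functional-response family.
This is the standard likelihood for depletion designs in which each prey is
independently at risk over the trial.

Fitting is done on log-transformed rate/time parameters (``log a``,
``log b``, ``log c``, ``log h``) so positivity holds without box
constraints; the scaling exponent ``q`` is left untransformed and
unconstrained. Standard errors come from the inverse numerical Hessian at
the optimum (delta method back to the natural scale), Wald z and two-sided
normal p-values from estimate/SE.

Model selection follows a three-step protocol:

1. an advisory polynomial-logistic shape test (:mod:`frfit.shape_test`);
2. the flexible-exponent model is fitted with ``q`` free and with ``q``
   fixed at 0 (i.e. Rogers type II) and the two are compared by AIC, with
   near-ties (|dAIC| below a threshold, default 2) resolved toward the model
   with fewer parameters;
3. if the flexible model wins, a Hassell type-III fit is added and the
   generalized response is retained only if its AIC beats the type-III AIC.

Confidence intervals use a nonparametric bootstrap that resamples trials
with replacement, stratified by initial density (the design's fixed factor),
refitting each resample; percentile intervals are the default, with BCa as
an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, lambertw
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from . import fr_models
from .errors import FitError, NumericalError
from .fr_models import FRModelSpec, max_feeding_rate
from .shape_test import ShapeTestResult, fit_shape_test
from .trial_data import TrialSet

__all__ = [
    "FRFitResult",
    "BootstrapResult",
    "SelectionResult",
    "neg_log_likelihood",
    "fit_fr",
    "select_model",
    "bootstrap_ci",
    "wald_stats",
]

_P_CLIP = 1e-9
_ALPHA_SIG = 0.05


def wald_stats(estimate: float, se: float) -> Tuple[float, float]:
    """Wald statistic and two-sided normal p-value for estimate/SE."""
    if not se > 0:
        raise ValueError(f"standard error must be positive (got {se})")
    z = estimate / se
    return float(z), float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# likelihood machinery


def _binom_const(n0: np.ndarray, ne: np.ndarray) -> float:
    """Sum of log binomial coefficients log C(n0, ne) (parameter-free)."""
    return float(
        np.sum(gammaln(n0 + 1) - gammaln(ne + 1) - gammaln(n0 - ne + 1))
    )


def neg_log_likelihood(spec: FRModelSpec, ts: TrialSet) -> float:
    """Binomial negative log-likelihood of a parameterized family.

    Predicted consumption probabilities are clipped to
    ``[1e-9, 1 - 1e-9]``; invalid parameters yield ``+inf`` rather than an
    exception so the value is always optimizer-safe.
    """
    ts.require_nonempty()
    df = ts.to_frame()
    n0 = df["n0"].to_numpy(dtype=float)
    ne = df["ne"].to_numpy(dtype=float)
    t = df["t_expose"].to_numpy(dtype=float)
    try:
        pred = np.asarray(spec.predict(n0, t), dtype=float)
    except (ValueError, NumericalError, OverflowError):
        return float("inf")
    if not np.all(np.isfinite(pred)):
        return float("inf")
    p = np.clip(pred / n0, _P_CLIP, 1.0 - _P_CLIP)
    ll = _binom_const(n0, ne) + float(
        np.sum(ne * np.log(p) + (n0 - ne) * np.log1p(-p))
    )
    return -ll


@dataclass
class _Aggregate:
    """Sufficient statistics of a trial set for density-only predictors."""

    u: np.ndarray       # unique initial densities
    counts: np.ndarray  # trials per density
    s_eaten: np.ndarray     # sum of ne per density
    s_missed: np.ndarray    # sum of n0 - ne per density
    const: float        # summed log binomial coefficients
    t: float


def _aggregate(ts: TrialSet) -> _Aggregate:
    df = ts.to_frame()
    n0 = df["n0"].to_numpy(dtype=float)
    ne = df["ne"].to_numpy(dtype=float)
    u, inv = np.unique(n0, return_inverse=True)
    counts = np.bincount(inv, minlength=u.size).astype(float)
    s_eaten = np.bincount(inv, weights=ne, minlength=u.size)
    s_missed = counts * u - s_eaten
    return _Aggregate(u, counts, s_eaten, s_missed, _binom_const(n0, ne), ts.t_expose)


def _rogers_fast(a, h: float, u: np.ndarray, t: float) -> np.ndarray:
    """Rogers solution on the unique-density grid, optimizer hot path.

    Same arithmetic as :func:`frfit.fr_models.predict_rogers2` (Lambert W
    plus one Newton polish, bisection where W's argument would overflow)
    but without validation/broadcast overhead. ``a`` is a positive scalar or
    per-density vector; ``h``, ``t`` are scalars with ``h >= 0``, ``t > 0``.
    """
    if h == 0.0:
        return u * (-np.expm1(-a * t))
    x = a * h * u
    expo = x - a * t
    if np.all(expo < 700.0):
        ne = u - lambertw(x * np.exp(expo)).real / (a * h)
        e = np.exp(np.minimum(a * (h * ne - t), 700.0))
        ne = ne - (ne - u * (1.0 - e)) / (1.0 + u * a * h * e)
        return np.clip(ne, 0.0, u)
    return fr_models._rogers_core(a, h, u, t)


def _family_setup(family: str, fix_q: Optional[float]):
    """Resolve (reported family, fitted parameter names, predictor).

    ``fix_q = 0`` on the flexible family is exactly the Rogers type-II model
    (with ``a = b``) and is reported as such.
    """
    if family not in fr_models.FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if fix_q is not None and family != "flexq":
        raise ValueError("fix_q only applies to the flexq family")
    if family == "flexq" and fix_q is not None and fix_q == 0:
        family, fix_q = "rogers2", None

    if family == "holling2":
        return family, ("a", "h"), (
            lambda p, u, t: p["a"] * u * t / (1.0 + p["a"] * p["h"] * u)
        )
    if family == "rogers2":
        return family, ("a", "h"), (
            lambda p, u, t: _rogers_fast(p["a"], p["h"], u, t)
        )
    if family == "flexq":
        qv = None if fix_q is None else float(fix_q)

        def _flexq_pred(p, u, t, _q=qv):
            q = p["q"] if _q is None else _q
            with np.errstate(over="ignore"):
                a = p["b"] * u**q
            if not np.all(np.isfinite(a)):
                raise ValueError("attack rate overflow")
            return _rogers_fast(a, p["h"], u, t)

        names = ("b", "q", "h") if fix_q is None else ("b", "h")
        return family, names, _flexq_pred

    # hassell3 fitted with baseline attack d pinned at 0 (the classic
    # b N0 / (1 + c N0) attack-rate form); d is only a reduction device.
    return family, ("b", "c", "h"), (
        lambda p, u, t: _rogers_fast(
            p["b"] * u / (1.0 + p["c"] * u), p["h"], u, t
        )
    )


def _pack(names: Sequence[str], values: Dict[str, float]) -> np.ndarray:
    return np.array(
        [values[n] if n == "q" else math.log(values[n]) for n in names]
    )


def _unpack(names: Sequence[str], theta: np.ndarray) -> Dict[str, float]:
    out = {}
    for name, v in zip(names, theta):
        out[name] = float(v) if name == "q" else float(np.exp(v))
    return out


def _make_objective(
    agg: _Aggregate,
    names: Sequence[str],
    predictor: Callable,
    family: Optional[str] = None,
) -> Callable[[np.ndarray], float]:
    u, s1, s0, t = agg.u, agg.s_eaten, agg.s_missed, agg.t
    const = agg.const  # summed log binomial coefficients

    def nll(theta: np.ndarray) -> float:
        params = _unpack(names, theta)
        if not all(np.isfinite(v) for v in params.values()):
            return float("inf")
        try:
            pred = np.asarray(predictor(params, u, t), dtype=float)
        except (ValueError, NumericalError, OverflowError):
            return float("inf")
        if not np.all(np.isfinite(pred)):
            return float("inf")
        p = np.clip(pred / u, _P_CLIP, 1.0 - _P_CLIP)
        val = -const - (s1 @ np.log(p) + s0 @ np.log1p(-p))
        return float(val) if np.isfinite(val) else float("inf")

    if family == "rogers2":
        return _make_objective_rogers(agg, nll)
    return nll


def _make_objective_rogers(
    agg: _Aggregate, generic_nll: Callable
) -> Callable[[np.ndarray], float]:
    """Scalar-math Rogers-II objective for the bootstrap/simulation hot path.

    Identical arithmetic to the generic objective (Lambert W plus one Newton
    polish, same probability clipping) but written with plain floats over
    the handful of unique densities, avoiding small-array numpy overhead.
    Falls back to the generic objective in the Lambert-W overflow regime.
    """
    from math import exp, log, log1p

    u = [float(x) for x in agg.u]
    s1 = [float(x) for x in agg.s_eaten]
    s0 = [float(x) for x in agg.s_missed]
    t = float(agg.t)
    const = float(agg.const)
    kk = len(u)
    p_lo, p_hi = _P_CLIP, 1.0 - _P_CLIP

    def nll(theta) -> float:
        la, lh = float(theta[0]), float(theta[1])
        if la > 700.0 or lh > 700.0:
            return float("inf")
        a, h = exp(la), exp(lh)
        ah = a * h
        tot = -const
        for k in range(kk):
            n0 = u[k]
            ex = ah * n0 - a * t
            if ex >= 700.0:
                return generic_nll(theta)
            if ah > 0.0:
                ne = n0 - lambertw(ah * n0 * exp(ex)).real / ah
                e = exp(min(a * (h * ne - t), 700.0))
                ne -= (ne - n0 * (1.0 - e)) / (1.0 + n0 * ah * e)
            else:
                ne = n0 * -(exp(-a * t) - 1.0)
            if ne < 0.0:
                ne = 0.0
            elif ne > n0:
                ne = n0
            p = ne / n0
            if p < p_lo:
                p = p_lo
            elif p > p_hi:
                p = p_hi
            tot -= s1[k] * log(p) + s0[k] * log1p(-p)
        return tot

    return nll


def _nm_minimize(obj, x0, loose: bool = False):
    # the loose profile is for bootstrap refits, where bound resolution far
    # below the Monte-Carlo error of the percentile is wasted effort
    opts = (
        {"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600}
        if loose
        else {"xatol": 1e-8, "fatol": 1e-11, "maxiter": 5000}
    )
    return minimize(obj, np.asarray(x0, dtype=float), method="Nelder-Mead", options=opts)


def _start_values(
    agg: _Aggregate, names: Sequence[str]
) -> List[Dict[str, float]]:
    """Paper-style starting values: a (or b) = 1 and h = 1/Fmax, where Fmax
    is the mean consumption at the highest density; plus deterministic
    density-scaled extras for the density-dependent families."""
    fmax = agg.s_eaten[-1] / agg.counts[-1]
    h0 = 1.0 / max(fmax, 1.0)
    med = float(np.median(agg.u))
    starts: List[Dict[str, float]] = []
    if names == ("a", "h"):
        starts.append({"a": 1.0, "h": h0})
    elif names == ("b", "h"):
        starts.append({"b": 1.0, "h": h0})
    elif names == ("b", "q", "h"):
        starts.append({"b": 1.0, "q": 0.0, "h": h0})
        starts.append({"b": 1.0 / med, "q": 1.0, "h": h0})
        starts.append({"b": 1.0 / med**2, "q": 2.0, "h": h0})
    else:  # hassell3: a_eff(median density) near 1
        starts.append({"b": 1.0 / med, "c": 0.01, "h": h0})
        starts.append({"b": 1.0 / med, "c": 0.1, "h": h0})
    return starts


@dataclass
class FRFitResult:
    """Maximum-likelihood fit of one functional-response family.

    ``estimates``/``se``/``z``/``p`` are keyed by parameter name on the
    natural scale; ``aic = 2 k - 2 loglik`` with ``k`` fitted parameters;
    ``mfr = 1 / (h T)`` is the maximum feeding rate in prey per day.
    """

    family: str
    estimates: Dict[str, float]
    se: Dict[str, float]
    z: Dict[str, float]
    p: Dict[str, float]
    loglik: float
    aic: float
    mfr: Optional[float]
    converged: bool
    n_trials: int
    t_expose: float
    starts_used: List[Dict[str, float]] = field(default_factory=list)
    n_restarts_used: int = 0
    fix_q: Optional[float] = None

    @property
    def k(self) -> int:
        return len(self.estimates)

    def significant(self, alpha: float = _ALPHA_SIG) -> bool:
        """True if every parameter except ``q`` is Wald-significant."""
        if not self.converged:
            return False
        return all(
            (name == "q") or (np.isfinite(pv) and pv < alpha)
            for name, pv in self.p.items()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": self.family,
                "parameter": name,
                "estimate": self.estimates[name],
                "se": self.se.get(name, float("nan")),
                "z": self.z.get(name, float("nan")),
                "p": self.p.get(name, float("nan")),
            }
            for name in self.estimates
        ]
        df = pd.DataFrame(rows)
        df["mfr"] = self.mfr
        return df


def fit_fr(
    ts: TrialSet,
    family: str,
    fix_q: Optional[float] = None,
    restarts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
) -> FRFitResult:
    """Fit one functional-response family by maximum likelihood.

    Runs Nelder-Mead from the paper-style starting values (``a = 1``,
    ``h = 1/Fmax``, ``q = 0`` plus deterministic density-scaled extras for
    density-dependent families); if no start yields a finite optimum, up to
    ``restarts`` multiplicatively jittered (x U(0.5, 2)) restarts are tried
    before declaring non-convergence. ``converged`` is also withdrawn when
    the numerical Hessian at the optimum is not positive definite — the
    fit's rendering of "no defensible functional-response fit".
    """
    ts.require_nonempty()
    report_family, names, predictor = _family_setup(family, fix_q)
    if report_family == "flexq" and len(ts.densities) < 3:
        raise FitError("flexible-q fits require at least 3 distinct densities")
    agg = _aggregate(ts)
    obj = _make_objective(agg, names, predictor, family=report_family)

    starts = _start_values(agg, names)
    rng = np.random.default_rng(seed)
    best = None
    n_restarts_used = 0
    tried: List[Dict[str, float]] = []

    def _try(start: Dict[str, float]):
        nonlocal best
        tried.append(dict(start))
        res = _nm_minimize(obj, _pack(names, start))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    for start in starts:
        _try(start)
    while (best is None or not best.success) and n_restarts_used < restarts:
        n_restarts_used += 1
        base = starts[(n_restarts_used - 1) % len(starts)]
        jig = {
            k: (v + rng.normal(0.0, 0.5) if k == "q" else v * rng.uniform(0.5, 2.0))
            for k, v in base.items()
        }
        _try(jig)

    if best is None or not np.isfinite(best.fun):
        nan = {n: float("nan") for n in names}
        return FRFitResult(
            family=report_family,
            estimates=nan,
            se=dict(nan),
            z=dict(nan),
            p=dict(nan),
            loglik=float("nan"),
            aic=float("nan"),
            mfr=None,
            converged=False,
            n_trials=len(ts),
            t_expose=agg.t,
            starts_used=tried,
            n_restarts_used=n_restarts_used,
            fix_q=fix_q,
        )

    theta = np.asarray(best.x, dtype=float)
    estimates = _unpack(names, theta)
    loglik = -float(best.fun)
    aic = 2.0 * len(names) - 2.0 * loglik
    mfr = (
        max_feeding_rate(estimates["h"], agg.t)
        if "h" in estimates and estimates["h"] > 0
        else None
    )

    se: Dict[str, float] = {n: float("nan") for n in names}
    zv: Dict[str, float] = {n: float("nan") for n in names}
    pv: Dict[str, float] = {n: float("nan") for n in names}
    converged = bool(best.success)
    if compute_se and converged:
        hess_ok = False
        try:
            H = approx_hess(theta, obj)
            np.linalg.cholesky(H)  # positive-definite check
            cov_theta = np.linalg.inv(H)
            jac = np.array(
                [1.0 if n == "q" else estimates[n] for n in names]
            )
            cov_nat = cov_theta * np.outer(jac, jac)
            diag = np.diag(cov_nat)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                hess_ok = True
                for i, n in enumerate(names):
                    se[n] = float(np.sqrt(diag[i]))
                    zv[n], pv[n] = wald_stats(estimates[n], se[n])
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            hess_ok = False
        converged = converged and hess_ok

    return FRFitResult(
        family=report_family,
        estimates=estimates,
        se=se,
        z=zv,
        p=pv,
        loglik=loglik,
        aic=aic,
        mfr=mfr,
        converged=converged,
        n_trials=len(ts),
        t_expose=agg.t,
        starts_used=tried,
        n_restarts_used=n_restarts_used,
        fix_q=fix_q,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionResult:
    """Outcome of the three-step selection protocol."""

    shape: ShapeTestResult
    fits: Dict[str, FRFitResult]
    chosen: Optional[str]
    final: Optional[FRFitResult]
    evidence: bool
    delta_aic_tie: float

    @property
    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": name,
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
                for name, fit in self.fits.items()
            ]
        )


def select_model(
    ts: TrialSet,
    delta_aic_tie: float = 2.0,
    alpha: float = _ALPHA_SIG,
    restarts: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Run the three-step shape-test / AIC selection protocol.

    Step 1 fits the advisory shape test. Step 2 compares the flexible-q fit
    against the fixed ``q = 0`` (Rogers type II) fit by AIC; an AIC
    difference smaller than ``delta_aic_tie`` counts as a tie and keeps the
    simpler model. Step 3, reached only when the flexible model clearly
    wins, adds a Hassell type-III fit and keeps the generalized response
    only if its AIC beats the type-III AIC. ``evidence`` is False when no
    fitted family converged with all non-``q`` parameters significant at
    ``alpha`` — the "no evidence of any functional response type" outcome.
    """
    shape = fit_shape_test(ts, alpha=alpha)
    flex = fit_fr(ts, "flexq", restarts=restarts, seed=seed)
    fixed = fit_fr(ts, "flexq", fix_q=0.0, restarts=restarts, seed=seed)
    fits: Dict[str, FRFitResult] = {"flexq": flex, "rogers2": fixed}

    chosen: Optional[str] = None
    if flex.converged and fixed.converged:
        if flex.aic - fixed.aic < -delta_aic_tie:
            hass = fit_fr(ts, "hassell3", restarts=restarts, seed=seed)
            fits["hassell3"] = hass
            if hass.converged and hass.aic <= flex.aic:
                chosen = "hassell3"
            else:
                chosen = "flexq"
        else:
            chosen = "rogers2"
    elif fixed.converged:
        chosen = "rogers2"
    elif flex.converged:
        chosen = "flexq"

    final = fits.get(chosen) if chosen else None
    evidence = any(f.significant(alpha) for f in fits.values())
    return SelectionResult(
        shape=shape,
        fits=fits,
        chosen=chosen,
        final=final,
        evidence=evidence,
        delta_aic_tie=delta_aic_tie,
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap confidence intervals for one fit."""

    n_boot: int
    replicate_estimates: Dict[str, np.ndarray]
    ci_lower: Dict[str, float]
    ci_upper: Dict[str, float]
    method: str
    seed: Optional[int]
    frac_nonconverged: float
    unreliable: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": name,
                    "ci_lower": self.ci_lower[name],
                    "ci_upper": self.ci_upper[name],
                }
                for name in self.ci_lower
            ]
        )


def bootstrap_ci(
    ts: TrialSet,
    family: str,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    fix_q: Optional[float] = None,
    point: Optional[FRFitResult] = None,
    method: str = "percentile",
    level: float = 0.95,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap confidence intervals.

    Trials are resampled with replacement within each initial-density
    stratum (the design's fixed factor), each resample is refitted from the
    point estimates, and interval bounds are taken from the converged
    resample distribution (``percentile`` by default, ``bca`` optional).
    More than 50% non-converged resamples flags the interval unreliable.
    """
    if n_boot <= 0:
        raise ValueError(f"n_boot must be a positive integer (got {n_boot})")
    if method not in ("percentile", "bca"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    if point is None:
        point = fit_fr(ts, family, fix_q=fix_q, seed=seed or 0)
    if not point.converged:
        raise FitError("bootstrap requires a converged point fit")

    report_family, names, predictor = _family_setup(family, fix_q)
    df = ts.to_frame()
    n0 = df["n0"].to_numpy(dtype=float)
    ne = df["ne"].to_numpy(dtype=float)
    t = ts.t_expose
    u, inv = np.unique(n0, return_inverse=True)
    strata = [np.flatnonzero(inv == k) for k in range(u.size)]
    counts = np.array([s.size for s in strata], dtype=float)
    x0 = _pack(names, point.estimates)
    rng = np.random.default_rng(seed)

    def _refit(ne_sums: np.ndarray) -> Optional[np.ndarray]:
        agg = _Aggregate(
            u, counts, ne_sums, counts * u - ne_sums, 0.0, t
        )
        obj = _make_objective(agg, names, predictor, family=report_family)
        res = _nm_minimize(obj, x0, loose=True)
        if res.success and np.isfinite(res.fun):
            return np.array([v for v in _unpack(names, res.x).values()])
        return None

    reps: List[np.ndarray] = []
    n_fail = 0
    for _ in range(n_boot):
        sums = np.empty(u.size)
        for k, idx in enumerate(strata):
            pick = rng.integers(0, idx.size, idx.size)
            sums[k] = ne[idx[pick]].sum()
        est = _refit(sums)
        if est is None:
            n_fail += 1
        else:
            reps.append(est)

    frac_fail = n_fail / n_boot
    rep_mat = (
        np.vstack(reps) if reps else np.empty((0, len(names)))
    )
    replicate_estimates = {
        name: rep_mat[:, i] for i, name in enumerate(names)
    }
    alpha2 = (1.0 - level) / 2.0
    ci_lower: Dict[str, float] = {}
    ci_upper: Dict[str, float] = {}
    if rep_mat.shape[0] == 0:
        for name in names:
            ci_lower[name] = float("nan")
            ci_upper[name] = float("nan")
    elif method == "percentile":
        lo = np.percentile(rep_mat, 100 * alpha2, axis=0)
        hi = np.percentile(rep_mat, 100 * (1 - alpha2), axis=0)
        for i, name in enumerate(names):
            ci_lower[name], ci_upper[name] = float(lo[i]), float(hi[i])
    else:  # BCa: bias correction from the resample distribution,
        # acceleration from a leave-one-out jackknife over trials
        jack = []
        for drop in range(len(ne)):
            keep = np.ones(len(ne), dtype=bool)
            keep[drop] = False
            inv_k = inv[keep]
            sums = np.bincount(inv_k, weights=ne[keep], minlength=u.size)
            cts = np.bincount(inv_k, minlength=u.size).astype(float)
            agg = _Aggregate(u, cts, sums, cts * u - sums, 0.0, t)
            res = _nm_minimize(
                _make_objective(agg, names, predictor, family=report_family),
                x0,
                loose=True,
            )
            if res.success and np.isfinite(res.fun):
                jack.append(
                    [v for v in _unpack(names, res.x).values()]
                )
        jack_mat = np.asarray(jack, dtype=float)
        for i, name in enumerate(names):
            theta_hat = point.estimates[name]
            col = rep_mat[:, i]
            prop = np.clip(np.mean(col < theta_hat), 1e-6, 1 - 1e-6)
            z0 = norm.ppf(prop)
            if jack_mat.size:
                jm = jack_mat[:, i]
                dev = jm.mean() - jm
                denom = 6.0 * (dev**2).sum() ** 1.5
                acc = (dev**3).sum() / denom if denom > 0 else 0.0
            else:
                acc = 0.0
            za, zb = norm.ppf(alpha2), norm.ppf(1 - alpha2)
            p_lo = norm.cdf(z0 + (z0 + za) / (1 - acc * (z0 + za)))
            p_hi = norm.cdf(z0 + (z0 + zb) / (1 - acc * (z0 + zb)))
            ci_lower[name] = float(np.percentile(col, 100 * p_lo))
            ci_upper[name] = float(np.percentile(col, 100 * p_hi))

    return BootstrapResult(
        n_boot=n_boot,
        replicate_estimates=replicate_estimates,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        method=method,
        seed=seed,
        frac_nonconverged=frac_fail,
        unreliable=frac_fail > 0.5,
    )
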