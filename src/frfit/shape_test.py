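"""Phenomenological curve-shape test for functional responses.

Following Juliano's classic protocol, the proportion of focal prey consumed
is regressed on polynomial terms of the initial density with a binomial GLM
(logit link). A significantly *negative* linear term indicates a hyperbolic,
type-II-like decline of the consumed proportion with density; a
significantly *positive* linear term indicates the sigmoidal rise of a
type-III / generalized response.

The test is advisory: it distinguishes hyperbolic from sigmoidal shapes but
cannot identify a generalized response, so final model choice is made by
information-criterion comparison in :mod:`frfit.fr_fitting`.

Implementation notes: the density is centered and scaled internally for
numerical conditioning; the cubic and quadratic terms are backward-eliminated
(highest order first) while non-significant, and the linear term is always
retained. The shape call uses the *raw-scale* linear coefficient (mapped back
from the standardized fit with its delta-method SE): it measures the logit
slope at low density, which is what separates an initially declining
(hyperbolic) from an initially rising (sigmoidal) consumed proportion — after
centering, the linear term would instead measure the slope at the mean
density and lose that meaning once higher-order terms are retained.
Coefficients are reported on both scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trial_data import TrialSet

__all__ = ["ShapeTestResult", "fit_shape_test", "classify_shape"]

TERM_NAMES = ("intercept", "linear", "quadratic", "cubic")

HYPERBOLIC = "hyperbolic"
SIGMOIDAL = "sigmoidal"
INDETERMINATE = "indeterminate"


@dataclass
class ShapeTestResult:
    """Polynomial logistic-regression shape test result.

    ``coefficients`` holds the standardized-scale estimates (one row per
    retained term: estimate, SE, z, p); ``coefficients_raw`` the same
    coefficients mapped back to the raw density scale. ``inferred_shape`` is
    ``"hyperbolic"`` (type-II candidate), ``"sigmoidal"`` (type-III /
    generalized candidate) or ``"indeterminate"``.
    """

    coefficients: pd.DataFrame
    coefficients_raw: pd.DataFrame
    retained_degree: int
    inferred_shape: str
    alpha: float
    diagnostic: Optional[str] = None

    @property
    def linear_term(self) -> pd.Series:
        """Raw-scale linear coefficient row (the classification basis)."""
        return self.coefficients_raw.set_index("term").loc["linear"]


def classify_shape(linear_estimate: float, linear_p: float, alpha: float = 0.05) -> str:
    """Shape call from the retained linear coefficient.

    Negative and significant -> hyperbolic; positive and significant ->
    sigmoidal; otherwise indeterminate.
    """
    if not np.isfinite(linear_estimate) or not np.isfinite(linear_p):
        return INDETERMINATE
    if linear_p > alpha or linear_estimate == 0:
        return INDETERMINATE
    return HYPERBOLIC if linear_estimate < 0 else SIGMOIDAL


def _raw_scale(coefs: np.ndarray, cov: np.ndarray, mu: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Map polynomial coefficients in z = (N - mu)/sigma back to powers of N.

    If eta = sum_j c_j z**j then eta = sum_i b_i N**i with
    b_i = sum_{j>=i} c_j * C(j, i) * (-mu)**(j-i) / sigma**j; the covariance
    transforms as A Cov A'.
    """
    k = len(coefs)
    A = np.zeros((k, k))
    for j in range(k):
        for i in range(j + 1):
            A[i, j] = comb(j, i) * (-mu) ** (j - i) / sigma**j
    return A @ coefs, A @ cov @ A.T


def fit_shape_test(ts: TrialSet, max_degree: int = 3, alpha: float = 0.05) -> ShapeTestResult:
    """Fit the polynomial logistic shape test to a trial set.

    The response is encoded as (successes, failures) = (ne, n0 - ne), giving
    each trial its correct binomial weight. Starting from ``max_degree``
    (1-3), the highest-order term is dropped while its p-value exceeds
    ``alpha``; the linear term is always retained. Complete separation or a
    non-converged GLM yields an indeterminate call with a diagnostic flag.
    """
    ts.require_nonempty()
    if max_degree not in (1, 2, 3):
        raise ValueError("max_degree must be 1, 2 or 3")
    df = ts.to_frame()
    if df["n0"].nunique() < 2:
        raise ValueError("shape test requires at least two distinct densities")

    n0 = df["n0"].to_numpy(dtype=float)
    ne = df["ne"].to_numpy(dtype=float)
    mu = float(n0.mean())
    sigma = float(n0.std(ddof=0)) or 1.0
    z = (n0 - mu) / sigma
    endog = np.column_stack([ne, n0 - ne])

    degree = max_degree
    fit = None
    diagnostic = None
    while degree >= 1:
        exog = np.column_stack([z**j for j in range(degree + 1)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(candidate.bse)):
                raise ValueError("non-finite standard errors")
        except Exception as exc:  # separation / convergence failure
            diagnostic = f"GLM failed at degree {degree}: {exc}"
            fit = None
            degree -= 1
            continue
        fit = candidate
        if degree == 1 or fit.pvalues[degree] <= alpha:
            break
        degree -= 1

    if fit is None:
        empty = pd.DataFrame(columns=["term", "estimate", "se", "z", "p"])
        return ShapeTestResult(
            coefficients=empty,
            coefficients_raw=empty.copy(),
            retained_degree=0,
            inferred_shape=INDETERMINATE,
            alpha=alpha,
            diagnostic=diagnostic or "no polynomial model could be fitted",
        )

    est = np.asarray(fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = est / se
    from scipy.stats import norm

    pval = 2.0 * norm.sf(np.abs(zval))
    terms = list(TERM_NAMES[: degree + 1])
    coefficients = pd.DataFrame(
        {"term": terms, "estimate": est, "se": se, "z": zval, "p": pval}
    )

    raw_est, raw_cov = _raw_scale(est, cov, mu, sigma)
    raw_se = np.sqrt(np.clip(np.diag(raw_cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_z = raw_est / raw_se
    raw_p = 2.0 * norm.sf(np.abs(raw_z))
    coefficients_raw = pd.DataFrame(
        {"term": terms, "estimate": raw_est, "se": raw_se, "z": raw_z, "p": raw_p}
    )

    shape = classify_shape(float(raw_est[1]), float(raw_p[1]), alpha)
    return ShapeTestResult(
        coefficients=coefficients,
        coefficients_raw=coefficients_raw,
        retained_degree=degree,
        inferred_shape=shape,
        alpha=alpha,
        diagnostic=diagnostic,
    )
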