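"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from frfit import FRParameters, SyntheticConfig, generate_experiment


def rogers_fixed_point_oracle(
    a: float,
    h: float,
    n0: float,
    t: float,
    tol: float = 1e-13,
    max_iter: int = 500_000,
) -> float:
    """Independent damped fixed-point solution of the implicit depletion
    equation ``Ne = N0 (1 - exp(a (h Ne - T)))``.

    Iterates ``Ne <- (1-lam) Ne + lam N0 (1 - exp(a (h Ne - T)))`` with
    adaptive damping ``lam = min(1/2, 1/(1 + a h N0))``, which bounds the
    damped map's derivative in [0, 1-lam] on the admissible interval and so
    guarantees monotone convergence. Deliberately shares no code with the
    Lambert-W implementation it checks.
    """
    if a == 0 or n0 == 0:
        return 0.0
    upper = n0 if h == 0 else min(n0, t / h)
    lam = min(0.5, 1.0 / (1.0 + a * h * n0))
    ne = 0.0
    for _ in range(max_iter):
        prop = n0 * -math.expm1(min(a * (h * ne - t), 700.0))
        prop = min(max(prop, 0.0), upper)
        nxt = (1.0 - lam) * ne + lam * prop
        if abs(nxt - ne) < tol:
            return nxt
        ne = nxt
    raise RuntimeError(f"oracle did not converge (a={a}, h={h}, n0={n0}, t={t})")


@pytest.fixture(scope="session")
def rogers_oracle():
    return rogers_fixed_point_oracle


@pytest.fixture(scope="session")
def noap2_params() -> FRParameters:
    """Rogers type-II parameters of the no-alternative-prey, with-IGP fit."""
    return FRParameters(a=0.9797, h=0.0104, T=1.0)


@pytest.fixture
def make_experiment():
    """Factory for synthetic experiments at the study design."""

    def _make(
        family: str = "rogers2",
        params: FRParameters | None = None,
        reps: int = 6,
        seed: int = 42,
        noise: str = "binomial",
        **kwargs,
    ):
        cfg = SyntheticConfig(
            family=family,
            params=params or FRParameters(a=0.9797, h=0.0104, T=1.0),
            reps_per_density=reps,
            noise=noise,
            seed=seed,
            **kwargs,
        )
        return generate_experiment(cfg)

    return _make
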