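"""Synthetic predation-trial generator replicating the study design.

The generator emulates the arena experiment that motivates this package:
focal-prey densities {5, 10, 25, 50, 80} with 6 replicate arena-days per
density, four alternative-prey treatments offering {0, 5, 25, 80} aphids,
two contexts (non-parasitized vs parasitized focal prey, the latter being
the intraguild-predation setting), and 24 h (= 1 day) exposure.

Consumption noise models
------------------------
``binomial``
    ``ne ~ Binomial(n0, Ne_hat/n0)`` with ``Ne_hat`` the depletion-corrected
    prediction. This matches the fitting likelihood exactly, making
    estimator-correctness tests well-posed.
``exact_depletion``
    A mechanistic continuous-time renewal simulation: waiting times to the
    next capture are exponential with rate ``a_eff * N_remaining`` and each
    capture consumes ``h`` days of handling from the remaining budget. Its
    mean consumption approaches the Rogers prediction, but with process
    (not binomial) variance — useful for robustness checks.
``beta_binomial``
    Binomial mean with beta-distributed trial-level probability
    (overdispersion knob ``rho``; off by default because the real data's
    variance model is unknown).

Alternative-prey consumption is generated from a treatment-level mean
fraction and never used in functional-response fitting (it enters the
analysis only as a treatment label), mirroring the focal-prey-only design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .fr_models import FRModelSpec, FRParameters
from .trial_data import PredationTrial, TrialSet

__all__ = ["SyntheticConfig", "simulate_trial", "generate_experiment"]

DESIGN_DENSITIES = (5, 10, 25, 50, 80)
DESIGN_REPS = 6
DESIGN_TREATMENTS = (("No AP", 0), ("5_AP", 5), ("25_AP", 25), ("80_AP", 80))

#: default mean fraction of offered alternative prey consumed, by number
#: offered; loosely mirrors observed aphid consumption (near-total at 5
#: offered, declining at higher densities)
DEFAULT_AP_FRACTIONS = {0: 0.0, 5: 0.9, 25: 0.8, 80: 0.7}

NOISE_MODELS = ("binomial", "exact_depletion", "beta_binomial")


@dataclass
class SyntheticConfig:
    """Design and generating process for a synthetic experiment.

    Defaults reproduce the study design for a single treatment and context;
    widen ``treatments`` / ``igp_contexts`` for the full factorial layout.
    """

    family: str = "rogers2"
    params: FRParameters = field(
        default_factory=lambda: FRParameters(a=1.0, h=0.02, T=1.0)
    )
    densities: Sequence[int] = DESIGN_DENSITIES
    reps_per_density: int = DESIGN_REPS
    treatments: Sequence[Tuple[str, int]] = (("No AP", 0),)
    igp_contexts: Sequence[str] = ("non-parasitized",)
    noise: str = "binomial"
    rho: float = 0.05  # beta-binomial overdispersion (only used by that mode)
    ap_fractions: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AP_FRACTIONS)
    )
    t_expose: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise not in NOISE_MODELS:
            raise ValueError(
                f"noise must be one of {NOISE_MODELS} (got {self.noise!r})"
            )
        if self.reps_per_density < 1:
            raise ValueError("reps_per_density must be >= 1")
        if any(int(d) < 1 for d in self.densities):
            raise ValueError("densities must be positive integers")

    def spec(self) -> FRModelSpec:
        return FRModelSpec(self.family, self.params)


def _effective_attack_rate(spec: FRModelSpec, n0: int) -> float:
    p = spec.params
    if spec.family in ("holling2", "rogers2"):
        return float(p.a)
    if spec.family == "flexq":
        return float(p.b * n0**p.q) if n0 > 0 else 0.0
    return float(((p.d or 0.0) + p.b * n0) / (1.0 + p.c * n0))


def _simulate_exact_depletion(
    spec: FRModelSpec, n0: int, t_expose: float, rng: np.random.Generator
) -> int:
    """Sequential search-then-handle renewal process.

    With ``n`` prey remaining the time to the next capture is exponential
    with rate ``a_eff * n``; a capture occurring before the budget runs out
    removes one prey and costs ``h`` days of handling. This is the
    mechanistic process whose mean-field limit is the Rogers equation.
    """
    a = _effective_attack_rate(spec, n0)
    h = float(spec.params.h)
    if a <= 0 or n0 <= 0:
        return 0
    remaining = float(t_expose)
    n = int(n0)
    eaten = 0
    while n > 0 and remaining > 0:
        wait = rng.exponential(1.0 / (a * n))
        if wait > remaining:
            break
        remaining -= wait
        eaten += 1
        n -= 1
        remaining -= h
    return eaten


def simulate_trial(
    spec: FRModelSpec,
    n0: int,
    t_expose: float,
    noise: str,
    rng: np.random.Generator,
    rho: float = 0.05,
) -> int:
    """Draw one consumption count for a trial of ``n0`` prey over
    ``t_expose`` days. Always returns an integer in ``[0, n0]``."""
    if n0 <= 0:
        return 0
    if noise == "exact_depletion":
        return _simulate_exact_depletion(spec, n0, t_expose, rng)
    pred = float(spec.predict(n0, t_expose))
    p = min(max(pred / n0, 0.0), 1.0)
    if noise == "binomial":
        return int(rng.binomial(n0, p))
    if noise == "beta_binomial":
        if p in (0.0, 1.0) or rho <= 0:
            return int(rng.binomial(n0, p))
        conc = (1.0 - rho) / rho
        pi = rng.beta(p * conc, (1.0 - p) * conc)
        return int(rng.binomial(n0, pi))
    raise ValueError(f"unknown noise model {noise!r}")


def generate_experiment(cfg: SyntheticConfig) -> TrialSet:
    """Generate a full trial set from a :class:`SyntheticConfig`.

    Produces ``len(densities) * reps_per_density`` trials per (treatment,
    context) cell; replicate labels index the simulated experimentation day.
    The returned metadata records the generating truth and seed.
    """
    spec = cfg.spec()
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for igp in cfg.igp_contexts:
        for label, ap_offered in cfg.treatments:
            frac = cfg.ap_fractions.get(ap_offered, 0.0)
            for rep in range(1, cfg.reps_per_density + 1):
                for n0 in cfg.densities:
                    ne = simulate_trial(
                        spec, int(n0), cfg.t_expose, cfg.noise, rng, cfg.rho
                    )
                    ap_eaten = (
                        int(rng.binomial(ap_offered, frac)) if ap_offered else 0
                    )
                    trials.append(
                        PredationTrial(
                            n0=int(n0),
                            ne=ne,
                            ap_offered=int(ap_offered),
                            ap_consumed=ap_eaten,
                            igp=igp,
                            treatment=label,
                            replicate=str(rep),
                            t_expose=cfg.t_expose,
                        )
                    )
    active = {
        k: v
        for k, v in vars(cfg.params).items()
        if v is not None
    }
    meta = {
        "source": "synthetic",
        "family": cfg.family,
        "true_params": active,
        "noise": cfg.noise,
        "seed": cfg.seed,
        "densities": list(map(int, cfg.densities)),
        "reps_per_density": cfg.reps_per_density,
    }
    return TrialSet(trials, meta)
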