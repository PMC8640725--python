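"""Proportional transition-intensity model Q(x) for the five-state chain.

Each allowed transition r->s has intensity

    q_rs(x) = exp(log q0_rs + beta_rs . x)

with a transition-specific baseline rate q0_rs (per year) and its own
log-linear coefficient vector over covariate dummies; exp(beta) is the
hazard ratio for that transition.  Diagonal entries are minus the row sum
so that Q generates a continuous-time Markov chain; the death row is zero.

Baseline log-rates of -inf encode structurally absent transitions; NaN
entries mark parameters that could not be estimated (reported as NA and
treated as rate zero when a matrix is requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .states import DEATH, N_STATES, TRANSITIONS, TransitionStructure, DEFAULT_STRUCTURE


@dataclass(frozen=True)
class IntensityModel:
    covariate_names: tuple[str, ...] = ()
    baseline_log_rates: Mapping[tuple[int, int], float] = field(default_factory=dict)
    coefficients: Mapping[tuple[int, int], np.ndarray] = field(default_factory=dict)
    structure: TransitionStructure = DEFAULT_STRUCTURE

    def __post_init__(self):
        p = len(self.covariate_names)
        for trans in self.baseline_log_rates:
            if not self.structure.is_allowed(*trans):
                raise ValueError(f"rate given for disallowed transition {trans}")
        for trans, beta in self.coefficients.items():
            if not self.structure.is_allowed(*trans):
                raise ValueError(f"coefficients for disallowed transition {trans}")
            if len(np.atleast_1d(beta)) != p:
                raise ValueError(
                    f"coefficient length mismatch for {trans}: "
                    f"{len(np.atleast_1d(beta))} != {p} covariates"
                )

    def linear_predictor(self, trans: tuple[int, int], x: np.ndarray | None) -> float:
        eta = self.baseline_log_rates.get(trans, -np.inf)
        beta = self.coefficients.get(trans)
        if beta is not None and x is not None and len(self.covariate_names):
            b = np.asarray(beta, dtype=float)
            xv = np.asarray(x, dtype=float)
            finite = np.isfinite(b)
            eta = eta + float(b[finite] @ xv[finite])
        return eta

    def rate(self, trans: tuple[int, int], x: np.ndarray | None = None) -> float:
        eta = self.linear_predictor(trans, x)
        if np.isnan(eta):
            return 0.0  # inestimable -> treated as absent, flagged upstream
        return float(np.exp(eta))

    def intensity_matrix(self, x: np.ndarray | None = None) -> np.ndarray:
        Q = np.zeros((N_STATES, N_STATES))
        for trans in self.structure.allowed:
            r, s = trans
            Q[r, s] = self.rate(trans, x)
        np.fill_diagonal(Q, 0.0)
        Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
        Q[DEATH, :] = 0.0
        return Q

    def hazard_ratio(self, trans: tuple[int, int], name: str) -> float:
        j = self.covariate_names.index(name)
        beta = self.coefficients.get(trans)
        if beta is None:
            return 1.0
        return float(np.exp(np.atleast_1d(beta)[j]))


def model_from_rates(
    baseline_rates: Mapping[tuple[int, int], float],
    hazard_ratios: Mapping[tuple[int, int], Mapping[str, float]] | None = None,
    covariate_names: tuple[str, ...] = (),
) -> IntensityModel:
    """Build an IntensityModel from per-year rates and hazard ratios.

    Transitions absent from ``baseline_rates`` (or with rate 0) are
    structural zeros; hazard ratios default to 1 for unnamed covariates.
    """
    log_rates = {}
    for trans in TRANSITIONS:
        q = float(baseline_rates.get(trans, 0.0))
        if q < 0:
            raise ValueError(f"negative baseline rate for {trans}")
        log_rates[trans] = np.log(q) if q > 0 else -np.inf
    coefs = {}
    hazard_ratios = hazard_ratios or {}
    for trans in TRANSITIONS:
        beta = np.zeros(len(covariate_names))
        for name, hr in hazard_ratios.get(trans, {}).items():
            if name not in covariate_names:
                raise ValueError(f"hazard ratio given for unknown covariate {name!r}")
            if hr <= 0:
                raise ValueError(f"hazard ratio must be positive, got {hr}")
            beta[covariate_names.index(name)] = np.log(hr)
        coefs[trans] = beta
    return IntensityModel(
        covariate_names=tuple(covariate_names),
        baseline_log_rates=log_rates,
        coefficients=coefs,
    )


def validate_generator(Q: np.ndarray, atol: float = 1e-10) -> None:
    """Raise unless Q is a valid intensity matrix on the five-state space."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected {N_STATES}x{N_STATES} matrix, got {Q.shape}")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -atol).any():
        raise ValueError("negative off-diagonal intensity")
    if np.abs(Q.sum(axis=1)).max() > 1e-8:
        raise ValueError("intensity-matrix rows must sum to zero")
    if np.abs(Q[DEATH]).max() > atol:
        raise ValueError("death row must be zero (absorbing state)")
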