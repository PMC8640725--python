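"""Continuous-time multistate Markov model over the five LTC states.

The model is time-homogeneous with proportional (log-linear) covariate
effects on each of the ten allowed transition intensities.  Two observation
schemes are supported:

* ``exact`` — transition times are treated as exactly observed (dated EHR
  events).  The log-likelihood of a path is the sum over sojourns of
  q_rr * duration plus log q_rs for each observed jump, with a censored
  final sojourn contributing only its survival term.  This factorises per
  transition into a Poisson likelihood with log-exposure offset, so the fit
  reduces to ten independent quasi-Newton maximisations from the crude-rate
  initialiser (observed jumps / person-time at risk).

* ``panel`` — the state is known only at the observation times; interval
  contributions are entries of the matrix exponential exp(dt * Q), with
  death treated as exactly timed via sum_r P(dt)[s, r] * q_r,Death.

Hazard ratios are exp(beta) with Wald 95% intervals on the log scale.
One-year transition-probability matrices come from the matrix exponential
(scaling-and-squaring Pade, via scipy); mean sojourn times are -1/q_rr.
Transitions or covariate categories with zero observed events are reported
as NA rather than regularised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .intensity import IntensityModel
from .states import (
    DEATH,
    DEFAULT_STRUCTURE,
    LIVING_STATES,
    N_STATES,
    STATE_LABELS,
    TransitionStructure,
    transition_label,
)
from .state_builder import StateHistory

Z95 = 1.959963984540054


def make_intensity_matrix(model: IntensityModel, x: np.ndarray | None = None) -> np.ndarray:
    """Q(x): exp(log-linear predictor) on allowed transitions, rows sum to 0."""
    return model.intensity_matrix(x)


def _is_absorbing(Q: np.ndarray, s: int) -> bool:
    return bool(np.all(Q[s] == 0.0))


def exact_path_loglik(history: StateHistory, Q: np.ndarray) -> float:
    """Log-likelihood of a fully observed path under intensity matrix Q.

    Returns -inf if the path contains a jump whose intensity is zero.
    Works for any state space whose states index rows of Q.
    """
    Q = np.asarray(Q, dtype=float)
    obs = history.observations
    ll = 0.0
    for i, (t, s) in enumerate(obs):
        if i + 1 < len(obs):
            t_next, s_next = obs[i + 1]
            dur = t_next - t
            if dur < 0:
                raise ValueError("observation times must be non-decreasing")
            ll += Q[s, s] * dur
            q = Q[s, s_next]
            if q <= 0.0:
                return -np.inf
            ll += np.log(q)
        elif history.censored:
            ll += Q[s, s] * (history.end_time - t)
    return float(ll)


def panel_loglik(
    observations: list[tuple[float, int]],
    Q: np.ndarray,
    _cache: dict[float, np.ndarray] | None = None,
) -> float:
    """Log-likelihood of sparse (time, state) snapshots under Q.

    A final jump into an absorbing state is treated as exactly timed:
    its interval contributes sum_r P(dt)[s, r] * q_r,absorbing over the
    non-absorbing states r.  Returns -inf for a zero-probability pair.
    """
    Q = np.asarray(Q, dtype=float)
    ll = 0.0
    cache: dict[float, np.ndarray] = {} if _cache is None else _cache
    for i, ((t0, s0), (t1, s1)) in enumerate(zip(observations, observations[1:])):
        dt = t1 - t0
        if dt < 0:
            raise ValueError("observation times must be non-decreasing")
        if dt == 0:
            if s0 != s1:
                raise ValueError("distinct states at identical times")
            continue
        P = cache.get(dt)
        if P is None:
            P = expm(Q * dt)
            cache[dt] = P
        if _is_absorbing(Q, s1) and s0 != s1 and i == len(observations) - 2:
            living = [r for r in range(Q.shape[0]) if not _is_absorbing(Q, r)]
            dens = float(sum(P[s0, r] * Q[r, s1] for r in living))
            if dens <= 0.0:
                return -np.inf
            ll += np.log(dens)
        else:
            p = float(P[s0, s1])
            if p <= 0.0:
                return -np.inf
            ll += np.log(p)
    return float(ll)


def panel_observations_from_history(
    history: StateHistory, extra_times: np.ndarray | None = None
) -> list[tuple[float, int]]:
    """Snapshots of a history at its change points (and optional extra
    times), always including the end of follow-up for censored patients."""
    obs = list(history.observations)
    times = {t for t, _ in obs}
    if history.censored and history.end_time not in times:
        obs.append((history.end_time, obs[-1][1]))
    if extra_times is not None:
        base = sorted(history.observations)
        for t in np.asarray(extra_times, dtype=float):
            if t in times or t < 0 or t > history.end_time:
                continue
            state = base[0][1]
            for tt, ss in base:
                if tt <= t:
                    state = ss
                else:
                    break
            if state == DEATH:
                continue
            obs.append((float(t), state))
    return sorted(set(obs))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: IntensityModel
    covariance: dict[tuple[int, int], np.ndarray | None]
    param_names: dict[tuple[int, int], list[str]]
    loglik: float
    converged: bool
    n_transitions_observed: dict[tuple[int, int], int]
    na_covariates: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    na_transitions: list[tuple[int, int]] = field(default_factory=list)
    mode: str = "exact"


def sufficient_stats(
    histories: list[StateHistory],
    structure: TransitionStructure = DEFAULT_STRUCTURE,
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Per-patient time at risk in each living state and per-transition
    jump counts — the sufficient statistics of the exact-times likelihood."""
    n = len(histories)
    time_at_risk = np.zeros((n, N_STATES))
    counts = {trans: np.zeros(n, dtype=float) for trans in structure.allowed}
    for i, h in enumerate(histories):
        obs = h.observations
        for j, (t, s) in enumerate(obs):
            if j + 1 < len(obs):
                t_next, s_next = obs[j + 1]
                time_at_risk[i, s] += t_next - t
                if (s, s_next) not in counts:
                    raise ValueError(
                        f"{h.patient_id}: disallowed transition "
                        f"{transition_label((s, s_next))}"
                    )
                counts[(s, s_next)][i] += 1
            elif h.censored:
                time_at_risk[i, s] += h.end_time - t
    return time_at_risk, counts


def _fit_one_transition(T, d, X, crude_init):
    """Maximise sum_p [d_p * eta_p - T_p * exp(eta_p)], eta = a + X beta."""
    Z = np.column_stack([np.ones(len(T)), X]) if X.shape[1] else np.ones((len(T), 1))

    def negll(theta):
        eta = Z @ theta
        return float(np.sum(T * np.exp(eta) - d * eta))

    def grad(theta):
        mu = T * np.exp(Z @ theta)
        return Z.T @ (mu - d)

    theta0 = np.zeros(Z.shape[1])
    theta0[0] = crude_init
    res = minimize(negll, theta0, jac=grad, method="BFGS", options={"gtol": 1e-8})
    # BFGS can flag precision loss after converging; trust the gradient norm
    scale = max(float(d.sum()), 1.0)
    ok = bool(res.success) or float(np.abs(grad(res.x)).max()) < 1e-6 * scale
    mu = T * np.exp(Z @ res.x)
    info = (Z * mu[:, None]).T @ Z  # observed information (closed form)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None
    return res.x, cov, -res.fun, ok


def _aggregate_patterns(T, d, X):
    """Collapse patients with identical covariate rows (huge speedup)."""
    if X.shape[1] == 0:
        return np.array([T.sum()]), np.array([d.sum()]), np.zeros((1, 0))
    uniq, inv = np.unique(X, axis=0, return_inverse=True)
    Tg = np.bincount(inv, weights=T, minlength=len(uniq))
    dg = np.bincount(inv, weights=d, minlength=len(uniq))
    return Tg, dg, uniq


def fit(
    histories: list[StateHistory],
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
    structure: TransitionStructure = DEFAULT_STRUCTURE,
    mode: str = "exact",
    panel_grid: float | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the intensity model to state histories.

    ``covariates`` is an (n_patients, n_dummies) matrix aligned with
    ``histories`` (None for an intercept-only model).  Transitions with no
    observed jumps, and covariate categories with no jumps while active,
    are flagged NA and excluded from estimation.
    """
    if mode not in ("exact", "panel"):
        raise ValueError("mode must be 'exact' or 'panel'")
    n = len(histories)
    if n == 0:
        raise ValueError("no histories to fit")
    X = (
        np.zeros((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float)
    )
    if X.shape[0] != n:
        raise ValueError("covariates must align with histories")
    if X.shape[1] != len(covariate_names):
        raise ValueError("covariate_names must match covariate columns")
    if mode == "panel":
        return _fit_panel(histories, X, covariate_names, structure, panel_grid)

    time_at_risk, counts = sufficient_stats(histories, structure)
    p = X.shape[1]
    log_rates: dict[tuple[int, int], float] = {}
    coefs: dict[tuple[int, int], np.ndarray] = {}
    covs: dict[tuple[int, int], np.ndarray | None] = {}
    pnames: dict[tuple[int, int], list[str]] = {}
    na_cov: dict[tuple[int, int], list[str]] = {}
    na_trans: list[tuple[int, int]] = []
    n_obs: dict[tuple[int, int], int] = {}
    total_ll = 0.0
    all_ok = True
    for trans in structure.allowed:
        r, _ = trans
        T = time_at_risk[:, r]
        d = counts[trans]
        n_obs[trans] = int(d.sum())
        if d.sum() == 0 or T.sum() <= 0:
            na_trans.append(trans)
            log_rates[trans] = np.nan
            coefs[trans] = np.full(p, np.nan)
            covs[trans] = None
            pnames[trans] = []
            na_cov[trans] = list(covariate_names)
            continue
        keep = [
            j
            for j in range(p)
            if d[X[:, j] > 0].sum() > 0 and T[X[:, j] > 0].sum() > 0
        ]
        na_cov[trans] = [covariate_names[j] for j in range(p) if j not in keep]
        Tg, dg, Xg = _aggregate_patterns(T, d, X[:, keep])
        crude = float(np.log(dg.sum() / Tg.sum()))
        theta, cov, ll, ok = _fit_one_transition(Tg, dg, Xg, crude)
        all_ok = all_ok and ok
        total_ll += ll
        log_rates[trans] = float(theta[0])
        beta = np.full(p, np.nan)
        for k, j in enumerate(keep):
            beta[j] = theta[1 + k]
        coefs[trans] = beta
        covs[trans] = cov
        pnames[trans] = ["log_rate"] + [covariate_names[j] for j in keep]
    model = IntensityModel(
        covariate_names=tuple(covariate_names),
        baseline_log_rates=log_rates,
        coefficients=coefs,
        structure=structure,
    )
    return FitResult(
        model=model,
        covariance=covs,
        param_names=pnames,
        loglik=total_ll,
        converged=all_ok,
        n_transitions_observed=n_obs,
        na_covariates=na_cov,
        na_transitions=na_trans,
        mode="exact",
    )


def _fd_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def _fit_panel(histories, X, covariate_names, structure, panel_grid=None):
    """Interval-censored (panel) fit over the full parameter vector.

    ``panel_grid`` adds snapshots every so many years on top of the change
    points, tightening the panel likelihood towards the exact one.
    Intended for sensitivity analyses and modest cohort sizes; the exact
    mode is the primary, fast path.
    """
    p = X.shape[1]
    trans_list = list(structure.allowed)
    k_per = 1 + p

    # crude initialisation from the jumps visible between snapshots
    time_at_risk, counts = sufficient_stats(histories, structure)
    theta0 = []
    for trans in trans_list:
        r, _ = trans
        d = counts[trans].sum()
        T = max(time_at_risk[:, r].sum(), 1e-9)
        theta0.extend([np.log(max(d, 0.5) / T)] + [0.0] * p)
    theta0 = np.array(theta0)

    obs_sets = [
        panel_observations_from_history(
            h,
            extra_times=(
                None
                if panel_grid is None
                else np.round(np.arange(0.0, h.end_time, panel_grid), 9)
            ),
        )
        for h in histories
    ]
    patterns = [tuple(row) for row in X]

    def build_Q(theta, xrow):
        Q = np.zeros((N_STATES, N_STATES))
        for m, trans in enumerate(trans_list):
            a = theta[m * k_per]
            beta = theta[m * k_per + 1 : (m + 1) * k_per]
            Q[trans] = np.exp(a + float(beta @ xrow))
        Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
        Q[DEATH, :] = 0.0
        return Q

    def negll(theta):
        qcache: dict[tuple, np.ndarray] = {}
        pcache: dict[tuple, dict] = {}
        total = 0.0
        for obs, pat in zip(obs_sets, patterns):
            Q = qcache.get(pat)
            if Q is None:
                Q = build_Q(theta, np.array(pat))
                qcache[pat] = Q
                pcache[pat] = {}
            ll = panel_loglik(obs, Q, _cache=pcache[pat])
            if not np.isfinite(ll):
                return 1e12
            total -= ll
        return total

    bounds = [(-15.0, 5.0), *[(-10.0, 10.0)] * p] * len(trans_list)
    res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    H = _fd_hessian(negll, res.x)
    log_rates, coefs, covs, pnames = {}, {}, {}, {}
    try:
        full_cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        full_cov = None
    n_obs = {t: int(counts[t].sum()) for t in trans_list}
    for m, trans in enumerate(trans_list):
        sl = slice(m * k_per, (m + 1) * k_per)
        log_rates[trans] = float(res.x[sl][0])
        coefs[trans] = res.x[sl][1:].copy()
        covs[trans] = full_cov[sl, sl] if full_cov is not None else None
        pnames[trans] = ["log_rate"] + list(covariate_names)
    model = IntensityModel(
        covariate_names=tuple(covariate_names),
        baseline_log_rates=log_rates,
        coefficients=coefs,
        structure=structure,
    )
    return FitResult(
        model=model,
        covariance=covs,
        param_names=pnames,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_transitions_observed=n_obs,
        mode="panel",
    )


def hazard_ratios(fit_result: FitResult) -> pd.DataFrame:
    """HR = exp(beta) with Wald 95% CIs, one row per transition x category.

    Inestimable entries (zero observed events in the category) carry NaN.
    """
    rows = []
    model = fit_result.model
    for trans in model.structure.allowed:
        beta = model.coefficients.get(trans)
        names = fit_result.param_names.get(trans, [])
        cov = fit_result.covariance.get(trans)
        for j, name in enumerate(model.covariate_names):
            b = np.nan if beta is None else float(np.atleast_1d(beta)[j])
            if np.isnan(b):
                hr = lo = hi = np.nan
            else:
                hr = float(np.exp(b))
                se = np.nan
                if cov is not None and name in names:
                    k = names.index(name)
                    var = cov[k, k]
                    se = float(np.sqrt(var)) if var >= 0 else np.nan
                if np.isnan(se):
                    lo = hi = np.nan
                else:
                    # a near-degenerate category can have a huge se; an
                    # infinite upper bound is the honest rendering
                    with np.errstate(over="ignore"):
                        lo = float(np.exp(b - Z95 * se))
                        hi = float(np.exp(b + Z95 * se))
            rows.append(
                {
                    "transition": transition_label(trans),
                    "covariate": name,
                    "hr": hr,
                    "lo": lo,
                    "hi": hi,
                    "n_transitions": fit_result.n_transitions_observed.get(trans, 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilities, sojourns, reports


@dataclass(frozen=True)
class ProbabilityMatrix:
    horizon: float
    P: np.ndarray
    labels: tuple[str, ...] = STATE_LABELS
    covariate_pattern: tuple[float, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.labels), columns=list(self.labels))


def transition_probability(Q: np.ndarray, t: float) -> ProbabilityMatrix:
    """P(t) = expm(t Q), validated: rows must sum to 1 within 1e-8."""
    if t < 0:
        raise ValueError("horizon must be non-negative")
    Q = np.asarray(Q, dtype=float)
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -1e-12).any() or np.abs(Q.sum(axis=1)).max() > 1e-8:
        raise ValueError("invalid intensity matrix")
    P = expm(Q * t)
    err = np.abs(P.sum(axis=1) - 1.0).max()
    if err > 1e-8:
        raise ValueError(f"transition matrix rows deviate from 1 by {err:.2e}")
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(horizon=float(t), P=P)


def sojourn_times(Q: np.ndarray) -> np.ndarray:
    """Mean sojourn time -1/q_rr (years) per living state; inf if no exits."""
    Q = np.asarray(Q, dtype=float)
    out = np.empty(len(LIVING_STATES))
    for r in LIVING_STATES:
        out[r] = np.inf if Q[r, r] == 0.0 else -1.0 / Q[r, r]
    return out


def render_one_in(p: float) -> str:
    """Render a probability as the '1 in N' convention used in reports."""
    if p <= 0:
        return "—"
    n = round(1.0 / p)
    return "1" if n <= 1 else f"1 in {n}"


def one_year_report(
    fit_result: FitResult,
    reference: dict[str, float] | None = None,
    horizon: float = 1.0,
) -> dict:
    """One-year matrix and headline summaries at a covariate pattern.

    Default pattern: age 40-59, reference category for everything else.
    Summaries are the annual probability of moving to higher morbidity or
    death from the healthy state (S0) and from the multimorbid state (S2),
    with a "1 in N" rendering, plus mean sojourn times.  Transitions that
    were inestimable are treated as rate zero and listed in the report.
    """
    model = fit_result.model
    if reference is None:
        reference = {"age_40_59": 1.0} if "age_40_59" in model.covariate_names else {}
    unknown = set(reference) - set(model.covariate_names)
    if unknown:
        raise ValueError(f"reference names not in model: {sorted(unknown)}")
    x = np.array(
        [float(reference.get(name, 0.0)) for name in model.covariate_names]
    )
    Q = model.intensity_matrix(x)
    pm = transition_probability(Q, horizon)
    P = pm.P
    p0 = float(P[0, 1] + P[0, DEATH])
    p2 = float(P[2, 3] + P[2, DEATH])
    return {
        "horizon": horizon,
        "covariate_pattern": {n: float(v) for n, v in zip(model.covariate_names, x)},
        "matrix": ProbabilityMatrix(horizon, P, covariate_pattern=tuple(x)),
        "p_up_or_death_from_S0": p0,
        "p_up_or_death_from_S0_one_in": render_one_in(p0),
        "p_up_or_death_from_S2": p2,
        "p_up_or_death_from_S2_one_in": render_one_in(p2),
        "sojourn_years": sojourn_times(Q),
        "inestimable_transitions": [
            transition_label(t) for t in fit_result.na_transitions
        ],
    }
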