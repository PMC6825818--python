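"""Weighted nonlinear least-squares fitting of the retinol kinetic model.

A tracer study is fit by minimizing fractional-standard-deviation (FSD)
weighted residuals

    r_t = (FD_obs(t) - FD_model(t)) / (fsd * FD_obs(t))

over the adjustable fractional transfer coefficients (by default L(6,5),
L(7,5), L(5,6), L(5,7), L(10,6) and L(5,4); the absorptive-phase
parameters L(2,1), L(4,3) and DT(3) and the plasma pool M(5) stay fixed at
their assigned values).  When a dietary vitamin A intake datum is supplied
it enters the same stream as one more weighted residual,

    r_U = (U_obs - U_model) / (fsd * U_obs),

where ``U_model = DR / absorption`` comes from the tracee steady state with
M(5) fixed — a steady-state constraint that anchors the terminal slope of
the tracer curve when the sampled data alone do not reach it.

The weighting convention puts the *observed* value in the denominator, the
usual FSD-weighting choice in SAAM-style kinetic software.  Parameter
uncertainty is summarized as per-parameter FSDs (coefficients of variation)
from the Gauss-Newton covariance at the optimum, both scaled by the reduced
chi-square and unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import ObservedStudy
from .model import ModelSpec, SteadyStateSolution, simulate_tracer, solve_steady_state

__all__ = [
    "PARAM_KEYS",
    "DEFAULT_ADJUSTABLE",
    "FitConfig",
    "FitResult",
    "RetinolKineticsModel",
    "wnls_objective",
    "fit_model",
    "parameter_fsd",
]

#: parameter-name <-> L(i, j) key correspondence
PARAM_KEYS: dict[str, tuple[int, int]] = {
    "L_2_1": (2, 1), "L_4_3": (4, 3), "L_5_4": (5, 4),
    "L_6_5": (6, 5), "L_7_5": (7, 5), "L_5_6": (5, 6),
    "L_5_7": (5, 7), "L_10_6": (10, 6), "L_10_7": (10, 7),
}

DEFAULT_ADJUSTABLE: tuple[str, ...] = (
    "L_6_5", "L_7_5", "L_5_6", "L_5_7", "L_10_6", "L_5_4")

_BIG = 1e9  # guard for unbounded steady-state predictions during search


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one weighted fit.

    ``base_spec`` supplies every fixed quantity (absorptive-phase
    parameters, M5, absorption) and the default start values for the
    adjustable coefficients.
    """

    base_spec: ModelSpec
    adjustable: tuple[str, ...] = DEFAULT_ADJUSTABLE
    weighting_fsd: float = 0.05
    include_intake: bool = False
    intake_value: float | None = None
    start: Mapping[str, float] | None = None
    multi_start: int = 5
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int = 3000
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.weighting_fsd <= 0:
            raise ValueError("weighting_fsd must be > 0")
        bad = [p for p in self.adjustable if p not in PARAM_KEYS]
        if bad:
            raise ValueError(f"unknown adjustable parameters: {bad}")
        if self.intake_value is not None and self.intake_value <= 0:
            raise ValueError("intake_value must be positive")


@dataclass(frozen=True)
class FitResult:
    """Estimates, uncertainties and the derived steady state of one fit."""

    estimates: dict[str, float]
    fsd: dict[str, float]            # scaled by reduced chi-square
    fsd_unscaled: dict[str, float]
    rss: float                       # weighted residual sum of squares
    converged: bool
    spec: ModelSpec
    steady_state: SteadyStateSolution | None
    n_obs: int
    message: str = ""

    def as_dict(self) -> dict:
        out = {
            "estimates": dict(self.estimates),
            "fsd": dict(self.fsd),
            "fsd_unscaled": dict(self.fsd_unscaled),
            "wrss": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "message": self.message,
        }
        if self.steady_state is not None:
            out["steady_state"] = self.steady_state.as_dict()
        return out


def _intake_prediction(spec: ModelSpec) -> float:
    """DR / absorption from the closed-form steady state; large-but-finite
    when the parameter vector admits no finite steady state (so the
    optimizer is pushed away rather than crashed)."""
    l65, l75 = spec.l(6, 5), spec.l(7, 5)
    l56, l57 = spec.l(5, 6), spec.l(5, 7)
    l106, l107 = spec.l(10, 6), spec.l(10, 7)
    d6 = l56 + l106
    d7 = l57 + l107
    m6 = spec.M5 * l65 / d6 if l65 > 0 and d6 > 0 else (0.0 if l65 == 0 else _BIG)
    m7 = spec.M5 * l75 / d7 if l75 > 0 and d7 > 0 else (0.0 if l75 == 0 else _BIG)
    dr = m6 * l106 + m7 * l107
    return min(dr / spec.absorption, _BIG)


class RetinolKineticsModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for retinol tracer kinetics.

    ``fit(X, y)`` takes sampling times in days (1-D, or a single-column
    2-D array) and observed plasma fraction of dose; ``predict(X)`` returns
    the model FD_p at the requested times from the fitted coefficients.

    Parameters mirror :class:`FitConfig`.  Fitted attributes:

    - ``params_`` — adjustable-coefficient estimates (per day);
    - ``fsd_`` / ``fsd_unscaled_`` — per-parameter fractional SDs;
    - ``spec_`` — the fitted :class:`ModelSpec`;
    - ``steady_state_`` — tracee steady state at the estimates (or None
      when no finite steady state exists, e.g. L(10,6) converged to 0);
    - ``rss_``, ``converged_``, ``n_obs_``.
    """

    def __init__(self, base_spec=None, adjustable=DEFAULT_ADJUSTABLE,
                 weighting_fsd=0.05, include_intake=False, intake_value=None,
                 start=None, multi_start=5, ftol=1e-10, xtol=1e-10,
                 max_nfev=3000, random_state=0):
        self.base_spec = base_spec
        self.adjustable = adjustable
        self.weighting_fsd = weighting_fsd
        self.include_intake = include_intake
        self.intake_value = intake_value
        self.start = start
        self.multi_start = multi_start
        self.ftol = ftol
        self.xtol = xtol
        self.max_nfev = max_nfev
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    def _spec_for(self, theta: np.ndarray) -> ModelSpec:
        updates = {PARAM_KEYS[name]: max(float(v), 0.0)
                   for name, v in zip(self.adjustable, theta)}
        return self.base_spec.with_updates(updates)

    def _make_residual_fn(self, times: np.ndarray, y: np.ndarray):
        fsd = self.weighting_fsd
        wy = fsd * y
        intake = self.intake_value

        def residuals(theta: np.ndarray) -> np.ndarray:
            spec = self._spec_for(theta)
            pred = simulate_tracer(spec, times).fd_plasma
            r = (y - pred) / wy
            if self.include_intake:
                r = np.append(r, (intake - _intake_prediction(spec)) / (fsd * intake))
            return r

        return residuals

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if self.base_spec is None:
            raise ValueError("base_spec is required")
        times = np.asarray(X, dtype=float)
        if times.ndim == 2 and times.shape[1] == 1:
            times = times[:, 0]
        y = np.asarray(y, dtype=float)
        if times.ndim != 1 or y.shape != times.shape:
            raise ValueError("X must be 1-D times (or (n,1)) matching y")
        if np.any(y <= 0):
            raise ValueError("observed FD_p must be positive for FSD weighting")
        if self.include_intake and (self.intake_value is None or self.intake_value <= 0):
            raise ValueError("include_intake requires a positive intake_value")
        n_par = len(self.adjustable)
        n_obs = times.size + (1 if self.include_intake else 0)
        if n_obs <= n_par:
            raise ValueError(
                f"need more observations ({n_obs}) than parameters ({n_par})")

        start = dict(self.start) if self.start else {}
        x0 = np.array([start.get(name, self.base_spec.l(*PARAM_KEYS[name]))
                       for name in self.adjustable], dtype=float)
        x0 = np.maximum(x0, 1e-8)
        residuals = self._make_residual_fn(times, y)
        rng = np.random.default_rng(self.random_state)

        best = None
        for attempt in range(max(1, self.multi_start)):
            xa = x0 if attempt == 0 else x0 * np.exp(0.5 * rng.standard_normal(n_par))
            try:
                res = least_squares(
                    residuals, np.maximum(xa, 1e-10), bounds=(0.0, np.inf),
                    method="trf", x_scale="jac", ftol=self.ftol,
                    xtol=self.xtol, gtol=1e-12, max_nfev=self.max_nfev)
            except Exception:  # singular linear algebra on a bad start
                continue
            if best is None or res.cost < best.cost:
                best = res
            if res.status > 0 and attempt == 0:
                break  # first start converged; no multi-start needed
        if best is None:
            raise RuntimeError("all optimization starts failed")
        res = best

        self.converged_ = bool(res.status > 0)
        self.rss_ = float(2.0 * res.cost)
        est = {name: float(v) for name, v in zip(self.adjustable, res.x)}
        self.params_ = est
        self.spec_ = self._spec_for(res.x)
        self.n_obs_ = n_obs
        fsd_s, fsd_u = parameter_fsd(res.jac, self.rss_, res.x, n_obs)
        self.fsd_ = {name: v for name, v in zip(self.adjustable, fsd_s)}
        self.fsd_unscaled_ = {name: v for name, v in zip(self.adjustable, fsd_u)}
        try:
            self.steady_state_ = solve_steady_state(self.spec_)
        except ValueError:
            self.steady_state_ = None
        self.message_ = str(res.message)
        return self

    def predict(self, X):
        times = np.asarray(X, dtype=float)
        if times.ndim == 2 and times.shape[1] == 1:
            times = times[:, 0]
        return simulate_tracer(self.spec_, times).fd_plasma

    def result(self) -> FitResult:
        return FitResult(
            estimates=dict(self.params_), fsd=dict(self.fsd_),
            fsd_unscaled=dict(self.fsd_unscaled_), rss=self.rss_,
            converged=self.converged_, spec=self.spec_,
            steady_state=self.steady_state_, n_obs=self.n_obs_,
            message=self.message_)


def parameter_fsd(
    jac: np.ndarray,
    rss: float,
    estimates: np.ndarray,
    n_obs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter fractional standard deviations from the weighted Jacobian.

    ``FSD_k = sqrt([ (J^T J)^-1 ]_kk * s^2) / |estimate_k|`` with the
    reduced chi-square ``s^2 = RSS / (n_obs - n_params)`` (scaled variant)
    or ``s^2 = 1`` (unscaled).  Parameters that are unidentifiable (rank
    deficient Jacobian, zero estimate, or no residual degrees of freedom)
    get FSD = +inf.
    """
    estimates = np.asarray(estimates, dtype=float)
    n_par = estimates.size
    dof = n_obs - n_par
    JtJ = jac.T @ jac
    try:
        cov = np.linalg.inv(JtJ)
        diag = np.diag(cov).copy()
        if np.any(diag < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ)
        diag = np.abs(np.diag(cov))
        rank = np.linalg.matrix_rank(JtJ)
        if rank < n_par:
            diag = np.full(n_par, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.abs(estimates)
        base = np.sqrt(diag)
        fsd_unscaled = np.where(denom > 0, base / denom, np.inf)
        if dof > 0:
            s = np.sqrt(rss / dof)
            fsd_scaled = np.where(denom > 0, base * s / denom, np.inf)
        else:
            fsd_scaled = np.full(n_par, np.inf)
    return fsd_scaled, fsd_unscaled


def _estimator_from_config(config: FitConfig) -> RetinolKineticsModel:
    return RetinolKineticsModel(
        base_spec=config.base_spec, adjustable=tuple(config.adjustable),
        weighting_fsd=config.weighting_fsd, include_intake=config.include_intake,
        intake_value=config.intake_value, start=config.start,
        multi_start=config.multi_start, ftol=config.ftol, xtol=config.xtol,
        max_nfev=config.max_nfev, random_state=config.random_state)


def wnls_objective(params: Mapping[str, float], study: ObservedStudy,
                   config: FitConfig) -> float:
    """Weighted residual sum of squares at a given parameter point."""
    est = _estimator_from_config(config)
    theta = np.array([params[name] for name in config.adjustable], dtype=float)
    r = est._make_residual_fn(study.times, study.fd_observed)(theta)
    return float(np.dot(r, r))


def fit_model(study: ObservedStudy, config: FitConfig) -> FitResult:
    """Fit one tracer study; never raises on non-convergence (flagged instead)."""
    if config.include_intake and config.intake_value is None:
        config = replace(config, intake_value=study.intake_datum)
    est = _estimator_from_config(config)
    est.fit(study.times, study.fd_observed)
    return est.result()
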