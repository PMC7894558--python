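"""Continuous-discrete extended Kalman filter for the hybrid soft sensor.

Between measurements the kinetic model propagates the state mean and its
covariance (continuous Lyapunov equation dP/dt = AP + PA' + Q with A the
model Jacobian along the mean); every 15 minutes the median of the
per-minute PLS concentration predictions of Glu, Xyl and EtOH forms a
measurement that updates mean and covariance through the standard Kalman
gain.  The measurement noise covariance switches once, from R1 to R2,
when the estimated glucose falls below a quarter of the glucose-on-
xylose inhibition constant — the onset of the xylose consumption phase,
where matrix interference on the spectra is much weaker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .kinetics import (IDX, N_STATES, KineticParameters, StateVector,
                       Trajectory, jacobian, reaction_rhs, simulate)

__all__ = [
    "MEASURED_STATES",
    "observation_matrix",
    "NoiseSpec",
    "EstimatorState",
    "MonitorRecord",
    "MonitorResult",
    "propagate_moments",
    "predict_step",
    "update_step",
    "select_R",
    "measurement_from_batch",
    "confidence_band",
    "run_monitor",
    "tune_Q",
]

#: The analytes observed through the spectroscopic soft sensor.
MEASURED_STATES = ("glu", "xyl", "etoh")


def observation_matrix() -> np.ndarray:
    """3x8 selector C picking (Glu, Xyl, EtOH) out of the state vector."""
    c = np.zeros((len(MEASURED_STATES), N_STATES))
    for row, name in enumerate(MEASURED_STATES):
        c[row, IDX[name]] = 1.0
    return c


def _check_psd(m: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() < -tol:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass(frozen=True)
class NoiseSpec:
    """Process noise Q ((g/L)^2/h, 8x8) and phase-dependent measurement
    noise R1 (glucose phase) / R2 (xylose phase), each 3x3 in (g/L)^2."""

    Q: np.ndarray
    R1: np.ndarray
    R2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "Q", _check_psd(self.Q, "Q"))
        object.__setattr__(self, "R1", _check_psd(self.R1, "R1"))
        object.__setattr__(self, "R2", _check_psd(self.R2, "R2"))

    @classmethod
    def isotropic(cls, q: float, r1_diag, r2_diag) -> "NoiseSpec":
        return cls(Q=q * np.eye(N_STATES), R1=np.diag(np.asarray(r1_diag, dtype=float)),
                   R2=np.diag(np.asarray(r2_diag, dtype=float)))


GLUCOSE_PHASE = "glucose-phase"
XYLOSE_PHASE = "xylose-phase"


def default_initial_covariance() -> np.ndarray:
    """Initial covariance consistent with how a batch is started: the t0
    offline sample fixes the concentrations to HPLC repeatability
    (SD 0.3 g/L) and the inoculum dry weight fixes biomass to ~0.1 g/L."""
    return np.diag([0.09] * 7 + [0.01])


@dataclass(frozen=True)
class EstimatorState:
    """Posterior mean and covariance at one instant, plus the phase latch."""

    time_h: float
    mean: np.ndarray          # (8,)
    cov: np.ndarray           # (8, 8)
    phase: str = GLUCOSE_PHASE

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise ValueError("mean must be 1-D with a matching square cov")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", 0.5 * (cov + cov.T))

    @classmethod
    def initial(cls, x0: StateVector,
                p0: np.ndarray | float | None = None) -> "EstimatorState":
        if p0 is None:
            cov = default_initial_covariance()
        elif np.isscalar(p0):
            cov = p0 * np.eye(N_STATES)
        else:
            cov = np.asarray(p0, dtype=float)
        return cls(time_h=0.0, mean=x0.to_array(), cov=cov)


def propagate_moments(
    mean: np.ndarray,
    cov: np.ndarray,
    t0: float,
    dt: float,
    rhs_fn,
    jac_fn,
    Q: np.ndarray,
    method: str = "continuous",
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearized moment propagation over ``dt`` for an arbitrary ODE model.

    'continuous' jointly integrates the mean ODE dx/dt = f(x) and the
    Lyapunov covariance ODE dP/dt = A(x)P + PA(x)' + Q with A the model
    Jacobian at the instantaneous mean.  'discrete' propagates the mean
    the same way but takes one transition-matrix covariance step,
    P+ = A_d P A_d' + Q with A_d = expm(A dt) at the initial mean.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    Q = np.asarray(Q, dtype=float)
    n = mean.size
    if method == "discrete":
        sol = solve_ivp(lambda t, x: rhs_fn(x), (t0, t0 + dt), mean,
                        method="LSODA", jac=lambda t, x: jac_fn(x),
                        rtol=rtol, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"mean propagation failed: {sol.message}")
        a_d = expm(jac_fn(mean) * dt)
        return sol.y[:, -1], a_d @ cov @ a_d.T + Q
    if method != "continuous":
        raise ValueError(f"unknown propagation method {method!r}")

    def rhs(t, z):
        x = z[:n]
        p = z[n:].reshape(n, n)
        a = jac_fn(x)
        dp = a @ p + p @ a.T + Q
        return np.concatenate([rhs_fn(x), dp.ravel()])

    z0 = np.concatenate([mean, cov.ravel()])
    sol = solve_ivp(rhs, (t0, t0 + dt), z0, method="RK45", rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"covariance propagation failed: {sol.message}")
    return sol.y[:n, -1], sol.y[n:, -1].reshape(n, n)


def predict_step(
    est: EstimatorState,
    params: KineticParameters,
    Q: np.ndarray,
    dt: float = 0.25,
    method: str = "continuous",
    rtol: float = 1e-8,
) -> EstimatorState:
    """Propagate mean and covariance of the fermentation state over ``dt``
    hours (a priori estimate); concentrations are floored at zero."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mean, cov = propagate_moments(
        est.mean, est.cov, est.time_h, dt,
        lambda x: reaction_rhs(x, params), lambda x: jacobian(x, params),
        Q, method=method, rtol=rtol,
    )
    return EstimatorState(time_h=est.time_h + dt, mean=np.clip(mean, 0.0, None),
                          cov=cov, phase=est.phase)


def measurement_from_batch(predictions) -> np.ndarray:
    """Per-analyte median of a batch of predicted (Glu, Xyl, EtOH) triplets.

    The median over the 15 per-minute predictions rejects isolated
    outliers (bubbles, spikes).  Even counts take the mean of the central
    pair.
    """
    arr = np.asarray(predictions, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != len(MEASURED_STATES):
        raise ValueError("predictions must be (n, 3) with n >= 1")
    return np.median(arr, axis=0)


def select_R(est: EstimatorState, R1: np.ndarray, R2: np.ndarray,
             ki_glu_xyl: float) -> tuple[np.ndarray, EstimatorState]:
    """Phase-dependent measurement covariance with a one-way latch.

    R1 applies while estimated glucose >= Ki_Glu_Xyl / 4; the first time
    the estimate drops strictly below the threshold the filter enters the
    xylose phase and keeps R2 for the rest of the run.
    """
    if ki_glu_xyl <= 0:
        raise ValueError("ki_glu_xyl must be > 0")
    if est.phase == XYLOSE_PHASE:
        return np.asarray(R2, dtype=float), est
    if est.mean[IDX["glu"]] < ki_glu_xyl / 4.0:
        return np.asarray(R2, dtype=float), replace(est, phase=XYLOSE_PHASE)
    return np.asarray(R1, dtype=float), est


def update_step(prior: EstimatorState, y: np.ndarray, R: np.ndarray,
                C: np.ndarray | None = None, floor: bool = True) -> EstimatorState:
    """Kalman measurement update: gain, mean correction, covariance shrink.

    K = P C' (C P C' + R)^-1 ; x+ = x + K(y - Cx) ; P+ = (I - KC) P.
    ``C`` defaults to the (Glu, Xyl, EtOH) selector.  Posterior
    concentrations are floored at zero (disable for non-concentration
    systems); a singular innovation covariance skips the update and
    returns the prior.
    """
    c = observation_matrix() if C is None else np.asarray(C, dtype=float)
    p = prior.cov
    n = prior.mean.size
    y = np.asarray(y, dtype=float)
    s = c @ p @ c.T + np.asarray(R, dtype=float)
    try:
        gain = np.linalg.solve(s.T, (p @ c.T).T).T  # K = P C' S^-1
    except np.linalg.LinAlgError:
        return prior
    mean = prior.mean + gain @ (y - c @ prior.mean)
    cov = (np.eye(n) - gain @ c) @ p
    if floor:
        mean = np.clip(mean, 0.0, None)
    return EstimatorState(time_h=prior.time_h, mean=mean, cov=cov, phase=prior.phase)


def confidence_band(est: EstimatorState, multiplier: float = 3.0) -> np.ndarray:
    """Per-state half-widths multiplier * sqrt(diag(P)); default +/-3 sigma."""
    return multiplier * np.sqrt(np.clip(np.diag(est.cov), 0.0, None))


@dataclass(frozen=True)
class MonitorRecord:
    """One filter iteration: a priori, measurement (if any), a posteriori."""

    time_h: float
    prior: EstimatorState
    measurement: np.ndarray | None
    posterior: EstimatorState
    band: np.ndarray
    updated: bool

    @property
    def phase(self) -> str:
        return self.posterior.phase


@dataclass(frozen=True)
class MonitorResult:
    """Full monitoring run: records at each update instant plus the t0
    open-loop model prediction for comparison."""

    records: list
    open_loop: Trajectory

    def times(self) -> np.ndarray:
        return np.array([r.time_h for r in self.records])

    def posterior_means(self) -> np.ndarray:
        return np.vstack([r.posterior.mean for r in self.records])

    def measurements(self) -> np.ndarray:
        """(n, 3) raw PLS measurement vectors; NaN rows where skipped."""
        nan = np.full(len(MEASURED_STATES), np.nan)
        return np.vstack([r.measurement if r.measurement is not None else nan
                          for r in self.records])

    def estimates_at(self, times: np.ndarray) -> np.ndarray:
        t = self.times()
        m = self.posterior_means()
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return np.column_stack([np.interp(times, t, m[:, j]) for j in range(N_STATES)])

    def to_frame(self):
        import pandas as pd

        from .kinetics import STATE_NAMES

        rows = []
        for r in self.records:
            row = {"time_h": r.time_h, "phase": r.phase, "updated": r.updated}
            for j, name in enumerate(STATE_NAMES):
                row[f"est_{name}"] = r.posterior.mean[j]
                row[f"band_{name}"] = r.band[j]
            for j, name in enumerate(MEASURED_STATES):
                row[f"pls_{name}"] = r.measurement[j] if r.measurement is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def run_monitor(
    x0: StateVector,
    params: KineticParameters,
    models: dict,
    spectra,
    noise: NoiseSpec,
    update_min: float = 15.0,
    horizon_h: float | None = None,
    p0: np.ndarray | float | None = None,
    band_multiplier: float = 3.0,
    propagation: str = "continuous",
) -> MonitorResult:
    """Run the hybrid monitor over a timestamped spectra stream.

    Every ``update_min`` minutes the spectra collected since the previous
    update are pushed through the PLS models; the per-analyte median
    forms the measurement.  An empty window degrades gracefully to a
    prediction-only step.
    """
    spectra = sorted(spectra, key=lambda s: s.timestamp_min)
    if horizon_h is None:
        horizon_h = spectra[-1].timestamp_min / 60.0 if spectra else 0.0
    dt = update_min / 60.0
    n_steps = int(round(horizon_h / dt))

    open_loop = simulate(x0, params, np.linspace(0.0, horizon_h, max(2, n_steps * 3)))

    est = EstimatorState.initial(x0, p0)
    records = []
    ordered = {name: models[name] for name in MEASURED_STATES}
    cursor = 0
    for _ in range(n_steps):
        prior = predict_step(est, params, noise.Q, dt, method=propagation)
        window_end = prior.time_h * 60.0 + 1e-9
        batch = []
        while cursor < len(spectra) and spectra[cursor].timestamp_min <= window_end:
            batch.append(spectra[cursor])
            cursor += 1
        if batch:
            triplets = [[m.predict(s) for m in ordered.values()] for s in batch]
            y = measurement_from_batch(triplets)
            r_mat, prior = select_R(prior, noise.R1, noise.R2, params.ki_glu_xyl)
            posterior = update_step(prior, y, r_mat)
            records.append(MonitorRecord(prior.time_h, prior, y, posterior,
                                         confidence_band(posterior, band_multiplier), True))
        else:
            records.append(MonitorRecord(prior.time_h, prior, None, prior,
                                         confidence_band(prior, band_multiplier), False))
        est = records[-1].posterior
    return MonitorResult(records=records, open_loop=open_loop)


def tune_Q(
    monitor_fn,
    reference_times: np.ndarray,
    reference_values: dict,
    q_init: float = 1e-7,
    growth_factor: float = 10.0**0.5,
    improvement_tol: float = 0.02,
    noise_sd: float | None = None,
    max_iter: int = 12,
) -> tuple[float, list]:
    """Iteratively grow the isotropic process noise until the estimates
    match the offline reference.

    ``monitor_fn(q)`` must run the full filter with Q = q*I and return a
    :class:`MonitorResult`.  Starting from a deliberately small ``q_init``
    (model-dominated filter), q is multiplied by ``growth_factor`` until
    the RMSE against the offline samples stops improving by more than
    ``improvement_tol`` (relative) or falls below the reference noise SD.
    Returns (q, [(q, rmse), ...]).
    """
    if q_init <= 0 or growth_factor <= 1:
        raise ValueError("q_init must be > 0 and growth_factor > 1")
    reference_times = np.asarray(reference_times, dtype=float)

    def rmse_for(q: float) -> float:
        result = monitor_fn(q)
        est = result.estimates_at(reference_times)
        errs = []
        for name, vals in reference_values.items():
            errs.append(est[:, IDX[name]] - np.asarray(vals, dtype=float))
        return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

    q = q_init
    best_rmse = rmse_for(q)
    trace = [(q, best_rmse)]
    if noise_sd is not None and best_rmse <= noise_sd:
        return q, trace
    best_q = q
    for _ in range(max_iter):
        q_next = q * growth_factor
        rmse = rmse_for(q_next)
        trace.append((q_next, rmse))
        if rmse < best_rmse * (1.0 - improvement_tol):
            best_q, best_rmse, q = q_next, rmse, q_next
            if noise_sd is not None and best_rmse <= noise_sd:
                break
        else:
            break
    return best_q, trace
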