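"""Off-line identification of the kinetic model.

Nonlinear least squares against HPLC-style concentration profiles,
local (finite-difference) sensitivity analysis with the root-mean-square
importance measure and the collinearity index for identifiable-subset
selection, residual-bootstrap re-estimation, and Monte Carlo propagation
of parameter uncertainty through the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import IDX, KineticParameters, StateVector, simulate

__all__ = [
    "FitDataset",
    "FitResult",
    "BootstrapResult",
    "fit_least_squares",
    "local_sensitivity",
    "collinearity_index",
    "bootstrap_estimate",
    "propagate_uncertainty",
]


@dataclass(frozen=True)
class FitDataset:
    """Measured concentration profiles for a named subset of states."""

    times: np.ndarray        # h
    measurements: dict       # state name -> array of g/L values
    x0: StateVector

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        for name, vals in self.measurements.items():
            if name not in IDX:
                raise ValueError(f"unknown state {name!r}")
            if len(vals) != t.size:
                raise ValueError(f"length mismatch for {name!r}")
        if t.size < 3:
            raise ValueError("need at least 3 sample points per fitted state")

    @property
    def state_names(self) -> tuple:
        return tuple(self.measurements)

    def matrix(self) -> np.ndarray:
        return np.column_stack([np.asarray(self.measurements[n], dtype=float)
                                for n in self.state_names])


def _sim_grid(times: np.ndarray) -> np.ndarray:
    """Simulation grid covering the sample times from t=0."""
    t = np.asarray(times, dtype=float)
    grid = np.unique(np.concatenate([[0.0], t]))
    return grid


#: ODE tolerance used inside the fitting loop; tight enough that the
#: integrator noise stays well below the finite-difference step.
FIT_SIM_RTOL = 1e-7


def _predict(dataset: FitDataset, params: KineticParameters,
             rtol: float = FIT_SIM_RTOL) -> np.ndarray:
    traj = simulate(dataset.x0, params, _sim_grid(dataset.times), rtol=rtol, atol=1e-9)
    states = traj.at(dataset.times)
    return np.column_stack([states[:, IDX[n]] for n in dataset.state_names])


@dataclass(frozen=True)
class FitResult:
    params: KineticParameters
    free_params: tuple
    estimates: np.ndarray     # fitted values of the free parameters
    residuals: np.ndarray     # (n_times, n_states): model - measured
    cost: float
    converged: bool
    message: str = ""


def fit_least_squares(
    dataset: FitDataset,
    free_params,
    init: KineticParameters,
    x_rtol: float = 1e-10,
    sim_rtol: float = FIT_SIM_RTOL,
    diff_step: float = 1e-5,
) -> FitResult:
    """Trust-region nonlinear least squares on the chosen parameters.

    Free parameters are bounded below at a small positive value; all
    other parameters are held at their ``init`` values.  Residuals are
    unweighted concentration differences (g/L).
    """
    free_params = tuple(free_params)
    if not free_params:
        raise ValueError("free_params must be nonempty")
    theta0 = np.array([getattr(init, name) for name in free_params], dtype=float)
    if np.any(theta0 <= 0):
        raise ValueError("initial guesses must be strictly positive")
    measured = dataset.matrix()

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        p = init.replace(**dict(zip(free_params, theta)))
        return (_predict(dataset, p, rtol=sim_rtol) - measured).ravel()

    sol = least_squares(
        residual_vec, theta0, bounds=(1e-8, np.inf), method="trf",
        x_scale=np.abs(theta0), xtol=x_rtol, ftol=1e-10, gtol=1e-10,
        diff_step=diff_step, max_nfev=300,
    )
    fitted = init.replace(**dict(zip(free_params, sol.x)))
    residuals = (_predict(dataset, fitted, rtol=sim_rtol) - measured)
    return FitResult(
        params=fitted, free_params=free_params, estimates=sol.x,
        residuals=residuals, cost=float(sol.cost), converged=bool(sol.success),
        message=str(sol.message),
    )


def local_sensitivity(
    params: KineticParameters,
    x0: StateVector,
    t_grid: np.ndarray,
    outputs=("glu", "xyl", "fur", "etoh"),
    param_names=None,
    perturbation: float = 1e-3,
) -> tuple[np.ndarray, dict]:
    """Scaled local sensitivities by central finite differences.

    s_ij = (dy_i/dtheta_j) * theta_j / sc_i with sc_i the range of output
    i over the horizon (fallback: max absolute value).  Returns the
    stacked sensitivity matrix (outputs*times, params) and the parameter
    importance ranking delta^msqr_j = rms over outputs and times.
    """
    if not 0 < perturbation <= 0.1:
        raise ValueError("perturbation fraction must be in (0, 0.1]")
    if param_names is None:
        param_names = KineticParameters.names()
    param_names = tuple(param_names)
    t_grid = np.asarray(t_grid, dtype=float)

    nominal = simulate(x0, params, t_grid)
    out_idx = [IDX[name] for name in outputs]
    scales = []
    for j in out_idx:
        col = nominal.y[:, j]
        sc = col.max() - col.min()
        if sc <= 0:
            sc = max(np.abs(col).max(), 1.0)
        scales.append(sc)
    scales = np.asarray(scales)

    cols = []
    for name in param_names:
        theta = getattr(params, name)
        if not np.isfinite(theta):
            cols.append(np.zeros(t_grid.size * len(out_idx)))
            continue
        h = perturbation * theta
        up = simulate(x0, params.replace(**{name: theta + h}), t_grid)
        dn = simulate(x0, params.replace(**{name: theta - h}), t_grid)
        dy = (up.y[:, out_idx] - dn.y[:, out_idx]) / (2.0 * h)
        cols.append((dy * theta / scales).T.ravel())
    s = np.column_stack(cols)
    importance = np.sqrt(np.mean(s**2, axis=0))
    ranking = {name: float(importance[j])
               for j, name in sorted(enumerate(param_names),
                                     key=lambda kv: -importance[kv[0]])}
    return s, ranking


def collinearity_index(sensitivity: np.ndarray, subset_cols) -> float:
    """Identifiability of a parameter subset: 1/sqrt(min eigenvalue) of the
    Gram matrix of unit-normalized sensitivity columns.  1 = orthogonal
    columns; large values mean the subset is jointly unidentifiable."""
    subset_cols = list(subset_cols)
    if len(subset_cols) < 2:
        raise ValueError("subset must contain at least 2 parameters")
    s = np.asarray(sensitivity, dtype=float)[:, subset_cols]
    norms = np.linalg.norm(s, axis=0)
    if np.any(norms == 0):
        return float("inf")
    s_tilde = s / norms
    lam_min = float(np.linalg.eigvalsh(s_tilde.T @ s_tilde).min())
    if lam_min <= 0:
        return float("inf")
    return 1.0 / np.sqrt(lam_min)


@dataclass(frozen=True)
class BootstrapResult:
    """Population of re-estimated parameters from residual bootstrap."""

    free_params: tuple
    population: np.ndarray    # (n_replicates, n_params)
    mean: np.ndarray
    sd: np.ndarray
    covariance: np.ndarray
    n_dropped: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"parameter": self.free_params, "mean": self.mean, "sd": self.sd}
        )


def bootstrap_estimate(
    dataset: FitDataset,
    free_params,
    init: KineticParameters,
    replicates: int = 100,
    seed: int | None = None,
    reference: FitResult | None = None,
    max_dropped_frac: float = 0.1,
    refit_x_rtol: float = 1e-6,
) -> BootstrapResult:
    """Residual-bootstrap uncertainty of the least-squares estimates.

    Residuals of the reference fit are resampled with replacement
    *within each measured state* (pools are not mixed across analytes of
    different magnitude), added to the reference model prediction, and
    the free parameters are re-estimated on each synthetic dataset.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rng = np.random.default_rng(seed)
    free_params = tuple(free_params)
    if reference is None:
        reference = fit_least_squares(dataset, free_params, init)
    pred = _predict(dataset, reference.params)
    resid = reference.residuals  # model - measured
    n_t = dataset.times.size

    population = []
    dropped = 0
    for _ in range(replicates):
        resampled = np.column_stack([
            resid[rng.integers(0, n_t, size=n_t), j] for j in range(resid.shape[1])
        ])
        # synthetic readouts are left unclipped: near-zero concentrations
        # legitimately scatter below zero, and flooring them would bias
        # the tail of the profile (and hence the re-estimates) upward
        synthetic = {
            name: pred[:, j] + resampled[:, j]
            for j, name in enumerate(dataset.state_names)
        }
        ds = FitDataset(times=dataset.times, measurements=synthetic, x0=dataset.x0)
        try:
            fit = fit_least_squares(ds, free_params, reference.params,
                                    x_rtol=refit_x_rtol)
        except Exception:
            dropped += 1
            continue
        if not fit.converged:
            dropped += 1
            continue
        population.append(fit.estimates)
    if dropped > max_dropped_frac * replicates:
        raise RuntimeError(f"{dropped}/{replicates} bootstrap replicates failed")
    pop = np.vstack(population)
    return BootstrapResult(
        free_params=free_params, population=pop,
        mean=pop.mean(axis=0), sd=pop.std(axis=0, ddof=1),
        covariance=np.atleast_2d(np.cov(pop, rowvar=False)),
        n_dropped=dropped,
    )


def propagate_uncertainty(
    boot: BootstrapResult,
    base_params: KineticParameters,
    x0: StateVector,
    t_grid: np.ndarray,
    draws: int = 500,
    seed: int | None = None,
    quantiles=(2.5, 50.0, 97.5),
) -> dict:
    """Monte Carlo propagation of the bootstrap parameter uncertainty.

    Parameter vectors are drawn from N(mean, covariance) truncated at
    positivity, the model is simulated for each draw, and per-state
    quantile bands over time are returned as
    {state: (len(quantiles), len(t_grid)) array}.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    cov = boot.covariance
    if np.any(np.linalg.eigvalsh(cov) < -1e-10):
        raise ValueError("bootstrap covariance must be PSD")

    sims = []
    rejections = 0
    attempts = 0
    while len(sims) < draws:
        theta = rng.multivariate_normal(boot.mean, cov)
        attempts += 1
        if np.any(theta <= 0):
            rejections += 1
            if attempts > 2 * draws and rejections > 0.5 * attempts:
                import warnings

                warnings.warn("more than 50% of draws rejected at the positivity "
                              "truncation; covariance may be implausible")
                attempts = -np.inf  # warn once
            continue
        p = base_params.replace(**dict(zip(boot.free_params, theta)))
        sims.append(simulate(x0, p, t_grid).y)
    stack = np.stack(sims)  # (draws, n_t, 8)
    from .kinetics import STATE_NAMES

    return {
        name: np.percentile(stack[:, :, j], quantiles, axis=0)
        for j, name in enumerate(STATE_NAMES)
    }
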