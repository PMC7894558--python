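"""PLS calibration of mid-infrared spectra for Glu, Xyl and EtOH.

Three independent single-response PLS models map preprocessed absorbance
spectra (950-1550 cm^-1 window, first difference along wavenumber, mean
centering) to analyte concentrations.  The number of latent variables is
chosen by leave-one-out cross-validation, minimizing RMSECV with a
parsimony tie-break.  Fitting is delegated to scikit-learn's NIPALS PLS;
prediction uses the stored centering vectors and coefficient vector so a
serialized model is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "Spectrum",
    "CalibrationSet",
    "PLSModel",
    "DEFAULT_WINDOW",
    "preprocess",
    "fit_pls",
    "select_latent_variables",
    "predict_concentrations",
]

#: Spectral window used for calibration, cm^-1.
DEFAULT_WINDOW = (950.0, 1550.0)


@dataclass(frozen=True)
class Spectrum:
    """Absorbance on a uniform ascending wavenumber grid (1 cm^-1 spacing)."""

    wavenumbers: np.ndarray  # cm^-1
    absorbance: np.ndarray   # a.u.
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be matching 1-D arrays")
        d = np.diff(wn)
        if wn.size >= 2 and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("wavenumber grid must be ascending and uniform")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class CalibrationSet:
    """Calibration spectra paired with reference concentrations (g/L)."""

    spectra: list
    references: dict  # analyte name -> array of concentrations

    def __post_init__(self) -> None:
        n = len(self.spectra)
        if n < 6:
            raise ValueError("calibration set needs at least 6 samples")
        for name, vals in self.references.items():
            if len(vals) != n:
                raise ValueError(f"reference length mismatch for {name!r}")


def preprocess(spectrum: Spectrum, window: tuple = DEFAULT_WINDOW) -> np.ndarray:
    """Crop to ``window`` and take the first difference along wavenumber.

    The derivative kills constant baseline offsets; mean centering is
    applied at fit/predict time from stored training means.  Output
    length is (window points - 1).
    """
    lo, hi = window
    wn = spectrum.wavenumbers
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(
            f"window ({lo}, {hi}) outside available grid ({wn[0]}, {wn[-1]}) cm^-1"
        )
    mask = (wn >= lo) & (wn <= hi)
    return np.diff(spectrum.absorbance[mask])


def _feature_matrix(spectra, window) -> np.ndarray:
    return np.vstack([preprocess(s, window) for s in spectra])


@dataclass(frozen=True)
class PLSModel:
    """A fitted single-analyte PLS calibration."""

    analyte: str
    window: tuple
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    rmsecv: np.ndarray = field(default=None)  # RMSECV per LV count (1..max_lv)
    explained_x: float = float("nan")  # fraction of X-block variance captured
    explained_y: float = float("nan")  # fraction of Y-block variance captured

    def predict(self, spectrum: Spectrum) -> float:
        xw = preprocess(spectrum, self.window)
        if xw.size != self.coef.size:
            raise ValueError(
                f"grid mismatch: model expects {self.coef.size} features, got {xw.size}"
            )
        return float((xw - self.x_mean) @ self.coef + self.y_mean)


def _fit_raw(x: np.ndarray, y: np.ndarray, n_lv: int):
    """Fit NIPALS PLS1 and return (coef, x_mean, y_mean, frac X var, frac Y var)."""
    import warnings

    pls = PLSRegression(n_components=n_lv, scale=False)
    with warnings.catch_warnings():
        # benign on exact-rank problems: y residual deflates to a constant
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(x, y)
    xc = x - x.mean(axis=0)
    # X-block variance captured by the score/loading reconstruction
    x_hat = pls.x_scores_ @ pls.x_loadings_.T
    ss_x = float(np.sum(xc**2))
    exp_x = 1.0 - float(np.sum((xc - x_hat) ** 2)) / ss_x if ss_x > 0 else 1.0
    y_fit = pls.predict(x).ravel()
    ss_y = float(np.sum((y - y.mean()) ** 2))
    exp_y = 1.0 - float(np.sum((y - y_fit) ** 2)) / ss_y if ss_y > 0 else 1.0
    return pls.coef_.ravel(), x.mean(axis=0), float(y.mean()), exp_x, exp_y


def _max_feasible_lv(x: np.ndarray, requested: int) -> int:
    return int(min(requested, x.shape[0] - 1, x.shape[1]))


def select_latent_variables(
    calibration: CalibrationSet,
    analyte: str,
    max_lv: int = 10,
    window: tuple = DEFAULT_WINDOW,
    tie_tol: float = 0.01,
) -> tuple[int, np.ndarray]:
    """Leave-one-out RMSECV over 1..max_lv latent variables.

    Returns the smallest LV count whose RMSECV is within ``tie_tol``
    (relative) of the minimum, and the full RMSECV curve.
    """
    x = _feature_matrix(calibration.spectra, window)
    y = np.asarray(calibration.references[analyte], dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    max_lv = _max_feasible_lv(x, max_lv)
    errors = np.zeros((max_lv, n))
    for i in range(n):
        keep = np.arange(n) != i
        xt, yt = x[keep], y[keep]
        lv_cap = _max_feasible_lv(xt, max_lv)
        for lv in range(1, max_lv + 1):
            coef, xm, ym, _, _ = _fit_raw(xt, yt, min(lv, lv_cap))
            errors[lv - 1, i] = (x[i] - xm) @ coef + ym - y[i]
    rmsecv = np.sqrt(np.mean(errors**2, axis=1))
    best = float(rmsecv.min())
    # parsimony: smallest LV within tie_tol (relative) of the minimum; the
    # absolute floor keeps exact-rank noiseless problems from chasing
    # meaningless sub-machine-precision improvements at high LV counts
    threshold = best * (1.0 + tie_tol) + 1e-8 * (float(np.std(y)) + 1.0)
    chosen = int(np.argmax(rmsecv <= threshold)) + 1
    return chosen, rmsecv


def fit_pls(
    calibration: CalibrationSet,
    analyte: str,
    max_lv: int = 10,
    window: tuple = DEFAULT_WINDOW,
    n_lv: int | None = None,
) -> PLSModel:
    """Fit the PLS1 calibration for one analyte.

    If ``n_lv`` is not given, it is selected by leave-one-out RMSECV.
    """
    x = _feature_matrix(calibration.spectra, window)
    y = np.asarray(calibration.references[analyte], dtype=float)
    if n_lv is None:
        n_lv, rmsecv = select_latent_variables(calibration, analyte, max_lv, window)
    else:
        cap = _max_feasible_lv(x, n_lv)
        if cap < n_lv:
            import warnings

            warnings.warn(f"requested {n_lv} LVs truncated to rank limit {cap}")
            n_lv = cap
        rmsecv = None
    coef, xm, ym, exp_x, exp_y = _fit_raw(x, y, n_lv)
    return PLSModel(
        analyte=analyte, window=tuple(window), n_lv=n_lv, x_mean=xm, y_mean=ym,
        coef=coef, rmsecv=rmsecv, explained_x=exp_x, explained_y=exp_y,
    )


def predict_concentrations(models: dict, spectrum: Spectrum) -> dict:
    """Apply each analyte's calibration to one spectrum; raw values, no clipping."""
    return {name: model.predict(spectrum) for name, model in models.items()}
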