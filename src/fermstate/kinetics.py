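"""Kinetic model of glucose/xylose co-fermentation by S. cerevisiae.

Eight states — glucose (Glu), xylose (Xyl), furfural (Fur), furfuryl
alcohol (FA), 5-hydroxymethylfurfural (5-HMF), acetic acid (HAc),
ethanol (EtOH) and biomass (X), all in g/L — evolve under five
biomass-specific uptake processes (Glu, Xyl, Fur, 5-HMF, HAc) mapped to
the states through a fixed stoichiometric matrix.  Substrate uptake is
Monod with substrate inhibition; inhibitor uptake is plain Monod; the
hydrolysate inhibitors (Fur, FA, 5-HMF, HAc) and the product (EtOH)
attenuate sugar uptake multiplicatively, and glucose competitively
inhibits xylose uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "STATE_NAMES",
    "NO_INHIBITION",
    "StateVector",
    "KineticParameters",
    "Trajectory",
    "stoichiometric_matrix",
    "substrate_uptake_rate",
    "inhibitor_uptake_rate",
    "inhibition_factor",
    "product_inhibition_factor",
    "competitive_inhibition_factor",
    "specific_rates",
    "reaction_rhs",
    "simulate",
    "jacobian",
]

#: Canonical component order used by every array in the package.
STATE_NAMES = ("glu", "xyl", "fur", "fa", "hmf", "hac", "etoh", "x")
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = 8

#: Sentinel meaning "this inhibition term is absent" (K_i -> infinity).
NO_INHIBITION = math.inf


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"parameter {name!r} must be > 0, got {value!r}")


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value >= 0:
            raise ValueError(f"{name!r} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class StateVector:
    """Concentrations of the eight model components, g/L."""

    glu: float
    xyl: float
    fur: float
    fa: float
    hmf: float
    hac: float
    etoh: float
    x: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state: {self}")
        if np.any(arr < 0):
            raise ValueError(f"negative concentration in state: {self}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.glu, self.xyl, self.fur, self.fa, self.hmf, self.hac, self.etoh, self.x],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_STATES,):
            raise ValueError(f"expected shape ({N_STATES},), got {arr.shape}")
        return cls(*arr)


@dataclass(frozen=True)
class KineticParameters:
    """Rate, inhibition and yield constants of the fermentation model.

    Units: vmax_* in g substrate / g biomass / h; all K-type constants in
    g/L; gamma_* dimensionless; yields y_* in g/g.  ``math.inf`` is the
    documented sentinel for an absent inhibition term.
    """

    # substrate uptake (Monod + substrate inhibition + product inhibition)
    vmax_glu: float = 2.7
    k_glu: float = 0.57
    ki_glu: float = 284.0
    pmax_glu: float = 95.0
    gamma_glu: float = 1.29
    vmax_xyl: float = 0.60
    k_xyl: float = 3.4
    ki_xyl: float = 600.0
    pmax_xyl: float = 60.0
    gamma_xyl: float = 1.04
    # inhibitor uptake (plain Monod)
    vmax_fur: float = 0.25
    ksp_fur: float = 0.20
    vmax_hmf: float = 0.12
    ksp_hmf: float = 0.50
    vmax_hac: float = 0.09
    ksp_hac: float = 2.0
    # inhibition of sugar uptake by hydrolysate compounds
    ki_fur_glu: float = 2.0
    ki_fur_xyl: float = 1.5
    ki_fa_glu: float = 5.0
    ki_fa_xyl: float = 4.0
    ki_hmf_glu: float = 3.0
    ki_hmf_xyl: float = 2.5
    ki_hac_glu: float = 5.0
    ki_hac_xyl: float = 6.0
    # competitive inhibition of xylose uptake by glucose
    ki_glu_xyl: float = 3.0
    # yields, g/g
    y_etoh_glu: float = 0.45
    y_etoh_xyl: float = 0.40
    y_x_glu: float = 0.115
    y_x_xyl: float = 0.10
    y_fa_fur: float = 0.90
    y_hac_hmf: float = 0.53

    def __post_init__(self) -> None:
        yields = {"y_etoh_glu", "y_etoh_xyl", "y_x_glu", "y_x_xyl", "y_fa_fur", "y_hac_hmf"}
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"parameter {f.name!r} must be > 0, got {v!r}")
            if f.name in yields and not v <= 1.2:
                raise ValueError(f"yield {f.name!r} must be in (0, 1.2], got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **updates: float) -> "KineticParameters":
        d = self.to_dict()
        d.update(updates)
        return KineticParameters.from_dict(d)

    @classmethod
    def names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


from functools import lru_cache


@lru_cache(maxsize=64)
def _stoich_cached(p: KineticParameters) -> np.ndarray:
    return stoichiometric_matrix(p)


def stoichiometric_matrix(p: KineticParameters) -> np.ndarray:
    """5 uptake processes (Glu, Xyl, Fur, 5-HMF, HAc) x 8 components.

    Each row consumes exactly one compound (-1) and credits its products
    through the yields.
    """
    s = np.zeros((5, N_STATES))
    s[0, IDX["glu"]] = -1.0
    s[0, IDX["etoh"]] = p.y_etoh_glu
    s[0, IDX["x"]] = p.y_x_glu
    s[1, IDX["xyl"]] = -1.0
    s[1, IDX["etoh"]] = p.y_etoh_xyl
    s[1, IDX["x"]] = p.y_x_xyl
    s[2, IDX["fur"]] = -1.0
    s[2, IDX["fa"]] = p.y_fa_fur
    s[3, IDX["hmf"]] = -1.0
    s[3, IDX["hac"]] = p.y_hac_hmf
    s[4, IDX["hac"]] = -1.0
    return s


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def substrate_uptake_rate(s: float, vmax: float, ks: float, ki: float = NO_INHIBITION) -> float:
    """Monod uptake with substrate inhibition: vmax*S / (KS + S + S^2/Ki).

    ``ki = math.inf`` (the NO_INHIBITION sentinel) recovers plain Monod.
    """
    _check_nonneg(s=s)
    _check_positive(vmax=vmax, ks=ks, ki=ki)
    return vmax * s / (ks + s + s * s / ki)


def _d_substrate_uptake(s: float, vmax: float, ks: float, ki: float) -> float:
    den = ks + s + s * s / ki
    return vmax * (ks - s * s / ki) / (den * den)


def inhibitor_uptake_rate(i: float, vmax: float, ksp: float) -> float:
    """Plain Monod uptake of an inhibitor: vmax*I / (KSP + I)."""
    _check_nonneg(i=i)
    _check_positive(vmax=vmax, ksp=ksp)
    return vmax * i / (ksp + i)


def _d_inhibitor_uptake(i: float, vmax: float, ksp: float) -> float:
    den = ksp + i
    return vmax * ksp / (den * den)


def inhibition_factor(i: float, ki: float) -> float:
    """Non-competitive attenuation 1 / (1 + I/Ki), in (0, 1]."""
    _check_nonneg(i=i)
    _check_positive(ki=ki)
    return 1.0 / (1.0 + i / ki)


def _d_inhibition_factor(i: float, ki: float) -> float:
    den = 1.0 + i / ki
    return -1.0 / (ki * den * den)


def product_inhibition_factor(p_conc: float, pmax: float, gamma: float) -> float:
    """Empirical product inhibition (1 - P/Pmax)^gamma, clamped to 0 above Pmax."""
    _check_nonneg(p=p_conc)
    _check_positive(pmax=pmax, gamma=gamma)
    if p_conc >= pmax:
        return 0.0
    return (1.0 - p_conc / pmax) ** gamma


def _d_product_inhibition(p_conc: float, pmax: float, gamma: float) -> float:
    if p_conc >= pmax:
        return 0.0
    return -(gamma / pmax) * (1.0 - p_conc / pmax) ** (gamma - 1.0)


def competitive_inhibition_factor(glu: float, ki_glu_xyl: float) -> float:
    """Glucose repression of xylose uptake, same hyperbolic form as
    :func:`inhibition_factor`."""
    return inhibition_factor(glu, ki_glu_xyl)


# ---------------------------------------------------------------------------
# right-hand side and Jacobian
# ---------------------------------------------------------------------------

def _rate_factor_table(x: np.ndarray, p: KineticParameters):
    """Per uptake process: list of (state index, factor value, d factor/d state).

    Each specific rate is a product of univariate factors of distinct
    states, which makes both the rate and its gradient cheap to assemble.
    Negative state values (integrator overshoot) are clamped to zero
    before evaluating the rate laws.
    """
    # unvalidated fast path: this sits inside the ODE integrator's inner
    # loop, so the formulas are inlined rather than routed through the
    # argument-checked public rate functions
    glu = x[0] if x[0] > 0 else 0.0
    xyl = x[1] if x[1] > 0 else 0.0
    fur = x[2] if x[2] > 0 else 0.0
    fa = x[3] if x[3] > 0 else 0.0
    hmf = x[4] if x[4] > 0 else 0.0
    hac = x[5] if x[5] > 0 else 0.0
    etoh = x[6] if x[6] > 0 else 0.0

    def monod_si(i, s, vmax, ks, ki):
        den = ks + s + s * s / ki
        return (i, vmax * s / den, vmax * (ks - s * s / ki) / (den * den))

    def monod(i, s, vmax, ksp):
        den = ksp + s
        return (i, vmax * s / den, vmax * ksp / (den * den))

    def inh(i, conc, ki):
        den = 1.0 + conc / ki
        return (i, 1.0 / den, -1.0 / (ki * den * den))

    def prod_inh(pconc, pmax, gamma):
        if pconc >= pmax:
            return (6, 0.0, 0.0)
        base = 1.0 - pconc / pmax
        return (6, base**gamma, -(gamma / pmax) * base ** (gamma - 1.0))

    glu_factors = [
        monod_si(0, glu, p.vmax_glu, p.k_glu, p.ki_glu),
        inh(2, fur, p.ki_fur_glu),
        inh(3, fa, p.ki_fa_glu),
        inh(4, hmf, p.ki_hmf_glu),
        inh(5, hac, p.ki_hac_glu),
        prod_inh(etoh, p.pmax_glu, p.gamma_glu),
    ]
    xyl_factors = [
        monod_si(1, xyl, p.vmax_xyl, p.k_xyl, p.ki_xyl),
        inh(2, fur, p.ki_fur_xyl),
        inh(3, fa, p.ki_fa_xyl),
        inh(4, hmf, p.ki_hmf_xyl),
        inh(5, hac, p.ki_hac_xyl),
        prod_inh(etoh, p.pmax_xyl, p.gamma_xyl),
        inh(0, glu, p.ki_glu_xyl),
    ]
    fur_factors = [monod(2, fur, p.vmax_fur, p.ksp_fur)]
    # furfural is detoxified first: it suppresses 5-HMF conversion; the
    # glucose-phase furfural constant is reused for this term
    hmf_factors = [monod(4, hmf, p.vmax_hmf, p.ksp_hmf), inh(2, fur, p.ki_fur_glu)]
    hac_factors = [monod(5, hac, p.vmax_hac, p.ksp_hac)]
    return [glu_factors, xyl_factors, fur_factors, hmf_factors, hac_factors]


def _specific_rates_scalar(x, p: KineticParameters):
    """The five biomass-specific uptake rates as plain floats (hot path)."""
    glu = x[0] if x[0] > 0 else 0.0
    xyl = x[1] if x[1] > 0 else 0.0
    fur = x[2] if x[2] > 0 else 0.0
    fa = x[3] if x[3] > 0 else 0.0
    hmf = x[4] if x[4] > 0 else 0.0
    hac = x[5] if x[5] > 0 else 0.0
    etoh = x[6] if x[6] > 0 else 0.0

    f_fur_g = 1.0 / (1.0 + fur / p.ki_fur_glu)
    q_glu = (
        p.vmax_glu * glu / (p.k_glu + glu + glu * glu / p.ki_glu)
        * f_fur_g
        / (1.0 + fa / p.ki_fa_glu)
        / (1.0 + hmf / p.ki_hmf_glu)
        / (1.0 + hac / p.ki_hac_glu)
        * ((1.0 - etoh / p.pmax_glu) ** p.gamma_glu if etoh < p.pmax_glu else 0.0)
    )
    q_xyl = (
        p.vmax_xyl * xyl / (p.k_xyl + xyl + xyl * xyl / p.ki_xyl)
        / (1.0 + fur / p.ki_fur_xyl)
        / (1.0 + fa / p.ki_fa_xyl)
        / (1.0 + hmf / p.ki_hmf_xyl)
        / (1.0 + hac / p.ki_hac_xyl)
        * ((1.0 - etoh / p.pmax_xyl) ** p.gamma_xyl if etoh < p.pmax_xyl else 0.0)
        / (1.0 + glu / p.ki_glu_xyl)
    )
    q_fur = p.vmax_fur * fur / (p.ksp_fur + fur)
    q_hmf = p.vmax_hmf * hmf / (p.ksp_hmf + hmf) * f_fur_g
    q_hac = p.vmax_hac * hac / (p.ksp_hac + hac)
    return q_glu, q_xyl, q_fur, q_hmf, q_hac


def _rhs_core(x, p: KineticParameters) -> np.ndarray:
    """Unvalidated rhs used inside the integrator's inner loop."""
    biomass = x[7] if x[7] > 0 else 0.0
    q_glu, q_xyl, q_fur, q_hmf, q_hac = _specific_rates_scalar(x, p)
    r_glu = q_glu * biomass
    r_xyl = q_xyl * biomass
    r_fur = q_fur * biomass
    r_hmf = q_hmf * biomass
    r_hac = q_hac * biomass
    return np.array([
        -r_glu,
        -r_xyl,
        -r_fur,
        p.y_fa_fur * r_fur,
        -r_hmf,
        p.y_hac_hmf * r_hmf - r_hac,
        p.y_etoh_glu * r_glu + p.y_etoh_xyl * r_xyl,
        p.y_x_glu * r_glu + p.y_x_xyl * r_xyl,
    ])


def specific_rates(x: np.ndarray, p: KineticParameters) -> np.ndarray:
    """The five biomass-specific uptake rates (g substrate/g biomass/h)."""
    return np.array(_specific_rates_scalar(np.asarray(x, dtype=float), p))


def reaction_rhs(x: np.ndarray, p: KineticParameters) -> np.ndarray:
    """d(state)/dt in g/L/h.

    Specific rates are multiplied by the biomass concentration X and
    mapped through the stoichiometric matrix; X = 0 freezes the system.
    """
    x = np.asarray(x, dtype=float)
    biomass = max(x[IDX["x"]], 0.0)
    q = specific_rates(x, p)
    dxdt = _stoich_cached(p).T @ (q * biomass)
    if not np.all(np.isfinite(dxdt)):
        raise FloatingPointError(f"non-finite derivative at state {x!r}")
    return dxdt


def jacobian(x: np.ndarray, p: KineticParameters) -> np.ndarray:
    """Analytic 8x8 Jacobian d(rhs)/d(state).

    Gradients of each product-form specific rate are assembled with the
    product rule over its univariate factors; the biomass column is the
    specific-rate vector itself (rates are linear in X).
    """
    x = np.asarray(x, dtype=float)
    biomass = max(x[IDX["x"]], 0.0)
    table = _rate_factor_table(x, p)
    dq = np.zeros((5, N_STATES))  # gradient of volumetric rate q_i * X
    for i, factors in enumerate(table):
        values = [f[1] for f in factors]
        q_i = math.prod(values)
        for k, (idx, _, dfk) in enumerate(factors):
            others = math.prod(v for j, v in enumerate(values) if j != k)
            dq[i, idx] += biomass * others * dfk
        dq[i, IDX["x"]] += q_i
    return _stoich_cached(p).T @ dq


@dataclass(frozen=True)
class Trajectory:
    """Simulated state history: time grid (h) and an (n, 8) state matrix."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or y.shape != (t.size, N_STATES):
            raise ValueError(f"shape mismatch: t {t.shape}, y {y.shape}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def state(self, name: str) -> np.ndarray:
        return self.y[:, IDX[name]]

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of all states onto ``times``."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return np.column_stack([np.interp(times, self.t, self.y[:, j]) for j in range(N_STATES)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.y, columns=list(STATE_NAMES)).assign(time_h=self.t)[
            ["time_h", *STATE_NAMES]
        ]


def simulate(
    x0: StateVector | np.ndarray,
    params: KineticParameters,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over ``t_grid`` (hours, strictly increasing).

    Uses LSODA (stiffness-switching, adaptive step).  Tiny negative
    excursions from the integrator are floored at zero on output.
    """
    x0 = x0.to_array() if isinstance(x0, StateVector) else np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D, strictly increasing, length >= 2")

    from scipy.integrate import odeint

    y, info = odeint(
        lambda x, t: _rhs_core(x, params),
        x0,
        t_grid,
        Dfun=lambda x, t: jacobian(x, params),
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=10_000,
    )
    if info["message"] != "Integration successful.":
        t_fail = info["tcur"][-1] if len(info.get("tcur", [])) else t_grid[0]
        raise RuntimeError(f"integration failed near t={t_fail:.3f} h: {info['message']}")
    if not np.all(np.isfinite(y)):
        raise RuntimeError("integration produced non-finite values")
    y = np.clip(y, 0.0, None)
    y[0] = x0
    return Trajectory(t=t_grid, y=y)
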