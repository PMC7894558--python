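"""Virtual plant: synthetic fermenter plus ATR mid-infrared instrument.

Generates everything the monitoring pipeline consumes — ground-truth
batch trajectories from the kinetic model, Beer-Lambert absorbance
spectra with overlapping analyte bands, the glycerol and biomass matrix
interference that biases early-batch predictions, per-minute spectra
streams, hourly HPLC-style offline samples, and transient sensor
disturbances (recirculation-loop clogging, bubbles).

The absorptivity library is a frozen, deterministic fixture: sums of
Gaussian bands at fixed positions inside the 950-1550 cm^-1 fingerprint
region, chosen so the three analytes overlap strongly but remain
identifiable, and so glycerol overlaps the xylose bands (the origin of
the early-batch xylose bias seen with end-of-fermentation calibration
matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import Spectrum
from .kinetics import IDX, KineticParameters, StateVector, Trajectory, simulate

__all__ = [
    "ScenarioSpec",
    "DisturbanceWindow",
    "AbsorptivityLibrary",
    "BatchData",
    "generate_truth",
    "synthesize_spectrum",
    "emit_batch",
    "inject_disturbance",
]

#: Instrument wavenumber grid: 428-1833 cm^-1 at 1 cm^-1.
INSTRUMENT_GRID = np.arange(428.0, 1834.0)


def _gaussian_bands(grid: np.ndarray, bands) -> np.ndarray:
    profile = np.zeros_like(grid)
    for center, width, height in bands:
        profile += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return profile


@dataclass(frozen=True)
class AbsorptivityLibrary:
    """Pure-component absorptivity profiles (a.u. per g/L) on a fixed grid."""

    grid: np.ndarray
    profiles: dict  # species -> profile array

    @classmethod
    def default(cls, grid: np.ndarray = INSTRUMENT_GRID) -> "AbsorptivityLibrary":
        # Band positions loosely follow the C-O / C-C stretch fingerprint
        # region of sugars and ethanol; heights scaled to ~1e-3 a.u. per g/L.
        profiles = {
            "glu": 1.2e-3 * _gaussian_bands(grid, [(1035, 18, 1.0), (1080, 14, 0.75), (1150, 24, 0.45)]),
            "xyl": 1.1e-3 * _gaussian_bands(grid, [(1045, 16, 0.9), (990, 13, 0.85), (1160, 22, 0.35)]),
            "etoh": 1.0e-3 * _gaussian_bands(grid, [(1046, 10, 1.0), (1088, 13, 0.85), (1275, 30, 0.3)]),
            # glycerol's C-O stretches sit almost on top of the xylose and
            # ethanol bands, which is what corrupts those predictions when
            # the matrix glycerol level deviates from the calibration matrix
            "glycerol": 2.5e-3 * _gaussian_bands(grid, [(1045, 16, 1.0), (1090, 15, 0.8), (990, 13, 0.6)]),
            # biomass: broad scattering background, amide II (~1545 cm^-1)
            # and cell-wall glucan C-O bands that shadow the glucose bands
            "biomass": 2.0e-3 * _gaussian_bands(grid, [(1200, 350, 0.25), (1545, 28, 0.5), (1035, 20, 0.55), (1082, 16, 0.45)]),
        }
        return cls(grid=grid, profiles=profiles)

    def analyte_condition_number(self, window=(950.0, 1550.0)) -> float:
        mask = (self.grid >= window[0]) & (self.grid <= window[1])
        m = np.column_stack([self.profiles[a][mask] for a in ("glu", "xyl", "etoh")])
        return float(np.linalg.cond(m))


@dataclass(frozen=True)
class DisturbanceWindow:
    """A transient sensor fault: ``mode`` is 'clog' or 'bubble'."""

    start_h: float
    duration_h: float
    mode: str = "clog"
    severity: float = 0.6  # peak fraction of signal lost (clog) / spike size (bubble)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything that defines one synthetic batch experiment."""

    x0: StateVector
    params: KineticParameters
    batch_hours: float = 30.0
    # in-line spectra of the flowing, solids-laden broth are much noisier
    # than static calibration measurements (~1 g/L prediction scatter)
    spectra_noise_sd: float = 1e-3    # a.u., iid per grid point
    glycerol_plateau: float = 3.0     # g/L reached by end of the glucose phase
    biomass_scatter: float = 1.0      # multiplier on the biomass baseline profile
    offline_noise_sd: float = 0.3     # g/L, HPLC repeatability
    offline_interval_h: float = 1.0
    disturbances: tuple = ()
    seed: int = 0

    @classmethod
    def default(cls, **overrides) -> "ScenarioSpec":
        """Batch-fermentation conditions of the reference experiment:
        37 g/L glucose, 22 g/L xylose, 1 g/L inoculum, dilute hydrolysate
        inhibitor levels."""
        base = dict(
            x0=StateVector(glu=37.0, xyl=22.0, fur=0.5, fa=0.0, hmf=0.15,
                           hac=2.5, etoh=0.0, x=1.0),
            params=KineticParameters(),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class BatchData:
    """Output of :func:`emit_batch`."""

    truth: Trajectory
    glycerol: np.ndarray        # g/L at each truth time point
    spectra: list               # per-minute Spectrum stream
    offline: pd.DataFrame       # HPLC-style table (time_h, glu, xyl, ..., etoh)


def glycerol_profile(truth: Trajectory, plateau: float) -> np.ndarray:
    """Glycerol rises with glucose consumption and plateaus with its
    exhaustion; it is not consumed during the xylose phase."""
    glu = truth.state("glu")
    glu0 = glu[0] if glu[0] > 0 else 1.0
    return plateau * np.clip(1.0 - glu / glu0, 0.0, 1.0)


def generate_truth(scenario: ScenarioSpec, dt_h: float = 1.0 / 60.0):
    """Simulate the true batch on a per-minute grid.

    Returns (trajectory, glycerol series) — glycerol is tracked outside
    the state vector because it only matters as a spectral interferent.
    """
    n = int(round(scenario.batch_hours / dt_h))
    t_grid = np.linspace(0.0, scenario.batch_hours, n + 1)
    truth = simulate(scenario.x0, scenario.params, t_grid)
    return truth, glycerol_profile(truth, scenario.glycerol_plateau)


def synthesize_spectrum(
    concentrations: dict,
    library: AbsorptivityLibrary,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    timestamp_min: float = 0.0,
) -> Spectrum:
    """Beer-Lambert forward model: absorbance = sum(c_s * profile_s) + noise."""
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}: {c}")
    a = np.zeros_like(library.grid)
    for name, c in concentrations.items():
        a = a + c * library.profiles[name]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        a = a + rng.normal(0.0, noise_sd, size=a.size)
    return Spectrum(wavenumbers=library.grid, absorbance=a, timestamp_min=timestamp_min)


def calibration_spectra(
    design_samples: np.ndarray,
    library: AbsorptivityLibrary,
    noise_sd: float = 2e-5,
    matrix_glycerol: float = 3.0,
    matrix_biomass: float = 0.5,
    seed: int | None = 0,
) -> list:
    """Spectra of semi-synthetic calibration samples.

    Samples are prepared in the end-of-fermentation matrix: the glycerol
    plateau concentration and a residual biomass level are present in
    every sample, which is exactly what leaves early-batch matrix changes
    unmodelled by the calibration.
    """
    rng = np.random.default_rng(seed)
    out = []
    for glu, xyl, etoh in np.asarray(design_samples, dtype=float):
        out.append(
            synthesize_spectrum(
                {"glu": glu, "xyl": xyl, "etoh": etoh,
                 "glycerol": matrix_glycerol, "biomass": matrix_biomass},
                library, noise_sd=noise_sd, rng=rng,
            )
        )
    return out


def emit_batch(scenario: ScenarioSpec, library: AbsorptivityLibrary) -> BatchData:
    """Run one batch: truth, per-minute spectra, hourly offline samples.

    Spectra are stamped at minutes 1..T (each is the average the
    instrument stores after a minute of acquisition); offline samples are
    taken at t = 0, 1, ..., batch_hours with additive HPLC noise.
    """
    rng = np.random.default_rng(scenario.seed)
    truth, gly = generate_truth(scenario)
    minutes = np.arange(1, int(round(scenario.batch_hours * 60)) + 1)
    states = truth.at(minutes / 60.0)
    gly_at = np.interp(minutes / 60.0, truth.t, gly)

    spectra = []
    for i, m in enumerate(minutes):
        conc = {
            "glu": states[i, IDX["glu"]],
            "xyl": states[i, IDX["xyl"]],
            "etoh": states[i, IDX["etoh"]],
            "glycerol": gly_at[i],
            "biomass": scenario.biomass_scatter * states[i, IDX["x"]],
        }
        spectra.append(
            synthesize_spectrum(conc, library, scenario.spectra_noise_sd, rng,
                                timestamp_min=float(m))
        )
    for window in scenario.disturbances:
        spectra = inject_disturbance(spectra, window, rng=rng)

    t_off = np.arange(0.0, scenario.batch_hours + 1e-9, scenario.offline_interval_h)
    off_states = truth.at(t_off)
    noise = rng.normal(0.0, scenario.offline_noise_sd, size=off_states.shape) \
        if scenario.offline_noise_sd > 0 else 0.0
    off = np.clip(off_states + noise, 0.0, None)
    offline = pd.DataFrame(
        {
            "time_h": t_off,
            "glu": off[:, IDX["glu"]],
            "xyl": off[:, IDX["xyl"]],
            "etoh": off[:, IDX["etoh"]],
            "fur": off[:, IDX["fur"]],
            "hmf": off[:, IDX["hmf"]],
            "hac": off[:, IDX["hac"]],
        }
    )
    return BatchData(truth=truth, glycerol=gly, spectra=spectra, offline=offline)


def inject_disturbance(
    spectra: list,
    window: DisturbanceWindow,
    rng: np.random.Generator | None = None,
) -> list:
    """Corrupt the spectra stream inside a disturbance window.

    'clog': the recirculation loop blocks; liquid contact with the ATR
    crystal degrades, so the live signal fades toward a stale spectrum
    (composition frozen at the window start) attenuated by a fouling
    film, with an elevated broad baseline.  Analyte signal loss makes the
    data-driven predictions collapse transiently.  'bubble': isolated
    single-spectrum spikes.
    """
    if rng is None:
        rng = np.random.default_rng()
    t0, t1 = window.start_h * 60.0, (window.start_h + window.duration_h) * 60.0
    idx = [i for i, s in enumerate(spectra) if t0 <= s.timestamp_min < t1]
    if not idx:
        return list(spectra)
    out = list(spectra)
    if window.mode == "clog":
        stale = spectra[idx[0]].absorbance
        baseline = 0.02 * np.exp(
            -0.5 * ((spectra[idx[0]].wavenumbers - 1100.0) / 300.0) ** 2
        )
        for k, i in enumerate(idx):
            # fouling fraction ramps up over the window, abrupt recovery at the end
            d = window.severity * np.sin(np.pi * min(1.0, (k + 1) / len(idx)) / 2.0) ** 0.5
            s = spectra[i]
            a = (1.0 - d) * s.absorbance + d * (0.3 * stale + baseline)
            out[i] = Spectrum(s.wavenumbers, a, s.timestamp_min)
    elif window.mode == "bubble":
        for i in idx:
            if rng.uniform() < 0.2:
                s = spectra[i]
                spike = rng.normal(0.0, window.severity * 0.01, size=s.absorbance.size)
                out[i] = Spectrum(s.wavenumbers, s.absorbance + spike, s.timestamp_min)
    else:
        raise ValueError(f"unknown disturbance mode {window.mode!r}")
    return out
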