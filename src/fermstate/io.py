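"""File formats and configuration.

Spectra are two-column plain text (wavenumber, absorbance), one file per
minute; concentration tables are comma-separated CSV with a mandatory
header; configuration is a flat YAML mapping.  All times are hours
internally; spectrum timestamps are minutes from batch start, taken from
the filename.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemometrics import PLSModel, Spectrum
from .kinetics import KineticParameters, StateVector

__all__ = [
    "read_spectrum_file",
    "write_spectrum_file",
    "read_spectra_dir",
    "write_spectra_dir",
    "read_offline_table",
    "write_offline_table",
    "load_config",
    "save_config",
    "save_pls_model",
    "load_pls_model",
    "config_hash",
]

_MINUTE_RE = re.compile(r"(\d+)(?=\D*$)")


def _timestamp_from_name(path: Path) -> float:
    m = _MINUTE_RE.search(path.stem)
    return float(m.group(1)) if m else 0.0


def read_spectrum_file(path, timestamp_min: float | None = None) -> Spectrum:
    """Parse a two-column spectrum file (whitespace or comma separated).

    A descending wavenumber grid is normalized to ascending.  The minute
    timestamp is read from the trailing integer in the filename unless
    given explicitly.
    """
    path = Path(path)
    wn, ab = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1 and any(not _is_number(p) for p in parts):
                continue  # optional header
            if len(parts) != 2 or not all(_is_number(p) for p in parts):
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            wn.append(float(parts[0]))
            ab.append(float(parts[1]))
    wn_arr = np.asarray(wn)
    ab_arr = np.asarray(ab)
    if wn_arr.size >= 2 and wn_arr[1] < wn_arr[0]:
        wn_arr, ab_arr = wn_arr[::-1], ab_arr[::-1]
    if timestamp_min is None:
        timestamp_min = _timestamp_from_name(path)
    return Spectrum(wavenumbers=wn_arr, absorbance=ab_arr, timestamp_min=timestamp_min)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_spectrum_file(spectrum: Spectrum, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1 absorbance\n")
        for w, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{w:.1f} {float(a)!r}\n")


def write_spectra_dir(spectra, directory) -> None:
    """One ``spectrum_<minute>.txt`` file per spectrum."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        write_spectrum_file(s, directory / f"spectrum_{int(round(s.timestamp_min)):05d}.txt")


def read_spectra_dir(directory) -> list:
    directory = Path(directory)
    paths = sorted(directory.glob("*.txt"), key=_timestamp_from_name)
    return [read_spectrum_file(p) for p in paths]


def read_offline_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("offline table must have a 'time_h' column")
    if np.any(np.diff(df["time_h"].to_numpy()) < 0):
        raise ValueError("offline sample times must be non-decreasing")
    return df


def write_offline_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def params_from_config(cfg: dict) -> KineticParameters:
    known = set(KineticParameters.names())
    return KineticParameters.from_dict(
        {k: v for k, v in cfg.items() if k in known}
    )


def state_from_config(cfg: dict, prefix: str = "x0_") -> StateVector:
    from .kinetics import STATE_NAMES

    return StateVector(**{n: float(cfg.get(prefix + n, 0.0)) for n in STATE_NAMES})


PLS_FORMAT_VERSION = 1


def save_pls_model(model: PLSModel, path) -> None:
    """Versioned plain-text serialization of a fitted calibration."""
    with open(path, "w") as fh:
        fh.write(f"fermstate-pls v{PLS_FORMAT_VERSION}\n")
        fh.write(f"analyte {model.analyte}\n")
        fh.write(f"window {float(model.window[0])!r} {float(model.window[1])!r}\n")
        fh.write(f"n_lv {model.n_lv}\n")
        fh.write(f"y_mean {float(model.y_mean)!r}\n")
        fh.write(f"explained_x {float(model.explained_x)!r}\n")
        fh.write(f"explained_y {float(model.explained_y)!r}\n")
        fh.write("x_mean " + " ".join(repr(float(v)) for v in model.x_mean) + "\n")
        fh.write("coef " + " ".join(repr(float(v)) for v in model.coef) + "\n")


def load_pls_model(path) -> PLSModel:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["fermstate-pls"]:
            raise ValueError(f"{path}: not a PLS model file")
        fields = {}
        for line in fh:
            key, *vals = line.split()
            fields[key] = vals
    return PLSModel(
        analyte=fields["analyte"][0],
        window=(float(fields["window"][0]), float(fields["window"][1])),
        n_lv=int(fields["n_lv"][0]),
        x_mean=np.array([float(v) for v in fields["x_mean"]]),
        y_mean=float(fields["y_mean"][0]),
        coef=np.array([float(v) for v in fields["coef"]]),
        explained_x=float(fields["explained_x"][0]),
        explained_y=float(fields["explained_y"][0]),
    )
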