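import numpy as np
import pytest

from fermstate.chemometrics import CalibrationSet, fit_pls
from fermstate.design import DesignSpace, select_design
from fermstate.kinetics import KineticParameters, StateVector
from fermstate.plant import AbsorptivityLibrary, calibration_spectra


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def ferm1_x0() -> StateVector:
    """Identification-batch initial conditions: concentrated hydrolysate,
    1.4 g/L inoculum."""
    return StateVector(glu=37.0, xyl=22.0, fur=0.5, fa=0.0, hmf=0.15,
                       hac=4.0, etoh=0.0, x=1.4)


@pytest.fixture(scope="session")
def library() -> AbsorptivityLibrary:
    return AbsorptivityLibrary.default()


@pytest.fixture(scope="session")
def design21(library):
    return select_design(DesignSpace.default(), 21, 500, seed=1)


@pytest.fixture(scope="session")
def calibration(design21, library) -> CalibrationSet:
    spectra = calibration_spectra(design21.samples, library, seed=2)
    return CalibrationSet(
        spectra=spectra,
        references={"glu": design21.samples[:, 0],
                    "xyl": design21.samples[:, 1],
                    "etoh": design21.samples[:, 2]},
    )


@pytest.fixture(scope="session")
def pls_models(calibration) -> dict:
    return {a: fit_pls(calibration, a) for a in ("glu", "xyl", "etoh")}
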