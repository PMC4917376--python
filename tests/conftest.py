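import numpy as np
import pytest

from irisqa import (
    ApertureSpec,
    BeamProfileModel,
    ChamberSpec,
    OutputFactorTable,
    default_output_factor_table,
)


@pytest.fixture(scope="session")
def chamber():
    return ChamberSpec()


@pytest.fixture(scope="session")
def model():
    """Default sigmoid-penumbra beam model (p = 3 mm, flat, tuned)."""
    return BeamProfileModel()


@pytest.fixture(scope="session")
def step_model():
    """Ideal step profile: closed-form areas, used for exact checks."""
    return BeamProfileModel(penumbra_mm=0.0)


@pytest.fixture(scope="session")
def of_table():
    return default_output_factor_table()


@pytest.fixture(scope="session")
def flat_table():
    """Constant output factor: isolates pure field-area effects."""
    return OutputFactorTable(diameters_mm=(5.0, 60.0), factors=(1.0, 1.0))


def radial_midpoint_oracle(model: BeamProfileModel, field_radius_mm: float,
                           r_max: float, n: int = 100_000) -> float:
    """Brute-force midpoint rule for ∫_0^rmax OCR(r) 2πr dr."""
    edges = np.linspace(0.0, r_max, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    h = r_max / n
    return float(np.sum(model.ocr(mid, field_radius_mm) * 2.0 * np.pi * mid) * h)


def offset_grid_oracle(model: BeamProfileModel, field_radius_mm: float,
                       r_max: float, shift_mm: float,
                       n_rho: int = 2000, n_phi: int = 2000) -> float:
    """Brute-force 2-D midpoint grid over the chamber disk, in polar
    coordinates centered on the (offset) chamber.

    The beam-axis distance of a chamber point (rho, phi) with the chamber
    center shifted by s along x is sqrt((s + rho cos phi)^2 + (rho sin phi)^2).
    """
    rho_edges = np.linspace(0.0, r_max, n_rho + 1)
    rho = 0.5 * (rho_edges[:-1] + rho_edges[1:])[:, None]
    phi_edges = np.linspace(0.0, 2.0 * np.pi, n_phi + 1)
    phi = 0.5 * (phi_edges[:-1] + phi_edges[1:])[None, :]
    d_beam = np.hypot(shift_mm + rho * np.cos(phi), rho * np.sin(phi))
    vals = model.ocr(d_beam, field_radius_mm)
    h_rho = r_max / n_rho
    h_phi = 2.0 * np.pi / n_phi
    return float(np.sum(vals * rho) * h_rho * h_phi)
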