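"""Shared fixtures: small hand-built plates and noise-free simulators."""

from __future__ import annotations

import numpy as np
import pytest

from btscreen.plate_data import PANEL, DoseSeries, Plate, Well, WellRole
from btscreen.synthetic_data import NoiseModel


def make_well(well_id: str, role: WellRole, values: dict[str, float],
              agent_id: str | None = None, dose: float | None = None,
              plate_id: str = "P1") -> Well:
    return Well(plate_id=plate_id, well_id=well_id, role=role, values=values,
                agent_id=agent_id, dose=dose,
                dose_unit="uM" if dose is not None else None)


def make_plate(agent_values: dict[float, dict[str, float]] | None = None,
               control_values: dict[str, float] | None = None,
               dmso_values: dict[str, float] | None = None,
               agent_id: str = "drugX", n_control: int = 2,
               n_dmso: int = 6) -> Plate:
    """A minimal valid plate: flat controls plus one agent's dose series."""
    control_values = control_values or {r: 100.0 for r in PANEL}
    dmso_values = dmso_values or {r: 10.0 for r in PANEL}
    wells = [
        make_well(f"C{i}", WellRole.CONTROL_STIMULATED, dict(control_values))
        for i in range(n_control)
    ]
    wells += [
        make_well(f"D{i}", WellRole.DMSO_NONSTIMULATED, dict(dmso_values))
        for i in range(n_dmso)
    ]
    for j, (dose, values) in enumerate(sorted((agent_values or {}).items())):
        wells.append(
            make_well(f"A{j}", WellRole.AGENT_STIMULATED, dict(values),
                      agent_id=agent_id, dose=dose)
        )
    return Plate(plate_id="P1", donor_pool_id="pool1", wells=wells)


@pytest.fixture
def flat_plate() -> Plate:
    """One agent at 4 doses, every readout exactly at the control mean."""
    return make_plate({d: {r: 100.0 for r in PANEL} for d in (0.1, 0.3, 1.0, 3.0)})


@pytest.fixture
def doses4() -> DoseSeries:
    return DoseSeries("template", (0.1, 0.3, 1.0, 3.0), "uM")


@pytest.fixture
def quiet_noise() -> NoiseModel:
    """The default noise model with all log10 sds set to zero."""
    return NoiseModel().with_uniform_sd(0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
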