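"""Shared fixtures: simulated activity–voltage datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from leafletshift import (
    DEFAULT_MODEL,
    LeafletState,
    MembraneSpec,
    SimulationCondition,
    condition_seed,
    simulate_trace,
)
from leafletshift.analysis import SigmaCurve, current_sigma, estimate_delta_u

VOLTAGES = (-40.0, -45.0, -50.0, -55.0, -60.0, -65.0)
N_SEEDS = 10
MASTER_SEED = 20110927

#: generator membranes producing the study's equivalent voltage shifts:
#: cis-SDS-like (-10), RH-421-like (-3.7), a symmetric perturbation (0,
#: exercising the electric cancellation), phlorizin-like (+2.8) and
#: trans-SDS-like (+10)
SHIFT_MEMBRANES = {
    -10.0: MembraneSpec(cis=LeafletState(surface_potential=-10.0, label="sds_cis")),
    -3.7: MembraneSpec(trans=LeafletState(dipole_shift=3.7, label="rh421")),
    0.0: MembraneSpec(
        cis=LeafletState(dipole_shift=5.0, label="sym"),
        trans=LeafletState(dipole_shift=5.0, label="sym"),
    ),
    2.8: MembraneSpec(trans=LeafletState(dipole_shift=-2.8, label="phlorizin")),
    10.0: MembraneSpec(trans=LeafletState(surface_potential=-10.0, label="sds_trans")),
}


def sigma_curve(membrane: MembraneSpec, tag: str, seed_index: int,
                duration: float = 20.0) -> SigmaCurve:
    points = []
    for v in VOLTAGES:
        cond = SimulationCondition(
            v_applied=v,
            membrane=membrane,
            duration=duration,
            seed=condition_seed(MASTER_SEED + seed_index, f"{tag}|{v:g}"),
            label=tag,
        )
        points.append((v, current_sigma(simulate_trace(DEFAULT_MODEL, cond))))
    return SigmaCurve(points=tuple(points), label=tag)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Control and perturbed sigma(V) curves plus recovered delta_U estimates.

    Ten independent repeats of the six-voltage sweep for the control membrane
    and for each generator shift in SHIFT_MEMBRANES; the estimator sees the
    known acquisition noise floor.
    """
    control = MembraneSpec()
    control_curves = [
        sigma_curve(control, "control", s) for s in range(N_SEEDS)
    ]
    curves = {
        shift: [sigma_curve(mem, f"shift{shift:+g}", s) for s in range(N_SEEDS)]
        for shift, mem in SHIFT_MEMBRANES.items()
    }
    estimates = {
        shift: [
            estimate_delta_u(
                control_curves[s], curves[shift][s],
                noise_sd=DEFAULT_MODEL.noise_sd,
            ).delta_u
            for s in range(N_SEEDS)
        ]
        for shift in SHIFT_MEMBRANES
    }
    return {
        "control_curves": control_curves,
        "treated_curves": curves,
        "estimates": estimates,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
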