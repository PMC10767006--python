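"""Shared fixtures: small synthetic inputs with known ground truth."""

import numpy as np
import pytest

from arterymech import mechanics as mech
from arterymech import simulate as sim


@pytest.fixture(scope="session")
def ctl_params():
    return sim.preset("CTL-like")


@pytest.fixture(scope="session")
def ht_params():
    return sim.preset("HT-like")


@pytest.fixture(scope="session")
def zero_noise_protocol():
    return sim.SimulationProtocol(diameter_noise_sd_um=0.0, force_noise_sd_mn=0.0)


@pytest.fixture(scope="session")
def simple_geometry():
    return mech.UnloadedGeometry(1.0, 0.8)


@pytest.fixture(scope="session")
def preset_recovery_runs(zero_noise_protocol):
    """In vivo stretch + tangent modulus recovery over 20 seeded presets.

    Computed once per session; consumed by the stretch-recovery and
    modulus-recovery acceptance checks.
    """
    runs = []
    for seed in range(20):
        name = "CTL-like" if seed % 2 == 0 else "HT-like"
        params = sim.perturbed_preset(name, seed)
        lz_true = sim.find_force_invariant_stretch(params)
        dataset = sim.simulate_dataset(params, zero_noise_protocol)
        est = mech.estimate_in_vivo_stretch(dataset)
        rec = min(dataset.records, key=lambda r: abs(r.axial_stretch - est.value))
        curve = mech.process_record(rec, params.geometry)
        modulus = mech.tangent_modulus(curve, 100.0)
        state = mech.state_at_pressure(curve, 100.0)
        analytic = (
            sim.circ_stress_derivative(params, state.circ_stretch, rec.axial_stretch)
            / 1000.0
        )
        runs.append(
            dict(
                seed=seed,
                preset=name,
                lz_true=lz_true,
                estimate=est,
                modulus_mpa=modulus,
                modulus_analytic_mpa=analytic,
            )
        )
    return runs
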