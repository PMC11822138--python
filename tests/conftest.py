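"""Shared fixtures: calibrated effort and leaks (session-scoped, expensive)."""

from __future__ import annotations

import pytest

import nivbench.ps_controller as psc
import nivbench.virtual_bench as vb


@pytest.fixture(scope="session")
def effort() -> vb.EffortProfile:
    """Effort calibrated to the bench occlusion targets (P0.1, Poccl)."""
    return vb.calibrate_effort()


@pytest.fixture(scope="session")
def leak_specs(effort) -> dict:
    """Calibrated leak orifices shared across the suite."""
    return {
        "inspiro-expiratory": {
            "L9": vb.calibrate_leak("L9", effort=effort),
            "L20": vb.calibrate_leak("L20", effort=effort),
        },
        "inspiratory-only": {
            "L20": vb.calibrate_leak("L20", kind="inspiratory-only", effort=effort),
        },
    }


@pytest.fixture(scope="session")
def normal_settings() -> psc.VentSettings:
    return psc.settings_for("normal", 8.0)


@pytest.fixture(scope="session")
def quiet_l0_record(effort, normal_settings) -> vb.WaveformRecord:
    """30 s of steady no-leak closed loop, normal mechanics, sync off."""
    mech = vb.MECHANICS_PRESETS["normal"]
    return vb.simulate_condition(
        mech, effort, normal_settings, vb.LeakSpec.no_leak(), "IS0", duration=30.0
    )
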