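"""Shared fixtures: presets, fitted-density models and reusable simulations."""

from __future__ import annotations

import time

import numpy as np
import pytest

from nucpatch import PatchModel, simulate_ap_train, species_preset
from nucpatch.fitting import fit_gmax_powell
from nucpatch.synth import synth_ap_command


@pytest.fixture(scope="session")
def presets():
    return {name: species_preset(name) for name in
            ("human_na", "mouse_na", "human_k", "mouse_k")}


def species_model(species: str, gmax_na: float, gmax_k: float, **kw) -> PatchModel:
    na = species_preset(f"{species}_na").with_gmax(gmax_na)
    k = species_preset(f"{species}_k").with_gmax(gmax_k)
    return PatchModel(na_channels=(na,), k_channels=(k,), **kw)


@pytest.fixture(scope="session")
def density_fits():
    """Powell density fits for the all-human and all-mouse models, with the
    wall-clock time each fit took."""
    out = {}
    for sp, hf in (("human", 1.0), ("mouse", 0.0)):
        t0 = time.perf_counter()
        fit = fit_gmax_powell(hf, hf)
        out[sp] = {"fit": fit, "elapsed_s": time.perf_counter() - t0}
    return out


@pytest.fixture(scope="session")
def fitted_models(density_fits):
    """Single-species spiking models at their own fitted densities."""
    return {
        sp: species_model(
            sp, density_fits[sp]["fit"].gmax_na, density_fits[sp]["fit"].gmax_k
        )
        for sp in ("human", "mouse")
    }


@pytest.fixture(scope="session")
def species_trains(fitted_models):
    """70-Hz, 200-AP evoked trains for both species at fitted densities."""
    return {
        sp: simulate_ap_train(m, freq=70.0, n_aps=200)
        for sp, m in fitted_models.items()
    }


@pytest.fixture(scope="session")
def ap_command():
    """Human-like AP-train command waveform with annotated peaks (10 APs)."""
    return synth_ap_command("human", freq=40.0, n_aps=10, dt=0.02)
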