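"""Shared fixtures: small synthetic sessions and their preprocessed products.

All fixtures are deterministic (fixed seeds) and sized for speed; the
acceptance tests build their own sessions at the sizes they need.
"""

from __future__ import annotations

import numpy as np
import pytest

from phasebehav.synthgen import AreaSpec, SimConfig, simulate_session
from phasebehav.preprocess import (bipolar_derive, clean_and_select_trials,
                                   condition_signal, extract_epochs)
from phasebehav.spectral import fft_epochs

REDUCED_AREAS = (
    AreaSpec("V1", "occipital"),
    AreaSpec("V4", "occipital"),
    AreaSpec("F1", "frontocentral"),
    AreaSpec("F4", "frontocentral"),
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_trials_per_condition=60, areas=REDUCED_AREAS, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def small_clean(small_session):
    """Preprocessed small session: bipolar, line-cleaned, trial-selected,
    normalized, with 200 ms epochs and their spectral frame."""
    rec, gt = small_session
    bp = bipolar_derive(rec)
    lined = condition_signal(bp, steps=("line",))
    mask = clean_and_select_trials(lined)
    clean = condition_signal(lined, keep=mask.keep,
                             steps=("detrend", "normalize"))
    epochs = extract_epochs(clean, "power-ppc-gpr", mask.keep)
    frame = fft_epochs(epochs)
    return {"raw": rec, "gt": gt, "mask": mask, "clean": clean,
            "epochs": epochs, "frame": frame,
            "rt": clean.rt[mask.keep],
            "condition": clean.condition[mask.keep]}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
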