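"""Shared fixtures.

The expensive artifacts (multi-start fits, the acceptance-scale Monte
Carlo cylinder run) are session-scoped so the acceptance tests and the
module tests reuse a single computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import sandix as sx
import sandix.montecarlo as mc


@pytest.fixture(scope="session")
def protocol():
    return sx.exvivo_protocol()


@pytest.fixture(scope="session")
def esandix_truth():
    """Ground truth inside the reported cortical parameter ranges."""
    return sx.GmModelParams(model_id="eSANDIX", fe=0.40, fn=0.38,
                            fn_imp=0.05, fs=0.16, fim=0.01, De=0.85,
                            Dn=0.5, tau_n=4.0, Rs=12.5)


@pytest.fixture(scope="session")
def noiseless_esandix_table(protocol, esandix_truth):
    return sx.model_signal(protocol, esandix_truth)


@pytest.fixture(scope="session")
def noiseless_esandix_fit(noiseless_esandix_table):
    return sx.fit_model(noiseless_esandix_table, "eSANDIX", n_starts=50,
                        seed=3)


@pytest.fixture(scope="session")
def noisy_dataset(protocol, esandix_truth):
    """1% Rician noise at measurement scale (10/30 averages, 30 directions)."""
    spec = sx.SyntheticSpec(params=esandix_truth, protocol=protocol,
                            sigma=0.01, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = sx.generate_dataset(spec)
    return table, truth


@pytest.fixture(scope="session")
def noisy_esandix_fit(noisy_dataset):
    return sx.fit_model(noisy_dataset[0], "eSANDIX", n_starts=50, seed=3)


@pytest.fixture(scope="session")
def noisy_sandix_fit(noisy_dataset):
    return sx.fit_model(noisy_dataset[0], "SANDIX", n_starts=50, seed=4)


@pytest.fixture(scope="session")
def cylinder_run():
    """Thin finite cylinder at the acquisition timings (stick analogue)."""
    geom = mc.cylinder(0.5, 200.0)
    cfg = mc.McConfig(n_particles=10000, step_sigma=0.05, duration=20.5,
                      seed=5)
    return mc.simulate(geom, cfg, [(16.0, 4.5)])


@pytest.fixture(scope="session")
def ball_sticks_run():
    geom = mc.ball_and_sticks(8.0, n_sticks=10, R_stick=0.5, L_stick=150.0,
                              seed=7)
    cfg = mc.McConfig(n_particles=2000, step_sigma=0.05, duration=20.5,
                      seed=6)
    return mc.simulate(geom, cfg, [(16.0, 4.5)])
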