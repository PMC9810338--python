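"""Shared fixtures: small simulated datasets reused across test modules.

All simulations here are scaled down (shorter traces, fewer replicates)
relative to a full analysis run; the statistical tolerances asserted in
the tests account for the correspondingly larger Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np
import pytest

from confcs.acf import apply_blinking_factor, average_acfs, compute_acf
from confcs.geometry import CellGeometry
from confcs.simulate import MotionModel, SimulationConfig, simulate_trace

BD_DIAMETER = 0.85
BD_DIFFUSION = 10.0
BD_DT = 1e-5
BD_DURATION = 8.0
BD_N_TRACES = 3


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # execution order, keeping individual test outcomes reproducible
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def bd_traces():
    """Confined-Brownian traces at the reference condition
    (L=5 µm, d=0.85 µm, D=10 µm²/s, N=50)."""
    traces = []
    for seed in range(BD_N_TRACES):
        config = SimulationConfig(
            n_particles=50,
            dt=BD_DT,
            duration=BD_DURATION,
            geometry=CellGeometry(L=5.0, d=BD_DIAMETER),
            motion=MotionModel.brownian(BD_DIFFUSION),
            seed=1000 + seed,
        )
        traces.append(simulate_trace(config))
    return traces


@pytest.fixture(scope="session")
def bd_acfs(bd_traces):
    """Blink-multiplied ACFs of the reference traces."""
    return [apply_blinking_factor(compute_acf(t)) for t in bd_traces]


@pytest.fixture(scope="session")
def bd_acf_mean(bd_acfs):
    """Replicate-averaged reference ACF (with per-lag SEM)."""
    return average_acfs(bd_acfs)


@pytest.fixture(scope="session")
def bd_ansatz_occupancy():
    """Ansatz model amplitude for the reference condition, from the PSF
    moments over the cell: G(0) = (m2 - m1^2)/(N_p m1^2), N = 1/G(0)."""
    from confcs.geometry import ConfocalVolume, psf_intensity
    from confcs.simulate import sample_uniform_positions

    rng = np.random.default_rng(99)
    geom = CellGeometry(L=5.0, d=BD_DIAMETER)
    conf = ConfocalVolume(center=(-1.5, 0.0, 0.0))
    intensity = psf_intensity(sample_uniform_positions(500_000, geom, rng), conf)
    m1, m2 = intensity.mean(), (intensity**2).mean()
    return 50 * m1**2 / (m2 - m1**2)
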