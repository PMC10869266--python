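"""Shared fixtures: analytic Gaussian traces with known areas."""

from __future__ import annotations

import numpy as np
import pytest

from runoffkit.trace_io import ProfileTrace


def gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian density."""
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def make_gaussian_trace(
    components,
    start=0.0,
    end=60.0,
    step=0.2,
    baseline=0.0,
    ramp=0.0,
    noise_sd=0.0,
    rng=None,
    **fields,
):
    """Trace that is a sum of (mu, sigma, area) Gaussians on a known baseline.

    The analytic area of each component is its ``area`` parameter, which
    makes the trace an oracle for integration and P/M tests.
    """
    x = np.arange(start, end + step / 2, step)
    y = np.full_like(x, baseline) + ramp * (x - start)
    for mu, sigma, area in components:
        y += area * gaussian(x, mu, sigma)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0, noise_sd, x.size)
    fields.setdefault("baseline_corrected",
                      baseline == 0 and ramp == 0 and noise_sd == 0)
    if fields["baseline_corrected"]:
        y = np.maximum(y, 0.0)
    return ProfileTrace(positions=x, absorbance=y, **fields)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_trace():
    """Baseline-corrected trace with an 80S peak and two polysome peaks."""
    return make_gaussian_trace(
        [(23.0, 1.2, 1.0), (34.0, 1.3, 1.5), (38.0, 1.4, 1.0)],
        sample_id="s1",
    )
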