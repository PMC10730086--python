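import numpy as np
import pytest

import apexprof as ap


def make_stack_params(**overrides) -> ap.StackParams:
    """Small, fast, noise-free stack parameters for unit tests."""
    base = dict(
        nx=41, ny=41, nz=120, dx=1.0, dy=1.0, dz=0.4,
        cx=0.03, cy=0.03, apex_iz=6, d0=20.0, sigma_ax=6.0, sigma_lat=8.0,
        amplitude=1000.0, background=5.0,
        poisson_noise=False, gaussian_sd=0.0, seed=0,
    )
    base.update(overrides)
    return ap.StackParams(**base)


def run_imaging_chain(params: ap.StackParams, cutoff_um: float = 25.0,
                      halfwidth_um: float = 15.0):
    """Full apex -> paraboloid -> mask -> profile -> metrics chain."""
    stack, truth = ap.generate_stack(params)
    structural = stack.get_channel(0)
    reporter = stack.get_channel(1)
    apex = ap.detect_apex(structural)
    model = ap.fit_paraboloid(structural, apex, halfwidth_um=halfwidth_um,
                              cutoff_radius_um=cutoff_um)
    mask = ap.build_mask(model, structural)
    raw = ap.extract_profile(reporter, mask, apex)
    smoothed = ap.smooth_profile(raw)
    metrics = ap.quantify_profile(smoothed)
    return metrics, truth


def gaussian_profile(d0: float, sigma: float, dz: float = 0.4,
                     depth_max: float | None = None,
                     amplitude: float = 1000.0) -> ap.DepthProfile:
    """Analytic Gaussian depth profile sampled on a regular grid."""
    if depth_max is None:
        depth_max = d0 + 4.0 * sigma
    depths = np.arange(0.0, depth_max + dz / 2, dz)
    intensity = amplitude * np.exp(-((depths - d0) ** 2) / (2 * sigma ** 2))
    return ap.DepthProfile(depths, intensity, state="smoothed")


@pytest.fixture
def stack_params():
    return make_stack_params


@pytest.fixture
def imaging_chain():
    return run_imaging_chain
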