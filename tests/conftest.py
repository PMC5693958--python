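"""Shared fixtures: small systems for unit tests and the two full
default-condition systems (analytic alpha, desk-scale beta Monte Carlo) that
the acceptance tests reuse across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpet.alpha import AlphaSourceSpec, RangeEnergyModel, alpha_prf_grid
from cpet.geometry import DepthGrid, SlabGeometry, alpha_slab
from cpet.kernel import build_depth_kernel, eigendecompose_kernel, radial_frequency_samples
from cpet.listmode import AttributeSpec, BinSpec
from cpet.pipeline import ExperimentConfig, _beta_listmode, _beta_prf, _finish

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def alpha_model():
    return RangeEnergyModel()


@pytest.fixture(scope="session")
def small_alpha_system(alpha_model):
    """Coarse, fast alpha system: 8 depths, 4-um lateral bins over 96 um.

    Used by the unit tests that exercise operator identities; the full
    default-resolution system lives in ``alpha_assets``.
    """
    slab = SlabGeometry(40.0, (96.0, 96.0))
    grid = DepthGrid(np.arange(2.5, 40.0, 5.0), 40.0, 5.0)
    bins = BinSpec(
        lateral_width_um=4.0, lateral_half_extent_um=48.0, energy_max_kev=5160.0,
        theta_width_deg=6.0, phi_width_deg=6.0, energy_width_kev=260.0,
    )
    attrs = AttributeSpec.position_energy()
    prf = alpha_prf_grid(grid.depths_um, attrs, bins, alpha_model, AlphaSourceSpec())
    freqs = radial_frequency_samples(np.sqrt(2.0) * bins.lateral_nyquist, 33)
    kernel = build_depth_kernel(prf, grid, freqs)
    es = eigendecompose_kernel(kernel, grid)
    return {"slab": slab, "grid": grid, "bins": bins, "attrs": attrs,
            "prf": prf, "kernel": kernel, "es": es, "model": alpha_model}


@pytest.fixture(scope="session")
def alpha_assets():
    """Default-condition alpha systems for all four detector configurations.

    The exact q = 5 PRF (20 depths, 2-um lateral bins) is built once and
    marginalized; each q gets its own kernel, eigensystem and phantom
    decomposition.
    """
    base = ExperimentConfig(modality="alpha", q=5)
    prf5 = alpha_prf_grid(
        base.depth_grid().depths_um, AttributeSpec.all_five(), base.bins(),
        RangeEnergyModel(), AlphaSourceSpec(), phi_subdivisions=base.phi_subdivisions,
    )
    results = {}
    prfs = {}
    for q in (2, 3, 4, 5):
        cfg = ExperimentConfig(modality="alpha", q=q)
        prfs[q] = prf5.marginalize(AttributeSpec.from_q(q))
        results[q] = _finish(cfg, prfs[q])
    return {"prf5": prf5, "prfs": prfs, "results": results}


@pytest.fixture(scope="session")
def beta_assets():
    """Desk-scale beta Monte Carlo systems: 1e5 particles per depth.

    One simulation serves all four detector configurations, re-histogrammed
    per attribute combination exactly as one instrument's list-mode data
    would be re-analyzed.
    """
    n = 100_000
    base = ExperimentConfig(modality="beta", q=5, n_particles_per_depth=n, seed=1)
    tables = _beta_listmode(base)
    prf5 = _beta_prf(base, AttributeSpec.all_five(), tables)
    del tables
    results = {}
    prfs = {}
    for q in (2, 3, 4, 5):
        cfg = ExperimentConfig(modality="beta", q=q, n_particles_per_depth=n, seed=1)
        prfs[q] = prf5.marginalize(AttributeSpec.from_q(q))
        results[q] = _finish(cfg, prfs[q])
    return {"prf5": prf5, "prfs": prfs, "results": results}
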