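"""Shared fixtures.

Expensive tissue simulations are session-scoped so the suite pays for each
at most once; everything stochastic is explicitly seeded.
"""

import numpy as np
import pytest

from rotorsim.cell_models import make_variant
from rotorsim.induction import crossfield_stimuli
from rotorsim.monodomain import default_conductivity, run_monodomain
from rotorsim.substrate import (generate_fibrotic_sheet,
                                make_block_patch_sheet,
                                make_calibration_slab, partition_regions)


@pytest.fixture(scope="session")
def reduced_params():
    return make_variant("reduced_test")


@pytest.fixture(scope="session")
def chronic_af_params():
    return make_variant("chronic_af")


@pytest.fixture(scope="session")
def spiral_sheet():
    """5 cm isotropic reduced-model sheet (100x100) with 7 regions."""
    grid = make_calibration_slab(5.0, 500.0)
    return partition_regions(grid, 7)


@pytest.fixture(scope="session")
def spiral_episode(spiral_sheet, reduced_params):
    """A sustained single-spiral episode induced by cross-field S1-S2."""
    cond = default_conductivity(spiral_sheet, sigma_l=0.3, ratio=1.0)
    stimuli = crossfield_stimuli(spiral_sheet, s2_time_ms=180.0)
    return run_monodomain(spiral_sheet, cond, reduced_params, stimuli,
                          duration_ms=2000.0)


@pytest.fixture(scope="session")
def engineered_induction(reduced_params):
    """Induction results on the engineered block-patch sheet from two
    pacing sites flanking the patch; at least one sustains."""
    from rotorsim.cell_models import make_variant
    from rotorsim.induction import (SCALED_COUPLING_INTERVALS,
                                    PacingProtocol, run_induction)
    from rotorsim.monodomain import apply_fibrotic_conductivity
    grid = make_block_patch_sheet()
    cond = apply_fibrotic_conductivity(
        default_conductivity(grid, sigma_l=0.3, ratio=1.0), grid, 0.8, 0.5)
    fp = make_variant("reduced_test_fibrotic")
    results = []
    for site in ((1.0, 2.5), (1.2, 1.2)):
        proto = PacingProtocol(site=site,
                               coupling_intervals=SCALED_COUPLING_INTERVALS,
                               post_pacing_ms=1000.0)
        results.append(run_induction(grid, cond, reduced_params, proto,
                                     fibrotic_params=fp))
    return grid, results


@pytest.fixture(scope="session")
def engineered_reentry(engineered_induction):
    _, results = engineered_induction
    return [r.outcome for r in results]


@pytest.fixture(scope="session")
def engineered_sustained_episode(engineered_induction):
    _, results = engineered_induction
    for r in results:
        if r.outcome == "sustained":
            return r.episode
    raise AssertionError("no sustained episode on the engineered sheet")


@pytest.fixture(scope="session")
def calibration_slab():
    return make_calibration_slab()


@pytest.fixture(scope="session")
def fibrotic_cv(slab_episode, calibration_slab):
    """(fibrotic CV, non-fibrotic CV): plane-wave speed through the default
    29.1% sheet with full fibrotic remodeling vs. the uniform slab."""
    from rotorsim.monodomain import (apply_fibrotic_conductivity,
                                     line_stimulus, measure_cv)
    grid = generate_fibrotic_sheet(seed=2024)
    partition_regions(grid, 7)
    cond = apply_fibrotic_conductivity(default_conductivity(grid), grid)
    rec = run_monodomain(grid, cond, make_variant("chronic_af"),
                         [line_stimulus(grid, "left")], duration_ms=220.0,
                         fibrotic_params=make_variant("chronic_af_fibrotic"))
    cv_fib = measure_cv(rec, grid, (1.0, 0.0), min_r2=0.5)
    cv_ref = measure_cv(slab_episode, calibration_slab, (1.0, 0.0))
    return cv_fib, cv_ref


@pytest.fixture(scope="session")
def slab_episode(calibration_slab, chronic_af_params):
    """Plane wave on the calibration slab with default calibrated
    conductivities and the chronic-AF detailed model."""
    from rotorsim.monodomain import line_stimulus
    cond = default_conductivity(calibration_slab)
    return run_monodomain(calibration_slab, cond, chronic_af_params,
                          [line_stimulus(calibration_slab, "left")],
                          duration_ms=150.0)
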