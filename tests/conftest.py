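"""Shared fixtures: small phantoms and (expensive) fitted sessions.

The kinetic fits are session-scoped because they take tens of seconds each;
every test that needs a fitted PASL or pCASL session shares these.
"""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import aslcalib as asl
from aslcalib.m0t import pve_weighted_t1

GRID = (18, 18, 5)


@pytest.fixture(scope="session")
def pasl_spec():
    return asl.PhantomSpec(grid_shape=GRID)


@pytest.fixture(scope="session")
def pasl_phantom(pasl_spec):
    return asl.make_phantom(pasl_spec)


@pytest.fixture(scope="session")
def crisp_phantom():
    """No PVE blur: binary tissue maps, exact per-tissue constants."""
    return asl.make_phantom(asl.PhantomSpec(grid_shape=GRID,
                                            pve_blur_fwhm_mm=0.0))


@pytest.fixture(scope="session")
def pasl_acq():
    return asl.AcquisitionParams.pasl_default(n_repeats=2)


@pytest.fixture(scope="session")
def pasl_acq_noslicetime(pasl_acq):
    return replace(pasl_acq, slice_time_ms=0.0)


@pytest.fixture(scope="session")
def pasl_ds(pasl_phantom, pasl_acq):
    tissue, truth = pasl_phantom
    return asl.simulate_asl_series(truth, tissue, pasl_acq, noise_sd=0.0,
                                   seed=11)


@pytest.fixture(scope="session")
def pasl_perf(pasl_phantom, pasl_ds):
    tissue, _ = pasl_phantom
    return asl.fit_volume(pasl_ds, pve_weighted_t1(tissue),
                          mask=tissue.brain_mask)


@pytest.fixture(scope="session")
def satrec_m0t(pasl_phantom, pasl_ds):
    tissue, _ = pasl_phantom
    return asl.m0t_satrec(pasl_ds, tissue)


@pytest.fixture(scope="session")
def default_opts(pasl_acq):
    return asl.CalibOptions(te_ms=pasl_acq.te_ms, alpha=pasl_acq.alpha)


@pytest.fixture(scope="session")
def pasl0_bundle(pasl_phantom, pasl_acq_noslicetime):
    """Noiseless PASL session acquired with zero slice-timing offset
    (makes the control-averaging corrections exactly analytic)."""
    tissue, truth = pasl_phantom
    ds = asl.simulate_asl_series(truth, tissue, pasl_acq_noslicetime,
                                 noise_sd=0.0, seed=11)
    perf = asl.fit_volume(ds, pve_weighted_t1(tissue),
                          mask=tissue.brain_mask)
    return tissue, truth, ds, perf


@pytest.fixture(scope="session")
def biased_bundle(pasl_spec, pasl_acq):
    """Same phantom with a 1.3 peak-to-trough coil bias field applied."""
    spec = replace(pasl_spec, bias_peak_to_trough=1.3)
    tissue, truth = asl.make_phantom(spec)
    ds = asl.simulate_asl_series(truth, tissue, pasl_acq, noise_sd=0.0,
                                 seed=11)
    perf = asl.fit_volume(ds, pve_weighted_t1(tissue),
                          mask=tissue.brain_mask)
    m0t_map, _ = asl.m0t_satrec(ds, tissue)
    return tissue, truth, ds, perf, m0t_map


@pytest.fixture(scope="session")
def pcasl_bundle():
    spec = asl.PhantomSpec(grid_shape=GRID, te_ms=13.0)
    tissue, truth = asl.make_phantom(spec)
    acq = asl.AcquisitionParams.pcasl_default(n_repeats=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ds = asl.simulate_asl_series(truth, tissue, acq, noise_sd=0.0,
                                     seed=11)
    calib = asl.simulate_calibration_scan(truth, acq)
    perf = asl.fit_volume(ds, pve_weighted_t1(tissue),
                          mask=tissue.brain_mask)
    return tissue, truth, ds, calib, perf
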