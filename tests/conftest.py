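import numpy as np
import pytest

from qmi.phantom import (LesionSpec, PhantomSpec, build_phantom,
                         default_cohort_spec, make_compartments, GM)
from qmi.pipeline import PipelineConfig, run_pipeline


def monoexp_series(rate_s, echo_times_ms, s0=1.0, shape=(1, 1, 1)):
    """Noiseless mono-exponential EchoSeries at a single rate."""
    from qmi.relaxometry import EchoSeries
    te = np.asarray(echo_times_ms, dtype=float)
    sig = s0 * np.exp(-rate_s * te / 1000.0)
    mag = np.broadcast_to(sig, shape + (te.size,)).copy()
    return EchoSeries(mag, np.zeros_like(mag), te)


@pytest.fixture(scope="session")
def protocol_echo_times():
    """The 6-echo GRE protocol: TE = 4.92 ... 29.52 ms."""
    return 4.92 * np.arange(1, 7)


@pytest.fixture(scope="session")
def small_grid():
    """A small phantom grid with the default anisotropic voxel."""
    return dict(grid_shape=(48, 48, 12), voxel_size_mm=(0.8, 0.8, 2.0))


@pytest.fixture(scope="session")
def cortex_center(small_grid):
    """A voxel index deep inside the cortical shell of the small grid."""
    from qmi.phantom import cortical_depth_mm
    comp = make_compartments(**small_grid)
    edt = cortical_depth_mm(comp == GM, small_grid["voxel_size_mm"])
    return tuple(int(c) for c in np.argwhere(edt == edt.max())[0])


@pytest.fixture(scope="session")
def noiseless_one_lesion(small_grid, cortex_center):
    """Noiseless small study with a single 3 mm lesion, onset visit 2."""
    spec = PhantomSpec(n_visits=5, noise_sd=0.0, param_noise_frac=0.0,
                       lesion_specs=[LesionSpec(center=cortex_center,
                                                diameter_mm=3.0,
                                                onset_visit=2)],
                       seed=11, **small_grid)
    study, truth = build_phantom(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def detect_run():
    """Default-noise 15-lesion cohort analysed end to end with the
    rule-based detector (the default pipeline demo)."""
    cfg = PipelineConfig(seed=1, make_plots=False)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def noiseless_truth_run():
    """Noiseless 15-lesion cohort analysed with truth lesion masks
    (the analogue of manual rater segmentations)."""
    cfg = PipelineConfig(seed=7, lesion_source="truth", noise_sd=0.0,
                         param_noise_frac=0.0, make_plots=False)
    spec = default_cohort_spec(n_lesions=15, seed=7)
    result = run_pipeline(cfg)
    return spec, result
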