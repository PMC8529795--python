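import numpy as np
import pytest

import t1rho_moco as tm

TSL_DEFAULT = [0.0, 10.0, 20.0, 35.0, 50.0]


@pytest.fixture()
def uniform_map():
    """16x16 uniform parameter map (T1rho 48.8 ms, M0 800)."""
    return tm.ParameterMap(np.full((16, 16), 48.8), np.full((16, 16), 800.0))


@pytest.fixture()
def uniform_series(uniform_map):
    return tm.synthesize_series(uniform_map, TSL_DEFAULT)


@pytest.fixture(scope="session")
def small_spec():
    return tm.PhantomSpec(shape=(96, 96), r_endo=15.0, r_epi=22.0,
                          seed=3, noise_sigma=0.01)


@pytest.fixture(scope="session")
def static_phantom(small_spec):
    traj = tm.Trajectory(kind="sinusoid", amplitude=0.0,
                         sample_times=tm.default_sample_times())
    return tm.generate_series(small_spec, TSL_DEFAULT, traj)


@pytest.fixture(scope="session")
def static_phantom_noise_free():
    spec = tm.PhantomSpec(shape=(96, 96), r_endo=15.0, r_epi=22.0,
                          seed=3, noise_sigma=0.0)
    traj = tm.Trajectory(kind="sinusoid", amplitude=0.0,
                         sample_times=tm.default_sample_times())
    return tm.generate_series(spec, TSL_DEFAULT, traj)


@pytest.fixture(scope="session")
def moving_phantom(small_spec):
    traj = tm.Trajectory(
        kind="per_image_offsets", amplitude=0.0,
        offsets_mm=np.array(
            [[0, 0], [4, 1], [-3, 0], [2, -2], [-5, 1]], dtype=float
        ),
        sample_times=tm.default_sample_times(),
    )
    return tm.generate_series(small_spec, TSL_DEFAULT, traj)


def light_moco_config(**kw):
    """Reduced-effort configuration for fast moco tests."""
    kw.setdefault("outer_iter", 3)
    kw.setdefault("reg", tm.RegConfig(levels=3, inner_iter=40, n_warps=5))
    return tm.MocoConfig(**kw)


@pytest.fixture(scope="session")
def moving_moco_result(moving_phantom):
    return tm.run_moco(moving_phantom["series"], light_moco_config())
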