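import numpy as np
import pytest

from hpcardiac.kinetics import FlipSchedule, RelaxationTimes
from hpcardiac.phantom import (AcquisitionProtocol, AIFModel, PhantomGeometry,
                               TissueKineticsSpec, build_geometry,
                               make_coil_array, render_dynamic_study)


@pytest.fixture(scope="session")
def relax() -> RelaxationTimes:
    return RelaxationTimes()


@pytest.fixture(scope="session")
def flips30() -> FlipSchedule:
    """The cardiac protocol's frame schedule: 30 frames every 3.6 s."""
    return FlipSchedule(times=3.6 * np.arange(30))


@pytest.fixture(scope="session")
def small_geometry() -> PhantomGeometry:
    """Desk-scale geometry: 3 slices covering all AHA levels on a 32x32 grid."""
    return build_geometry(shape=(3, 32, 32), lv_radius=4.0,
                          myo_outer_radius=7.5, rv_radius=3.0,
                          slice_levels=("basal", "mid", "apical"))


@pytest.fixture(scope="session")
def small_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(n_slices=3)


@pytest.fixture(scope="session")
def small_study(small_geometry, small_protocol):
    """One rendered fasted-state study at desk scale (seeded)."""
    coils = make_coil_array(small_geometry.shape, seed=11)
    return render_dynamic_study(small_geometry, TissueKineticsSpec(),
                                AIFModel(), coils, small_protocol)


@pytest.fixture(scope="session")
def noiseless_study(small_geometry, small_protocol):
    coils = make_coil_array(small_geometry.shape, seed=11)
    proto = AcquisitionProtocol(n_slices=3, noise_sigma=1e-12, seed=1)
    return render_dynamic_study(small_geometry, TissueKineticsSpec(),
                                AIFModel(), coils, proto)
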