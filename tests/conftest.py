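import numpy as np
import pytest

from scatterprint.curves import ScatteringCurve
from scatterprint.synth import EmulsionModel, PorodSphere, generate_emulsion_curve


@pytest.fixture(scope="session")
def droplet_model() -> EmulsionModel:
    """Noise-free polydisperse oil-droplet model on the USAXS range."""
    return EmulsionModel(
        spheres=[PorodSphere(mean_radius_um=0.5, polydispersity=0.2,
                             volume_fraction=0.01)],
        q_range=(0.0003, 0.005),
        n_points=200,
    )


@pytest.fixture(scope="session")
def droplet_curve(droplet_model) -> ScatteringCurve:
    return generate_emulsion_curve(droplet_model, sample_id="droplets")


def power_law_curve(amplitude=1e-9, exponent=4.0, qlo=1e-4, qhi=5e-3, n=120,
                    **kwargs) -> ScatteringCurve:
    q = np.geomspace(qlo, qhi, n)
    return ScatteringCurve(q=q, intensity=amplitude * q ** (-exponent), **kwargs)
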