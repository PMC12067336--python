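import numpy as np
import pytest

import n2ibone as nb


@pytest.fixture(scope="session")
def default_phantom():
    """The packaged default bone phantom (64×192×192, 150 lacunae)."""
    return nb.generate_phantom(nb.default_bone_spec())


@pytest.fixture(scope="session")
def small_spec():
    return nb.PhantomSpec(
        grid_shape=(16, 72, 72),
        n_lacunae=10,
        volume_range_um3=(150.0, 700.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return nb.generate_phantom(small_spec)


@pytest.fixture()
def disk_image():
    """Uniform disk of known attenuation on a 101×101 grid (µ = 0.3 mm⁻¹)."""
    n, r, mu = 101, 30, 0.3
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2
    img = np.where((yy - c) ** 2 + (xx - c) ** 2 <= r**2, mu, 0.0)
    return img, r, mu


def make_sinogram(n_angles: int, n_det: int = 16, **kw) -> nb.Sinogram:
    """A structurally valid sinogram with deterministic dummy data."""
    rng = np.random.default_rng(kw.pop("seed", 0))
    return nb.Sinogram(
        data=rng.uniform(0.0, 1.0, (n_angles, n_det)),
        angles=nb.forward_model.uniform_angles(n_angles),
        **kw,
    )
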