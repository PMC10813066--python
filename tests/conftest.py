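import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cementum import synthetic, thickness
from cementum.records import included, load_fixture

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_records():
    return load_fixture()


@pytest.fixture(scope="session")
def study_sample(fixture_records):
    """The 33 included single-rooted teeth."""
    return included(fixture_records)


@pytest.fixture(scope="session")
def uniform_root():
    """Uniform 500 µm cementum, no gradient, no texture: exact analytic truth."""
    spec = synthetic.SyntheticSpec(
        base_cementum_um=500.0, texture=(0.0, 500.0, 0.0), seed=11,
        n_theta=56, n_axial=70,
    )
    dentine, cementum, truth = synthetic.make_root_pair(spec)
    return spec, dentine, cementum, truth


@pytest.fixture(scope="session")
def gradient_root():
    """Apico-lingual gradient (700 µm) over a 500 µm base with mild texture."""
    spec = synthetic.SyntheticSpec(
        base_cementum_um=500.0, angular_gradient=(">", 700.0, 1),
        texture=(100.0, 500.0, 0.0), seed=12, n_theta=56, n_axial=70,
    )
    dentine, cementum, truth = synthetic.make_root_pair(spec)
    return spec, dentine, cementum, truth


@pytest.fixture(scope="session")
def gradient_analysis(gradient_root):
    _, dentine, cementum, truth = gradient_root
    field = thickness.compute_thickness(cementum, dentine)
    partition = thickness.partition_root(cementum)
    return field, partition, cementum, truth


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres 5.0 / 5.5 mm as RootMesh wrappers (500 µm offset)."""
    import trimesh

    inner = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    outer = trimesh.creation.icosphere(subdivisions=4, radius=5.5)

    def wrap(m):
        return synthetic.RootMesh(
            vertices=m.vertices.view(np.ndarray).copy(),
            triangles=m.faces.view(np.ndarray).copy(),
            apex_point=np.array([0.0, 0.0, -5.0]),
            cej_ring_height=10.0,
            axis=np.array([0.0, 0.0, 1.0]),
            buccal_reference=np.array([1.0, 0.0, 0.0]),
        )

    return wrap(inner), wrap(outer)
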