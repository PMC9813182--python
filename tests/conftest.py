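import numpy as np
import pytest

import shapepose as sp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_clean_dataset(
    n_poses=80,
    d=3,
    n_ep=3,
    sigma_n=0.01,
    seed=0,
    shape_name="poly",
    translation_scale=2.0,
):
    """Small clean simulated dataset plus its truth bundle."""
    shape = sp.make_shape(shape_name, d=d)
    rng = np.random.default_rng(seed)
    eig = sp.make_eigenposes(shape.shape[0], d, n_ep, rng=rng, mean_shape=shape)
    spec = sp.ContaminationSpec(sigma_n=sigma_n, p_op=0.0, p_mp=0.0, seed=seed)
    return sp.simulate_dataset(
        shape, eig, n_poses, sp.default_b_scales(n_ep), spec,
        translation_scale=translation_scale, rng=rng,
    )


@pytest.fixture
def clean_dataset():
    return make_clean_dataset()


@pytest.fixture
def small_model(rng):
    """Hand-built valid shape model on 5 points in 3D (p=15, r=3)."""
    p, r = 15, 3
    q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    v = q[:, :r]
    return sp.ShapeModel(
        mu=rng.standard_normal(p),
        eigenposes=v,
        eigenvalues=np.array([4.0, 2.0, 1.0]),
        sigma2=0.1,
        d=3,
    )


def random_rigid(rng, d=3, scale=1.0):
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return sp.RigidTransform(q, rng.standard_normal(d) * 2.0, scale)
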