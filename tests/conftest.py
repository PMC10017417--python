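"""Shared fixtures: parametric organ surface samplers and small helpers."""
import numpy as np
import pytest

from podskel.synth import _sample_box_pod, _sample_tube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sample_tube(radius=2.0, length=60.0, n_points=5000, noise=0.0,
                occlusion=0.0, seed=0, axis="z"):
    """Surface points of a straight tube along +axis starting at origin."""
    rng = np.random.default_rng(seed)
    n_nodes = max(int(length // 10), 2) + 1
    poly = np.zeros((n_nodes, 3))
    poly[:, "xyz".index(axis)] = np.linspace(0, length, n_nodes)
    density = n_points / (2 * np.pi * radius * length)
    pts = _sample_tube(rng, poly, radius, density, occlusion)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


def sample_pod(length=60.0, width=3.0, thickness=1.5, density=2.0,
               occlusion=0.0, noise=0.0, seed=0,
               base=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
    """Surface points of a straight box-section pod."""
    rng = np.random.default_rng(seed)
    pts = _sample_box_pod(rng, np.asarray(base, float),
                          np.asarray(direction, float), length, width,
                          thickness, density, occlusion)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


def dist_to_segment(points, a, b):
    """Distances of points to the segment a-b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
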