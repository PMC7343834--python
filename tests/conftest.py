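"""Shared fixtures: one mid-size ground-truthed phantom per session."""

from __future__ import annotations

import numpy as np
import pytest

from cereplaq.phantom import (
    LayerModel,
    PhantomSpec,
    PlaqueModel,
    PurkinjeModel,
    VesselModel,
    generate_phantom,
    ground_truth_seeds,
)

VOXEL_UM = 1.625


def make_spec(seed: int = 11, **overrides) -> PhantomSpec:
    kwargs = dict(
        grid_shape=(144, 144, 144),
        plaque_model=PlaqueModel(count=30),
        purkinje_model=PurkinjeModel(count=12),
        vessel_model=VesselModel(count=6),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def phantom144():
    """(spec, volume, ground_truth) for a 144^3 phantom with all object classes."""
    spec = make_spec()
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture(scope="session")
def phantom144_seeds(phantom144):
    _, _, gt = phantom144
    return ground_truth_seeds(gt)


def digitized_sphere(radius_vox: int) -> np.ndarray:
    """Binary mask of a solid sphere centred on a lattice point."""
    n = 2 * radius_vox + 5
    idx = np.indices((n, n, n)) - n // 2
    return (idx**2).sum(axis=0) <= radius_vox**2


def flood_fill_26(mask: np.ndarray) -> np.ndarray:
    """Reference 26-connected labelling by explicit breadth-first search."""
    out = np.zeros(mask.shape, np.int32)
    nxt = 0
    offsets = [(di, dj, dk)
               for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
               if (di, dj, dk) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if out[start]:
            continue
        nxt += 1
        stack = [start]
        out[start] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                p = (i + di, j + dj, k + dk)
                if all(0 <= p[d] < mask.shape[d] for d in range(3)) \
                        and mask[p] and not out[p]:
                    out[p] = nxt
                    stack.append(p)
    return out


def digitized_ellipsoid(a_vox: float, b_vox: float, axis=None) -> np.ndarray:
    """Binary mask of a prolate ellipsoid (semi-axes a >= b = b), optionally
    with its long axis along a given unit vector."""
    if axis is None:
        axis = np.array([1.0, 0.0, 0.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = int(np.ceil(a_vox)) + 3
    n = 2 * half + 1
    idx = np.indices((n, n, n)) - half
    coords = np.stack(idx, axis=-1).astype(float)
    along = coords @ axis
    perp2 = (coords**2).sum(axis=-1) - along**2
    return along**2 / a_vox**2 + perp2 / b_vox**2 <= 1.0


def thin_layer_overrides() -> dict:
    """Layer/fold settings that leave room for plaques on a 96^3 grid."""
    return dict(
        layer_model=LayerModel(white_thickness_um=30.0, granular_thickness_um=30.0),
        fold_amplitude_um=8.0,
    )
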