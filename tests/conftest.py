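import numpy as np
import pytest

from eulplan import GridGeometry, PhantomSpec, StructureMask


def make_mask(shape, indices, spacing_mm=(10.0, 10.0, 10.0), label="PTV"):
    """Mask with the given (z, y, x) voxel indices occupied."""
    geom = GridGeometry(shape=shape, spacing_mm=spacing_mm)
    vox = np.zeros(shape, dtype=bool)
    for idx in indices:
        vox[tuple(idx)] = True
    return StructureMask(geom, vox, label)


def brute_force_distance_cm(ptv: StructureMask) -> np.ndarray:
    """Exhaustive min-over-source Euclidean centre-to-centre distance, cm."""
    spacing = np.asarray(ptv.geometry.spacing_mm, float)
    src = np.argwhere(ptv.voxels) * spacing  # (M, 3) mm
    all_idx = np.indices(ptv.geometry.shape).reshape(3, -1).T * spacing
    d2 = ((all_idx[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    dist_mm = np.sqrt(d2.min(axis=1)).reshape(ptv.geometry.shape)
    dist_mm[ptv.voxels] = 0.0
    return dist_mm / 10.0


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced pelvic phantom for fast randomized sweeps."""
    return PhantomSpec(
        grid=GridGeometry(shape=(24, 32, 32), spacing_mm=(6.0, 6.0, 6.0)),
        body_semiaxes_cm=(6.0, 8.0, 8.5),
        ptv_semiaxes_cm=(3.0, 2.5, 3.5),
        bladder_semiaxes_cm=(2.5, 1.5, 2.5),
        rectum_semiaxes_cm=(3.0, 1.2, 1.2),
        femoral_head_radius_cm=1.8,
        femoral_head_offset_cm=(1.0, 6.3),
    )
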