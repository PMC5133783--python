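import numpy as np
import pytest

from fociquant3d import foci
from fociquant3d.synthetic import FociPhantomParams, gen_foci_stack

#: suite-wide base seed; all stochastic tests derive from it
BASE_SEED = 20160

NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def flood_fill_label(binary: np.ndarray) -> list[frozenset]:
    """Brute-force 26-connected components as voxel-index sets (oracle)."""
    binary = np.asarray(binary, bool)
    visited = np.zeros_like(binary)
    shape = binary.shape
    components = []
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            z, y, x = stack.pop()
            comp.append((z, y, x))
            for dz, dy, dx in NEIGHBOR_OFFSETS:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and binary[nz, ny, nx]
                    and not visited[nz, ny, nx]
                ):
                    visited[nz, ny, nx] = True
                    stack.append((nz, ny, nx))
        components.append(frozenset(comp))
    return components


def label_partition(labels: np.ndarray) -> set[frozenset]:
    """Label-invariant partition of a labeled grid."""
    out = {}
    for idx in zip(*np.nonzero(labels)):
        out.setdefault(labels[idx], []).append(idx)
    return {frozenset(v) for v in out.values()}


def analyze_phantom(stack):
    """Standard segmentation + two-channel detection + per-cell records."""
    mask = foci.segment_nuclei(stack.data[0])
    gh = foci.detect_foci(
        stack.data[1], mask, foci.MIN_VOXELS_GH2AX, channel_name="gH2AX",
        voxel_size_nm=stack.voxel_size_nm,
    )
    smc = foci.detect_foci(
        stack.data[2], mask, foci.MIN_VOXELS_SMC6, channel_name="SMC6",
        voxel_size_nm=stack.voxel_size_nm,
    )
    return mask, gh, smc, foci.per_cell_records(mask, gh, smc)


def match_truth(mask, ground_truth, voxel_size_nm):
    """Map mask labels to ground-truth nuclei via the mask centroid."""
    vox_um = np.array([v / 1000.0 for v in voxel_size_nm])
    mapping = {}
    for lab, centroid in mask.centroids_vox.items():
        nt = ground_truth.nucleus_at_um(centroid * vox_um)
        assert nt is not None, "segmented nucleus centroid outside all truth nuclei"
        mapping[lab] = nt
    return mapping


@pytest.fixture(scope="session")
def noiseless_phantom():
    params = FociPhantomParams(
        n_nuclei=6, n_gh2ax_per_nucleus=5, extra_smc6=1, noise=False,
        stack_shape=(42, 224, 336), seed=BASE_SEED,
    )
    return params, *gen_foci_stack(params)


@pytest.fixture(scope="session")
def noisy_phantom():
    params = FociPhantomParams(
        n_nuclei=6, n_gh2ax_per_nucleus=8, noise=True,
        stack_shape=(42, 224, 336), seed=BASE_SEED + 1,
    )
    return params, *gen_foci_stack(params)
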