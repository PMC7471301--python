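"""Independent oracles used by the tests.

These re-derive expected values from first principles (exhaustive
enumeration, closed forms) without going through the code paths they
check.
"""

import numpy as np


def neighbor_pairs_6(shape, spacing):
    """All unordered face-neighbor voxel pairs (flat indices) and distances."""
    flat = np.arange(int(np.prod(shape))).reshape(shape)
    pairs = []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, shape[ax] - 1)
        sl_b[ax] = slice(1, shape[ax])
        ia = flat[tuple(sl_a)].ravel()
        ib = flat[tuple(sl_b)].ravel()
        pairs.append((ia, ib, float(spacing[ax])))
    return pairs


def exhaustive_min_energy(volume, seeds, params, model):
    """Exact minimum of the segmentation energy over all labelings that
    honor the seeds, by vectorized enumeration.  Volume must have at most
    ~20 free voxels."""
    shape = volume.shape
    n = int(np.prod(shape))
    intensities = volume.data.astype(float).ravel()
    u1 = -model.log_p_fg(intensities)
    u0 = -model.log_p_bg(intensities)

    fg = np.ravel_multi_index(seeds.foreground.T, shape)
    bg = np.ravel_multi_index(seeds.background.T, shape)
    fixed = np.concatenate([fg, bg])
    free = np.setdiff1d(np.arange(n), fixed)
    nf = len(free)
    assert nf <= 20, "exhaustive oracle limited to 20 free voxels"

    # all labelings: fixed seed labels + every bit pattern on free voxels
    count = 1 << nf
    labels = np.zeros((count, n), dtype=bool)
    labels[:, fg] = True
    bits = np.arange(count, dtype=np.uint32)
    for b, vox in enumerate(free):
        labels[:, vox] = (bits >> b) & 1

    energy = labels @ u1 + (~labels) @ u0
    sigma2 = 2.0 * params.sigma_edge**2
    for ia, ib, dist in neighbor_pairs_6(shape, volume.spacing):
        w = np.exp(-((intensities[ia] - intensities[ib]) ** 2) / sigma2) / dist
        energy += params.lam * ((labels[:, ia] != labels[:, ib]) @ w)
    return float(energy.min())


def point_to_plane_distance(point, a, b, c):
    """Unsigned point-to-plane distance through three points, closed form."""
    a, b, c, point = (np.asarray(v, float) for v in (a, b, c, point))
    n = np.cross(b - a, c - a)
    return abs(np.dot(point - a, n)) / np.linalg.norm(n)


def point_to_line_distance_2d(p, a, b):
    """Unsigned 2-D point-to-line distance, |cross| / |b - a|."""
    a, b, p = (np.asarray(v, float) for v in (a, b, p))
    e = b - a
    return abs(e[0] * (p[1] - a[1]) - e[1] * (p[0] - a[0])) / np.linalg.norm(e)
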