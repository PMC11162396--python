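"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: component
labelling is a plain breadth-first flood fill, Otsu is an exhaustive
threshold sweep, and the depth-weighted projection is a direct vectorized
sum over grid planes.
"""

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """26-connectivity component labels via breadth-first flood fill."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    current = 0
    nz, ny, nx = mask.shape
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        labels[start] = current
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < nz
                    and 0 <= p[1] < ny
                    and 0 <= p[2] < nx
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = current
                    queue.append(p)
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True when two labelings induce the same partition of the foreground."""
    if not np.array_equal(labels_a > 0, labels_b > 0):
        return False
    fg = labels_a > 0
    pairs = set(zip(labels_a[fg].tolist(), labels_b[fg].tolist()))
    a_to_b = {}
    b_to_a = {}
    for a, b in pairs:
        if a_to_b.setdefault(a, b) != b or b_to_a.setdefault(b, a) != a:
            return False
    return True


def otsu_sweep(values: np.ndarray) -> float:
    """Exhaustive between-class-variance-maximizing threshold.

    Returns the candidate value t maximizing the weighted between-class
    variance of the split ``values < t`` / ``values >= t``.
    """
    flat = np.sort(np.unique(values.ravel().astype(np.float64)))
    best_t, best_var = flat[0], -1.0
    for t in flat[1:]:
        lo = values[values < t]
        hi = values[values >= t]
        w0, w1 = lo.size, hi.size
        if w0 == 0 or w1 == 0:
            continue
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def depth_weighted_projection(
    field: np.ndarray, grid_spacing: float, z_face: float, attenuation: float
) -> np.ndarray:
    """Direct sum of grid planes below a cut face with exponential weights.

    Requires the cut face to lie exactly on a grid plane; unit weight at
    the face itself, ``exp(-depth / attenuation)`` below.
    """
    j0 = int(round(z_face / grid_spacing))
    assert abs(j0 * grid_spacing - z_face) < 1e-9, "face must lie on the grid"
    depths = (np.arange(field.shape[0] - j0)) * grid_spacing
    weights = np.exp(-depths / attenuation)
    return np.tensordot(weights, field[j0:], axes=(0, 0))
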