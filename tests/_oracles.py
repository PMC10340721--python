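"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the implementation: flood fill is a pure-Python BFS, the total-least-
squares line comes from the closed-form angle rather than an eigendecomposition.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np

NEIGHBOURS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components of a 3D boolean array, BFS voxel by voxel."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        if seen[z, y, x]:
            continue
        comp = set()
        queue = deque([(int(z), int(y), int(x))])
        seen[z, y, x] = True
        while queue:
            cz, cy, cx = queue.popleft()
            comp.add((cz, cy, cx))
            for dz, dy, dx in NEIGHBOURS_26:
                pz, py, px = cz + dz, cy + dy, cx + dx
                if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                    if mask[pz, py, px] and not seen[pz, py, px]:
                        seen[pz, py, px] = True
                        queue.append((pz, py, px))
        comps.append(comp)
    return comps


def tls_line_closed_form(a: np.ndarray, b: np.ndarray):
    """Orthogonal regression line via the closed-form angle.

    The direction minimising the sum of squared perpendicular distances makes
    angle phi with the x-axis where tan(2*phi) = 2*Sab / (Saa - Sbb), with
    centred second moments S. Returns (mean point, unit direction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ma, mb = a.mean(), b.mean()
    da, db = a - ma, b - mb
    saa, sbb, sab = (da * da).sum(), (db * db).sum(), (da * db).sum()
    phi = 0.5 * np.arctan2(2 * sab, saa - sbb)
    direction = np.array([np.cos(phi), np.sin(phi)])
    return np.array([ma, mb]), direction


def perpendicular_distances(a, b, point, direction):
    pts = np.stack([np.asarray(a, float), np.asarray(b, float)], axis=1) - point
    normal = np.array([-direction[1], direction[0]])
    return np.abs(pts @ normal)
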