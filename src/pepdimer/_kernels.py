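"""Compiled inner loops for move evaluation.

The square-well model's cost per Monte Carlo step is dominated by updating
minimum-image distances of the displaced beads and re-checking bond windows,
hard cores and well occupancies against them.  These loops are compiled with
numba; the hydrogen-bond matching stays in Python (it runs on a handful of
candidate pairs).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["move_kernel"]


@njit(cache=True, fastmath=False)
def move_kernel(new_coords, moved, moved_mask, box, dist_old, patched,
                bond_i, bond_j, bond_lo, bond_hi,
                hs_matrix, sw_depth_index, sw_dsw, n_depths):
    """Evaluate feasibility and square-well occupancy changes of a move.

    Writes updated minimum-image distances for the moved beads into
    ``patched`` (a copy of ``dist_old``) and returns
    ``(feasible, sw_delta)`` where ``sw_delta[k]`` is the change in the
    number of occupied wells of depth index ``k``.
    """
    n = new_coords.shape[0]
    sw_delta = np.zeros(n_depths, dtype=np.int64)

    # bonds touching moved beads
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        if moved_mask[i] or moved_mask[j]:
            dx = new_coords[i, 0] - new_coords[j, 0]
            dy = new_coords[i, 1] - new_coords[j, 1]
            dz = new_coords[i, 2] - new_coords[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            if r < bond_lo[b] or r > bond_hi[b]:
                return False, sw_delta

    for t in range(moved.shape[0]):
        m = moved[t]
        for j in range(n):
            if j == m:
                continue
            dx = new_coords[m, 0] - new_coords[j, 0]
            dy = new_coords[m, 1] - new_coords[j, 1]
            dz = new_coords[m, 2] - new_coords[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            hs = hs_matrix[m, j]
            if hs > 0.0 and r <= hs:
                return False, sw_delta
            # count each affected pair once
            if (not moved_mask[j]) or (j > m):
                k = sw_depth_index[m, j]
                if k >= 0:
                    dsw = sw_dsw[m, j]
                    r_old = dist_old[m, j]
                    if hs < r < dsw:
                        sw_delta[k] += 1
                    if hs < r_old < dsw:
                        sw_delta[k] -= 1
            patched[m, j] = r
            patched[j, m] = r
    return True, sw_delta
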