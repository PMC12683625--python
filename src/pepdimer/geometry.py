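"""Geometry kernels: periodic boundaries, sphere intersections, dihedrals,
rigid rotations, and deterministic construction of feasible extended chains.

The bond network is a web of narrow square-well windows, so an initial
configuration cannot be written down from textbook internal coordinates; it is
built bead by bead as an exact intersection of the ideal-length spheres, with
depth-first backtracking over the remaining angular freedom and steric checks
against all previously placed beads.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image",
    "pair_distances",
    "dihedral",
    "rotation_matrix",
    "build_chain_coords",
    "SetupError",
]


class SetupError(RuntimeError):
    """No feasible initial placement was found within bounded retries."""


def minimum_image(dx: np.ndarray, box_edge: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return dx - box_edge * np.round(dx / box_edge)


def pair_distances(coords_a, coords_b, box_edge):
    """Minimum-image distances between two bead sets, shape (len(a), len(b))."""
    dx = coords_a[:, None, :] - coords_b[None, :, :]
    dx = minimum_image(dx, box_edge)
    return np.sqrt(np.einsum("ijk,ijk->ij", dx, dx))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians, in (-pi, pi]) of four points about
    the p1-p2 axis, using the standard atan2 formulation."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return float(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _circle_points(p1, r1, p2, r2, n_angles):
    """Points on the intersection circle of two spheres (empty if disjoint)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = np.linalg.norm(p2 - p1)
    if d < 1e-12 or d > r1 + r2 or d < abs(r1 - r2):
        return []
    u = (p2 - p1) / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - a * a
    if h2 < 0:
        return []
    rho = np.sqrt(max(h2, 0.0))
    centre = p1 + a * u
    # deterministic orthonormal basis perpendicular to u
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    return [centre + rho * (np.cos(t) * e1 + np.sin(t) * e2) for t in thetas]


def _trilaterate(p1, r1, p2, r2, p3, r3):
    """Intersection points of three spheres (0, 1 or 2 points)."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d < 1e-12:
        return []
    ex /= d
    i = np.dot(ex, p3 - p1)
    ey = p3 - p1 - i * ex
    ny = np.linalg.norm(ey)
    if ny < 1e-12:
        return []
    ey /= ny
    ez = np.cross(ex, ey)
    j = np.dot(ey, p3 - p1)
    x = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    y = (r1 * r1 - r3 * r3 + i * i + j * j - 2 * i * x) / (2 * j)
    z2 = r1 * r1 - x * x - y * y
    if z2 < -1e-9:
        return []
    z = np.sqrt(max(z2, 0.0))
    base = p1 + x * ex + y * ey
    if z < 1e-9:
        return [base]
    return [base + z * ez, base - z * ez]


def build_chain_coords(topology, params, n_angles: int = 16) -> np.ndarray:
    """Deterministically embed a chain satisfying every bond window exactly
    (ideal lengths) and all hard-sphere constraints.

    Backbone beads are placed residue by residue on the exact sphere
    intersections of their ideal bond and pseudo-bond lengths; the remaining
    angular freedom is searched depth-first, preferring extended placements.
    Side-chain beads are attached afterwards on clash-free directions.  The
    steric table is the same one the energy model uses
    (:meth:`ChainTopology.hs_matrix`), so an accepted embedding is feasible
    for the model by construction.

    Raises
    ------
    SetupError
        if no feasible embedding is found.
    """
    bl = params.bond_lengths
    pl = params.pseudobond_lengths
    n_res = topology.n_residues
    hsm = topology.hs_matrix(params)

    r_NA = bl[("NH", "CA", 0)]
    r_AC = bl[("CA", "CO", 0)]
    r_CN = bl[("CO", "NH", 1)]
    r_AN1 = pl[("CA", "NH", 1)]
    r_CA1 = pl[("CO", "CA", 1)]
    r_AA1 = pl[("CA", "CA", 1)]
    r_NC1 = pl[("NH", "CO", 1)]

    coords = np.zeros((topology.n_beads, 3))
    placed = np.zeros(topology.n_beads, dtype=bool)

    def idx(res, kind):
        return topology.bead_index(res, kind)

    def clashes(point, bead_idx):
        thr = hsm[bead_idx]
        for j in np.nonzero(placed)[0]:
            if thr[j] > 0.0 and np.linalg.norm(point - coords[j]) <= thr[j]:
                return True
        return False

    def put(bead_idx, point):
        coords[bead_idx] = point
        placed[bead_idx] = True

    # first residue: angle at CA is unconstrained by bonds; pick a value
    # comfortably outside the intra-residue NH-CO hard core
    put(idx(0, "NH"), np.zeros(3))
    put(idx(0, "CA"), np.array([r_NA, 0.0, 0.0]))
    theta = np.deg2rad(111.0)
    put(idx(0, "CO"),
        coords[idx(0, "CA")] + r_AC * np.array([-np.cos(theta), np.sin(theta), 0.0]))

    def solve(res):
        if res == n_res:
            return True
        N1 = coords[idx(res - 1, "NH")]
        A1 = coords[idx(res - 1, "CA")]
        C1 = coords[idx(res - 1, "CO")]
        iN, iA, iC = idx(res, "NH"), idx(res, "CA"), idx(res, "CO")

        n2_candidates = _circle_points(C1, r_CN, A1, r_AN1, n_angles)
        # prefer extension: away from the previous residue's N
        n2_candidates.sort(key=lambda p: -np.linalg.norm(p - N1))
        for N2 in n2_candidates:
            if clashes(N2, iN):
                continue
            put(iN, N2)
            for A2 in _trilaterate(N2, r_NA, C1, r_CA1, A1, r_AA1):
                if clashes(A2, iA):
                    continue
                put(iA, A2)
                c2_candidates = _circle_points(A2, r_AC, N1, r_NC1, n_angles)
                c2_candidates.sort(key=lambda p: -np.linalg.norm(p - A1))
                for C2 in c2_candidates:
                    if clashes(C2, iC):
                        continue
                    put(iC, C2)
                    if solve(res + 1):
                        return True
                    placed[iC] = False
                placed[iA] = False
            placed[iN] = False
        return False

    if not solve(1):
        raise SetupError(
            f"could not embed a {n_res}-residue backbone satisfying all bond windows"
        )

    backbone_idx = np.nonzero(placed)[0]
    centroid = coords[backbone_idx].mean(axis=0)
    golden = np.pi * (3.0 - np.sqrt(5.0))

    for i, (res, kind) in enumerate(topology.beads):
        if kind != "SC":
            continue
        A = coords[idx(res, "CA")]
        outward = A - centroid
        if np.linalg.norm(outward) < 1e-9:
            outward = np.array([0.0, 0.0, 1.0])
        outward /= np.linalg.norm(outward)
        pole = np.array([0.0, 0.0, 1.0])
        axis = np.cross(pole, outward)
        ang = np.arccos(np.clip(np.dot(pole, outward), -1, 1))
        rot = rotation_matrix(axis, ang) if np.linalg.norm(axis) > 1e-9 else np.eye(3)
        found = False
        for k in range(128):
            # spiral over directions, starting near 'outward'
            z = 1.0 - 2.0 * k / 127.0
            r = np.sqrt(max(1.0 - z * z, 0.0))
            phi = golden * k
            d = rot @ np.array([r * np.cos(phi), r * np.sin(phi), z])
            cand = A + params.sc_bond_length * d
            if not clashes(cand, i):
                put(i, cand)
                found = True
                break
        if not found:
            raise SetupError(f"could not attach side-chain bead of residue {res}")

    return coords - coords.mean(axis=0)
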