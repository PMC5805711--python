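"""Independent numerical oracles used only by the test suite."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_superpose_rmsd(mobile, target, coarse_deg=15.0):
    """Best-rigid-fit RMSD by exhaustive rotation search plus local refinement.

    Independent of the SVD route: centers both sets (the optimal
    translation matches centroids for any rotation), scans a coarse
    Euler-angle grid, then polishes the best cell with Nelder-Mead to
    far below 0.1 degree resolution.
    """
    A = np.asarray(mobile, float)
    B = np.asarray(target, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rmsd_of(euler):
        R = Rotation.from_euler("zyz", euler).as_matrix()
        d = A @ R.T - B
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    grid = np.arange(0.0, 360.0, coarse_deg)
    grid_beta = np.arange(0.0, 180.0 + coarse_deg, coarse_deg)
    az, el, rz = np.meshgrid(grid, grid_beta, grid, indexing="ij")
    eulers = np.column_stack([az.ravel(), el.ravel(), rz.ravel()])
    mats = Rotation.from_euler("zyz", eulers, degrees=True).as_matrix()
    moved = np.einsum("rij,nj->rni", mats, A)
    rmsds = np.sqrt(np.mean(np.sum((moved - B[None]) ** 2, axis=2), axis=1))
    best = eulers[int(np.argmin(rmsds))]

    res = minimize(
        lambda e: rmsd_of(np.deg2rad(e)),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
    )
    return float(res.fun)


def complex_concentration_brentq(P_t, L_t, Kd):
    """1-D root-bracketing solution of (P-c)(L-c) = Kd*c on [0, min(P, L)]."""
    from scipy.optimize import brentq

    if L_t == 0 or P_t == 0:
        return 0.0

    def balance(c):
        return (P_t - c) * (L_t - c) - Kd * c

    hi = min(P_t, L_t)
    if balance(hi) >= 0:
        return hi
    return brentq(balance, 0.0, hi, xtol=1e-24, rtol=1e-15)
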