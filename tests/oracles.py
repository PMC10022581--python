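"""Independent reference implementations used only to check the package.

Each oracle is written from the textbook formulation, deliberately not
sharing code with the implementation it validates.
"""

import numpy as np


def dihedral_normal_form(p1, p2, p3, p4):
    """Signed dihedral via the two plane normals (atan2 form), degrees."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else ang


def needleman_wunsch_affine(a, b, match=1.0, mismatch=-1.0,
                            gap_open=-5.0, gap_extend=-1.0):
    """Global alignment score with affine gaps (Gotoh three-matrix DP).

    ``gap_open`` is the score of the first gapped position, ``gap_extend``
    of each further position.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to '-')
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def quaternion_superposition_rmsd(moving, fixed):
    """Optimal-superposition RMSD via the Horn quaternion method."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    a = moving - moving.mean(axis=0)
    b = fixed - fixed.mean(axis=0)
    sxx = a.T @ b
    k = np.empty((4, 4))
    k[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    k[0, 1] = k[1, 0] = sxx[1, 2] - sxx[2, 1]
    k[0, 2] = k[2, 0] = sxx[2, 0] - sxx[0, 2]
    k[0, 3] = k[3, 0] = sxx[0, 1] - sxx[1, 0]
    k[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    k[1, 2] = k[2, 1] = sxx[0, 1] + sxx[1, 0]
    k[1, 3] = k[3, 1] = sxx[0, 2] + sxx[2, 0]
    k[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    k[2, 3] = k[3, 2] = sxx[1, 2] + sxx[2, 1]
    k[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = (a ** 2).sum() + (b ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(e2, 0.0) / len(moving)))


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def circular_mean_vector(values_deg):
    """Circular mean by averaging unit vectors, degrees."""
    rad = np.radians(np.asarray(values_deg, float))
    return np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
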