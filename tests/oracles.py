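"""Independent reference implementations used only to check the package.

These deliberately share no code with megastitch: the superposition oracle
uses Horn's quaternion characteristic-polynomial method instead of SVD,
the radius oracle is a brute-force all-pairs scan, and the window oracle
sums windows directly.
"""

from __future__ import annotations

import numpy as np

from megastitch.constants import KYTE_DOOLITTLE, vdw_radius


def quaternion_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation of Q onto P via Horn's quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(0), Q.mean(0)
    Pc, Qc = P - cp, Q - cq
    S = Qc.T @ Pc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    rmsd = float(np.sqrt(np.mean(np.sum((Pc - Qc @ R.T) ** 2, axis=1))))
    return R, rmsd


def brute_force_min_radius(model, point: np.ndarray) -> float:
    """Maximal-ball radius at a point: plain all-atom minimum, no index."""
    d = np.linalg.norm(model.coords - np.asarray(point, float), axis=1)
    vdw = np.array([vdw_radius(e) for e in model.element])
    return float((d - vdw).min())


def brute_force_clashes(model, cutoff: float, min_sep: int = 3) -> set[tuple[int, int]]:
    """All-pairs clash scan (quadratic, small models only)."""
    n = len(model)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if abs(int(model.residue_number[i]) - int(model.residue_number[j])) < min_sep:
                continue
            if np.linalg.norm(model.coords[i] - model.coords[j]) <= cutoff:
                out.add((i, j))
    return out


def direct_window_means(seq: str, window: int) -> dict[int, float]:
    """Sliding hydropathy means by explicit per-window summation.

    Keys are 1-based centre positions; 'X' contributes 0.
    """
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq.upper()]
    half = window // 2
    out = {}
    for c in range(half, len(seq) - half):
        out[c + 1] = sum(vals[c - half : c + half + 1]) / window
    return out


def direct_moment(seq: str, delta_deg: float = 100.0) -> float:
    """Hydrophobic moment by explicit vector summation."""
    sx = sy = 0.0
    for i, aa in enumerate(seq.upper()):
        h = KYTE_DOOLITTLE.get(aa, 0.0)
        ang = np.deg2rad(delta_deg) * i
        sx += h * np.cos(ang)
        sy += h * np.sin(ang)
    return float(np.hypot(sx, sy) / len(seq))
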