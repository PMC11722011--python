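"""Independent numerical oracles used only by the test suite."""

import numpy as np


def quaternion_rmsd(P, Q):
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method.

    Independent of the SVD-based implementation under test: builds the 4x4
    key matrix from the centered correlation matrix and takes its largest
    eigenvalue.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    e2 = (P0 * P0).sum() + (Q0 * Q0).sum() - 2.0 * lam_max
    return np.sqrt(max(e2, 0.0) / len(P))


def tauc_to_ratio_oracle(tauc_ns, nu_h_mhz, gamma_ratio=0.1013756):
    """Hand-derived algebraic inverse of the tau_c(R2/R1) expression."""
    nu_n_hz = nu_h_mhz * 1e6 * gamma_ratio
    x = 4.0 * np.pi * nu_n_hz * tauc_ns * 1e-9
    return (x ** 2 + 7.0) / 6.0


def random_rotation(rng):
    """Uniform random proper rotation from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm
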