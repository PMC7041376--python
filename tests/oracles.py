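"""Independent closed-form / symbolic oracles shared by the FE tests.

Everything here is written against the textbook formulas, not against the
package internals, so agreement is a genuine cross-check.
"""

import numpy as np


def terzaghi_pressure(z_from_drained, L, cv, t, p0, n_terms=60):
    """1-D consolidation pore-pressure series (single drainage at z=0)."""
    M = (2 * np.arange(n_terms) + 1) * np.pi / 2.0
    Z = np.asarray(z_from_drained, dtype=float) / L
    T = cv * t / L**2
    return p0 * (
        (2.0 / M)[None, :] * np.sin(np.outer(Z, M)) * np.exp(-(M**2) * T)[None, :]
    ).sum(axis=1)


def terzaghi_settlement(L, cv, t, p0, M_constrained, n_terms=60):
    """Consolidation settlement of the column at time t (no undrained part
    for incompressible constituents)."""
    M = (2 * np.arange(n_terms) + 1) * np.pi / 2.0
    T = cv * t / L**2
    U = 1.0 - np.sum((2.0 / M**2) * np.exp(-(M**2) * T))
    return p0 * L / M_constrained * U


def sympy_hex_stiffness(h, E, nu):
    """Exact (symbolically integrated) stiffness of a trilinear cube element.

    Built from scratch: trilinear shape functions on [0, h]^3 in the same
    node order as the package (VTK hexahedron), small-strain B matrix,
    isotropic C, entries integrated with sympy.
    """
    import sympy as sym

    x, y, z = sym.symbols("x y z", positive=True)
    corners = [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ]
    hs = sym.Rational(1)
    N = []
    for cx, cy, cz in corners:
        nx = x / h if cx else 1 - x / h
        ny = y / h if cy else 1 - y / h
        nz = z / h if cz else 1 - z / h
        N.append(nx * ny * nz)

    lam = sym.nsimplify(E) * nu / ((1 + nu) * (1 - 2 * nu))
    G = sym.nsimplify(E) / (2 * (1 + nu))
    C = sym.zeros(6, 6)
    for i in range(3):
        for j in range(3):
            C[i, j] = lam
    for i in range(3):
        C[i, i] += 2 * G
    for i in range(3, 6):
        C[i, i] = G

    B = sym.zeros(6, 24)
    for a in range(8):
        gx, gy, gz = sym.diff(N[a], x), sym.diff(N[a], y), sym.diff(N[a], z)
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx

    integrand = B.T * C * B
    K = sym.zeros(24, 24)
    for i in range(24):
        for j in range(i, 24):
            val = sym.integrate(
                sym.integrate(sym.integrate(integrand[i, j], (x, 0, h)), (y, 0, h)),
                (z, 0, h),
            )
            K[i, j] = K[j, i] = val
    return np.array(K, dtype=float)
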