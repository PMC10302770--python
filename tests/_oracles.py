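"""Independent brute-force oracles used by the test suite.

Everything here is written from the mathematical statement of the
problem, with explicit loops and generic root finding, deliberately
avoiding the package's own solver machinery.
"""

import numpy as np
from scipy.optimize import root


def dense_oxygen_solve(alpha, medium_mask, Q, Q1):
    """Solve ∇²C = Q·α·C/(1+Q1·C) on the unit square by generic root
    finding on the dense residual (5-point stencil, mirrored walls,
    C = 1 on medium nodes)."""
    ny, nx = alpha.shape
    hx, hy = 1.0 / (nx - 1), 1.0 / (ny - 1)

    def residual(cvec):
        c = cvec.reshape(ny, nx)
        r = np.empty_like(c)
        for j in range(ny):
            for i in range(nx):
                if medium_mask[j, i]:
                    r[j, i] = c[j, i] - 1.0
                    continue
                im, ip = (1 if i == 0 else i - 1), (nx - 2 if i == nx - 1 else i + 1)
                jm, jp = (1 if j == 0 else j - 1), (ny - 2 if j == ny - 1 else j + 1)
                lap = ((c[j, ip] - 2 * c[j, i] + c[j, im]) / hx**2
                       + (c[jp, i] - 2 * c[j, i] + c[jm, i]) / hy**2)
                r[j, i] = lap - Q * alpha[j, i] * c[j, i] / (1 + Q1 * c[j, i])
        return r.ravel()

    sol = root(residual, np.ones(nx * ny), method="krylov",
               options={"fatol": 1e-12})
    assert sol.success, sol.message
    return sol.x.reshape(ny, nx)


def strip_closed_form(x, Q):
    """C'' = Q·C on [0,1] with C(0) = C(1) = 1 (uniform alpha = 1, Q1 = 0)."""
    s = np.sqrt(Q)
    return np.cosh(s * (x - 0.5)) / np.cosh(s / 2.0)


def count_above_threshold(img, threshold):
    """Exhaustive pixel scan."""
    n = 0
    for row in np.asarray(img, dtype=float):
        for v in row:
            if v > threshold:
                n += 1
    return n
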