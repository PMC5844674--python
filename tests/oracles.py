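"""Independent closed-form oracles used to verify the numerical solvers.

The layered Lame solution is assembled directly from the textbook
``u = A r + B / r`` ansatz per layer with interface continuity of
displacement and radial stress, an applied inner pressure and a spring
traction on the outer boundary. It shares no code with the finite-element
path it checks.
"""

import numpy as np


def lame_layered(radii, lams, mus, pressure, foundation_k):
    """Plane-strain layered thick-walled cylinder under inner pressure.

    Parameters
    ----------
    radii : sequence of layer-boundary radii, inner to outer (n_layers + 1)
    lams, mus : Lame parameters per layer
    pressure : inner lumen pressure (sigma_rr(a) = -P)
    foundation_k : outer spring, sigma_rr(b) = -k u(b)

    Returns
    -------
    functions u(r), sigma_rr(r), eps_theta(r) valid across all layers.
    """
    radii = np.asarray(radii, dtype=float)
    n = len(mus)
    # unknowns [A_0, B_0, A_1, B_1, ...]
    m = np.zeros((2 * n, 2 * n))
    rhs = np.zeros(2 * n)

    def srr_coeffs(lam, mu, r):
        return 2.0 * (lam + mu), -2.0 * mu / r ** 2

    # inner boundary
    ca, cb = srr_coeffs(lams[0], mus[0], radii[0])
    m[0, 0], m[0, 1] = ca, cb
    rhs[0] = -pressure
    row = 1
    for i in range(n - 1):
        r = radii[i + 1]
        # displacement continuity
        m[row, 2 * i:2 * i + 2] = [r, 1.0 / r]
        m[row, 2 * i + 2:2 * i + 4] = [-r, -1.0 / r]
        row += 1
        # radial stress continuity
        ca, cb = srr_coeffs(lams[i], mus[i], r)
        cc, cd = srr_coeffs(lams[i + 1], mus[i + 1], r)
        m[row, 2 * i:2 * i + 2] = [ca, cb]
        m[row, 2 * i + 2:2 * i + 4] = [-cc, -cd]
        row += 1
    # outer boundary: sigma_rr(b) + k u(b) = 0
    b = radii[-1]
    ca, cb = srr_coeffs(lams[-1], mus[-1], b)
    m[row, 2 * (n - 1)] = ca + foundation_k * b
    m[row, 2 * (n - 1) + 1] = cb + foundation_k / b
    coef = np.linalg.solve(m, rhs)

    def layer_of(r):
        return np.clip(np.searchsorted(radii[1:-1], r, side="right"), 0, n - 1)

    def u(r):
        r = np.asarray(r, dtype=float)
        i = layer_of(r)
        a_c = coef[2 * i]
        b_c = coef[2 * i + 1]
        return a_c * r + b_c / r

    def sigma_rr(r):
        r = np.asarray(r, dtype=float)
        i = layer_of(r)
        lam = np.take(lams, i)
        mu = np.take(mus, i)
        a_c = coef[2 * i]
        b_c = coef[2 * i + 1]
        return 2.0 * (lam + mu) * a_c - 2.0 * mu * b_c / r ** 2

    def eps_theta(r):
        r = np.asarray(r, dtype=float)
        i = layer_of(r)
        return coef[2 * i] + coef[2 * i + 1] / r ** 2

    return u, sigma_rr, eps_theta


def heat_kernel_decay(x, y, t, sigma0, diffusivity, decay):
    """Decaying Gaussian solution of dC/dt = D lap C - K C on the plane,
    normalised to peak 1 at t = 0."""
    var = sigma0 ** 2 + 2.0 * diffusivity * t
    return (sigma0 ** 2 / var) * np.exp(-(x ** 2 + y ** 2) / (2.0 * var)) \
        * np.exp(-decay * t)
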