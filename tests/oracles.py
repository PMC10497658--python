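"""Independent reference computations used only by the test suite.

These deliberately avoid the code paths they check: the radial two-point
boundary-value solve uses collocation on the real/imaginary split ODE, the
Womersley pipe formula is evaluated directly from Bessel functions, and the
polygon metrics use the shoelace formula on dense vertex lists.
"""

import numpy as np
from scipy.integrate import solve_bvp
from scipy.special import jv


def womersley_pipe_mobility(radius, frequency, density=1.0, viscosity=0.01):
    """Closed-form oscillatory mobility of a circular pipe, J0/J1 form."""
    omega = 2 * np.pi * frequency
    if omega == 0:
        return np.pi * radius**4 / (8 * viscosity)
    alpha = radius * np.sqrt(omega * density / viscosity)
    lam = alpha * np.exp(3j * np.pi / 4)
    return (
        np.pi
        * radius**2
        / (1j * omega * density)
        * (1 - 2 * jv(1, lam) / (lam * jv(0, lam)))
    )


def annulus_mobility_bvp(r_inner, r_outer, frequency, density=1.0, viscosity=0.01):
    """Oscillatory annulus mobility by numerically solving the radial ODE.

    mu (u'' + u'/r) - i w rho u = -1 with u(ri) = u(ro) = 0, split into real
    and imaginary parts and solved by collocation; the flow integral
    2 pi int r u dr is evaluated by the trapezoid rule on a fine grid.
    """
    omega = 2 * np.pi * frequency

    def rhs(r, y):
        ur, ui, vr, vi = y
        # u'' = -u'/r + (i w rho u - 1)/mu
        d2r = -vr / r + (-omega * density * ui - 1.0) / viscosity
        d2i = -vi / r + (omega * density * ur) / viscosity
        return np.vstack([vr, vi, d2r, d2i])

    def bc(ya, yb):
        return np.array([ya[0], ya[1], yb[0], yb[1]])

    # mesh clustered at both walls to resolve thin Stokes layers
    t = np.linspace(0.0, 1.0, 401)
    r = r_inner + (r_outer - r_inner) * 0.5 * (1 - np.cos(np.pi * t))
    y0 = np.zeros((4, r.size))
    sol = solve_bvp(rhs, bc, r, y0, tol=1e-8, max_nodes=500000)
    assert sol.success, sol.message
    rf = np.linspace(r_inner, r_outer, 4001)
    u = sol.sol(rf)[0] + 1j * sol.sol(rf)[1]
    return 2 * np.pi * np.trapezoid(rf * u, rf)


def annulus_poiseuille_resistance(r_inner, r_outer, length, viscosity=0.01):
    """Steady annular Poiseuille resistance 8 mu L / (pi [ ... ])."""
    ri, ro = r_inner, r_outer
    bracket = ro**4 - ri**4 - (ro**2 - ri**2) ** 2 / np.log(ro / ri)
    return 8 * viscosity * length / (np.pi * bracket)


def polygon_metrics(vertices):
    """(area, perimeter) of a closed polygon via the shoelace formula."""
    v = np.asarray(vertices)
    x, y = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = np.sum(np.hypot(x2 - x, y2 - y))
    return area, perim


def eccentric_annulus_metrics(r_inner, r_outer, offset, n_vertices=10000):
    """High-resolution polygon reference for an eccentric annulus.

    Valid while the inner circle stays strictly inside the outer one, so the
    area/perimeter are differences/sums of the two circles' values.
    """
    assert offset + r_inner < r_outer
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    outer = np.c_[r_outer * np.cos(th), r_outer * np.sin(th)]
    inner = np.c_[offset + r_inner * np.cos(th), r_inner * np.sin(th)]
    ao, po = polygon_metrics(outer)
    ai, pi_ = polygon_metrics(inner)
    return ao - ai, po + pi_


def gaussian_disc_mean(peak, sigma, roi_radius):
    """Mean over a centred disc of a radial Gaussian with given peak."""
    return peak * (2 * sigma**2 / roi_radius**2) * (1 - np.exp(-(roi_radius**2) / (2 * sigma**2)))
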