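"""Independent reference implementations used only to check the package.

The Mie oracle evaluates the textbook coefficient formulas directly from
upward-evaluated Riccati–Bessel functions (scipy's spherical Bessel
routines), whereas the package uses the downward logarithmic-derivative
recurrence — a genuinely different numerical path to the same series.
"""

import numpy as np
from scipy import special


def mie_coefficients_direct(x: float, m: float, nmax: int):
    """a_n, b_n from ψ/ξ at x and m·x evaluated by scipy (upward)."""
    n = np.arange(0, nmax + 1)

    def riccati_psi(rho):
        j = special.spherical_jn(n, rho)
        jp = special.spherical_jn(n, rho, derivative=True)
        return rho * j, j + rho * jp

    psi_x, psip_x = riccati_psi(x)
    psi_mx, psip_mx = riccati_psi(m * x)
    y = special.spherical_yn(n, x)
    yp = special.spherical_yn(n, x, derivative=True)
    chi_x, chip_x = -x * y, -(y + x * yp)
    xi_x = psi_x - 1j * chi_x
    xip_x = psip_x - 1j * chip_x

    sl = slice(1, None)
    a = (m * psi_mx[sl] * psip_x[sl] - psi_x[sl] * psip_mx[sl]) / (
        m * psi_mx[sl] * xip_x[sl] - xi_x[sl] * psip_mx[sl]
    )
    b = (psi_mx[sl] * psip_x[sl] - m * psi_x[sl] * psip_mx[sl]) / (
        psi_mx[sl] * xip_x[sl] - m * xi_x[sl] * psip_mx[sl]
    )
    return a, b


def mie_qext_direct(x: float, m: float, nmax: int) -> float:
    a, b = mie_coefficients_direct(x, m, nmax)
    n = np.arange(1, nmax + 1, dtype=float)
    return float((2.0 / x**2) * np.sum((2 * n + 1) * (a + b).real))


def rayleigh_qsca(x: float, m: float) -> float:
    """Small-particle limit of the scattering efficiency."""
    return (8.0 / 3.0) * x**4 * abs((m**2 - 1.0) / (m**2 + 2.0)) ** 2
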