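"""Single-scattering physics: Mie spheres and infinite cylinders at oblique
incidence, plus precomputed sampling tables for the Monte Carlo engine.

Spheres use the Lorenz–Mie series with the logarithmic-derivative downward
recurrence and the Wiscombe truncation criterion.  Cylinders use the classical infinite-circular-
cylinder solution at oblique incidence: for tilt angle ``zeta`` between the
incident direction and the cylinder axis, scattered light is confined to a
cone with the same axial direction component, parameterized by the azimuth
``Theta`` around the cone (``Theta = 0`` is forward).

Scatterers are embedded in the interstitial medium, so size parameters use
the medium wavelength and the relative index n_scatterer / n_medium
(defaults 1.4 / 1.33).  Populations are specified by their share of the
total scattering coefficient (the "sphere-cylinder ratio" against a fixed
μs), not by number density.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special

__all__ = [
    "SpherePopulation",
    "CylinderPopulation",
    "ScatteringLookup",
    "mie_coefficients",
    "mie_efficiencies",
    "mie_S1S2",
    "mie_mueller",
    "mie_asymmetry",
    "cylinder_coefficients",
    "cylinder_amplitudes",
    "cylinder_efficiencies",
    "amplitude_to_mueller",
    "build_lookup",
]


@dataclass(frozen=True)
class SpherePopulation:
    """Monodisperse spherical scatterers (organelles / nuclei surrogate)."""

    diameter_um: float = 0.2
    refractive_index: float = 1.4
    mus_share: float = 20.0  # cm^-1

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.refractive_index <= 1.0:
            raise ValueError("refractive index must exceed 1")
        if self.mus_share < 0:
            raise ValueError("mus_share must be nonnegative")


@dataclass(frozen=True)
class CylinderPopulation:
    """Infinitely long cylindrical scatterers (dermal-fibre surrogate).

    ``mean_axis_deg`` and ``angular_std_deg`` describe the wrapped-normal
    distribution of the per-event fibre axis within the sample plane.
    """

    diameter_um: float = 1.5
    refractive_index: float = 1.4
    mus_share: float = 180.0  # cm^-1
    mean_axis_deg: float = 0.0
    angular_std_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.angular_std_deg < 0:
            raise ValueError("angular_std must be nonnegative")
        if self.mus_share < 0:
            raise ValueError("mus_share must be nonnegative")


# ---------------------------------------------------------------------------
# Mie series (spheres)
# ---------------------------------------------------------------------------

def _wiscombe_nmax(x: float) -> int:
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0)) + 1


def mie_coefficients(size_parameter: float, relative_index: float | complex,
                     nmax: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mie series coefficients (a_n, b_n), n = 1..N.

    Uses downward recurrence for the logarithmic derivative at ``m·x`` and
    upward Riccati–Bessel recurrences at ``x``; N follows the Wiscombe
    criterion unless given.
    """
    x = float(size_parameter)
    if x <= 0:
        raise ValueError("size parameter must be positive")
    m = complex(relative_index)
    N = nmax or _wiscombe_nmax(x)
    mx = m * x

    # downward recurrence for D_n(mx), seeded well above N
    nstart = N + max(15, int(np.ceil(abs(mx))) // 2 + 15)
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    if not np.all(np.isfinite(D[: N + 1])):
        raise ArithmeticError("downward recurrence for the Mie log-derivative diverged")
    D = D[1 : N + 1]

    n = np.arange(1, N + 1, dtype=float)
    # Riccati-Bessel psi, chi at real x via scipy spherical Bessel functions
    jn = special.spherical_jn(np.arange(0, N + 1), x)
    yn = special.spherical_yn(np.arange(0, N + 1), x)
    psi = x * jn[1:]
    psi_m1 = x * jn[:-1]
    chi = -x * yn[1:]
    chi_m1 = -x * yn[:-1]
    xi = psi - 1j * chi
    xi_m1 = psi_m1 - 1j * chi_m1

    da = D / m + n / x
    db = D * m + n / x
    a = (da * psi - psi_m1) / (da * xi - xi_m1)
    b = (db * psi - psi_m1) / (db * xi - xi_m1)
    return a, b


def mie_efficiencies(size_parameter: float, relative_index: float | complex
                     ) -> tuple[float, float]:
    """(Qext, Qsca) scattering efficiencies."""
    x = float(size_parameter)
    a, b = mie_coefficients(x, relative_index)
    n = np.arange(1, a.size + 1, dtype=float)
    qext = (2.0 / x**2) * np.sum((2 * n + 1) * (a + b).real)
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    return float(qext), float(qsca)


def mie_asymmetry(size_parameter: float, relative_index: float | complex) -> float:
    """Asymmetry parameter g = <cos θ> of the Mie phase function."""
    x = float(size_parameter)
    a, b = mie_coefficients(x, relative_index)
    n = np.arange(1, a.size + 1, dtype=float)
    ab_next = np.empty(a.size)
    ab_next[:-1] = (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ab_next[-1] = 0.0
    cross = (a * np.conj(b)).real
    _, qsca = mie_efficiencies(x, relative_index)
    g = (4.0 / (x**2 * qsca)) * np.sum(
        (n * (n + 2) / (n + 1)) * ab_next + ((2 * n + 1) / (n * (n + 1))) * cross
    )
    return float(g)


def _pi_tau(costheta: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n, tau_n for n = 1..N, shapes (N, len(theta))."""
    mu = np.atleast_1d(costheta)
    pi = np.zeros((N + 1, mu.size))
    tau = np.zeros((N + 1, mu.size))
    pi[1] = 1.0
    for n in range(2, N + 1):
        pi[n] = ((2 * n - 1) / (n - 1)) * mu * pi[n - 1] - (n / (n - 1)) * pi[n - 2]
    for n in range(1, N + 1):
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def mie_S1S2(size_parameter: float, relative_index: float | complex,
             theta_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(θ), S2(θ) for θ in degrees."""
    a, b = mie_coefficients(size_parameter, relative_index)
    N = a.size
    mu = np.cos(np.deg2rad(np.atleast_1d(theta_deg)))
    pi_n, tau_n = _pi_tau(mu, N)
    n = np.arange(1, N + 1, dtype=float)[:, None]
    w = (2 * n + 1) / (n * (n + 1))
    S1 = np.sum(w * (a[:, None] * pi_n + b[:, None] * tau_n), axis=0)
    S2 = np.sum(w * (a[:, None] * tau_n + b[:, None] * pi_n), axis=0)
    return S1, S2


def mie_mueller(size_parameter: float, relative_index: float | complex,
                theta_deg: np.ndarray) -> np.ndarray:
    """Single-scattering Mueller matrices, shape (len(theta), 4, 4).

    m11 is the (unnormalized) phase function; the matrix has the sphere
    block structure m12 = m21, m33 = m44, m34 = −m43.
    """
    S1, S2 = mie_S1S2(size_parameter, relative_index, theta_deg)
    m11 = 0.5 * (np.abs(S1) ** 2 + np.abs(S2) ** 2)
    m12 = 0.5 * (np.abs(S2) ** 2 - np.abs(S1) ** 2)
    m33 = (S1 * np.conj(S2)).real
    m34 = (S1 * np.conj(S2)).imag
    out = np.zeros(m11.shape + (4, 4))
    out[..., 0, 0] = m11
    out[..., 0, 1] = out[..., 1, 0] = m12
    out[..., 1, 1] = m11
    out[..., 2, 2] = out[..., 3, 3] = m33
    out[..., 2, 3] = m34
    out[..., 3, 2] = -m34
    return out


# ---------------------------------------------------------------------------
# Infinite cylinder at oblique incidence
# ---------------------------------------------------------------------------

def cylinder_coefficients(size_parameter: float, relative_index: float,
                          zeta_deg: float, nmax: int | None = None):
    """Series coefficients for an infinite cylinder tilted at ``zeta``.

    Returns (a_I, b_I, a_II, b_II) for n = 0..N.  Case I is the incident
    electric field parallel to the plane containing the incident direction
    and the cylinder axis; case II is perpendicular.  At normal incidence
    (ζ = 90°) the cross-polarizing coefficients a_I and b_II vanish.
    """
    x = float(size_parameter)
    if x <= 0:
        raise ValueError("size parameter must be positive")
    z = np.deg2rad(zeta_deg)
    if not 0.0 < zeta_deg <= 90.0:
        raise ValueError("zeta must lie in (0, 90] degrees")
    m = float(relative_index)
    xi = x * np.sin(z)
    eta = x * np.sqrt(m * m - np.cos(z) ** 2)
    N = nmax or int(np.ceil(xi + 4.05 * xi ** (1.0 / 3.0) + 2.0)) + 6

    n = np.arange(0, N + 1)
    Jx = special.jv(n, xi)
    Jxp = special.jvp(n, xi)
    Hx = special.hankel1(n, xi)
    Hxp = special.h1vp(n, xi)
    Je = special.jv(n, eta)
    Jep = special.jvp(n, eta)
    if not (np.all(np.isfinite(Jx)) and np.all(np.isfinite(np.abs(Hx)))):
        raise ArithmeticError("cylinder Bessel evaluation failed to converge")

    cosz = np.cos(z)
    A = 1j * xi * (xi * Jep * Jx - eta * Je * Jxp)
    B = xi * (m * m * xi * Jep * Jx - eta * Je * Jxp)
    C = n * cosz * eta * Je * Jx * ((xi / eta) ** 2 - 1.0)
    Dn = n * cosz * eta * Je * Hx * ((xi / eta) ** 2 - 1.0)
    V = xi * (m * m * xi * Jep * Hx - eta * Je * Hxp)
    W = 1j * xi * (eta * Je * Hxp - xi * Jep * Hx)

    den = W * V + 1j * Dn * Dn
    a_I = (C * V - B * Dn) / den
    b_I = (W * B + 1j * Dn * C) / den
    a_II = -(A * V - 1j * C * Dn) / den
    b_II = -1j * (C * W + A * Dn) / den
    return a_I, b_I, a_II, b_II


def cylinder_amplitudes(size_parameter: float, relative_index: float,
                        zeta_deg: float, Theta_deg: np.ndarray
                        ) -> np.ndarray:
    """2×2 complex amplitude matrices on the scattering cone.

    ``Theta`` is the azimuth around the cone (0 = forward).  Returns shape
    (len(Theta), 2, 2) mapping (E_parallel, E_perp) incident → scattered,
    i.e. [[T1, T4], [T3, T2]].
    """
    a_I, b_I, a_II, b_II = cylinder_coefficients(
        size_parameter, relative_index, zeta_deg
    )
    Th = np.deg2rad(np.atleast_1d(Theta_deg))
    N = a_I.size - 1
    n = np.arange(1, N + 1)[:, None]
    cosn = np.cos(n * Th[None, :])
    sinn = np.sin(n * Th[None, :])
    T1 = b_I[0] + 2.0 * np.sum(b_I[1:, None] * cosn, axis=0)
    T2 = a_II[0] + 2.0 * np.sum(a_II[1:, None] * cosn, axis=0)
    T3 = -2j * np.sum(a_I[1:, None] * sinn, axis=0)
    T4 = -2j * np.sum(b_II[1:, None] * sinn, axis=0)
    out = np.empty(Th.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = T1
    out[..., 0, 1] = T4
    out[..., 1, 0] = T3
    out[..., 1, 1] = T2
    return out


def cylinder_efficiencies(size_parameter: float, relative_index: float,
                          zeta_deg: float) -> dict[str, float]:
    """Extinction/scattering efficiencies per unit length for both cases."""
    x = float(size_parameter)
    a_I, b_I, a_II, b_II = cylinder_coefficients(x, relative_index, zeta_deg)
    qext_I = (2.0 / x) * (b_I[0] + 2.0 * np.sum(b_I[1:])).real
    qsca_I = (2.0 / x) * (
        np.abs(b_I[0]) ** 2
        + 2.0 * np.sum(np.abs(b_I[1:]) ** 2 + np.abs(a_I[1:]) ** 2)
    )
    qext_II = (2.0 / x) * (a_II[0] + 2.0 * np.sum(a_II[1:])).real
    qsca_II = (2.0 / x) * (
        np.abs(a_II[0]) ** 2
        + 2.0 * np.sum(np.abs(a_II[1:]) ** 2 + np.abs(b_II[1:]) ** 2)
    )
    return {
        "Qext_I": float(qext_I),
        "Qsca_I": float(qsca_I),
        "Qext_II": float(qext_II),
        "Qsca_II": float(qsca_II),
    }


_JONES_TO_MUELLER_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_JONES_TO_MUELLER_AINV = np.linalg.inv(_JONES_TO_MUELLER_A)


def amplitude_to_mueller(J: np.ndarray) -> np.ndarray:
    """Convert 2×2 complex amplitude matrices (..., 2, 2) to real Mueller (..., 4, 4).

    Uses M = A (J ⊗ J*) A⁻¹ with the Stokes basis (I, Q, U, V),
    Q = |E_parallel|² − |E_perp|².
    """
    J = np.asarray(J, dtype=complex)
    kron = np.einsum("...ij,...kl->...ikjl", J, np.conj(J))
    kron = kron.reshape(J.shape[:-2] + (4, 4))
    M = np.einsum("ij,...jk,kl->...il", _JONES_TO_MUELLER_A, kron, _JONES_TO_MUELLER_AINV)
    return M.real


# ---------------------------------------------------------------------------
# Lookup tables for the transport engine
# ---------------------------------------------------------------------------

@dataclass
class ScatteringLookup:
    """Precomputed sampling tables shared by the Monte Carlo kernel.

    Sphere block: scattering-angle grid, the Mueller matrix normalized by
    m11 at each angle, and the CDF of the (sin θ weighted) phase function.
    Cylinder block: tilt-angle × cone-azimuth grid of m11-normalized Mueller
    matrices and a per-tilt CDF over the azimuth.  Normalizing each event
    matrix by its own m11 makes the path matrix an unbiased importance-
    sampled estimate of the polarization transfer.
    """

    wavelength_nm: float
    medium_index: float
    # sphere tables
    sph_theta_rad: np.ndarray  # (Ns,)
    sph_cdf: np.ndarray  # (Ns,) CDF over theta
    sph_mm: np.ndarray  # (Ns, 4) -> m12/m11, m33/m11, m34/m11 stored [1:], m11 raw in [:,0]
    sph_g: float
    # cylinder tables
    cyl_zeta_rad: np.ndarray  # (Nz,)
    cyl_Theta_rad: np.ndarray  # (Nt,)
    cyl_cdf: np.ndarray  # (Nz, Nt) per-zeta CDF over Theta
    cyl_mm: np.ndarray  # (Nz, Nt, 4, 4) normalized by m11
    cyl_m11: np.ndarray  # (Nz, Nt) raw phase function
    #: per-zeta phase-weighted mean of (m12, m13, m14)/m11 — the ensemble
    #: diattenuation of one cylinder event (polarization-dependent gain)
    cyl_row0_avg: np.ndarray  # (Nz, 3)

    def sample_sphere_theta(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF sample of the sphere scattering angle (radians)."""
        idx = np.searchsorted(self.sph_cdf, np.asarray(u), side="left")
        idx = np.clip(idx, 1, self.sph_cdf.size - 1)
        c0, c1 = self.sph_cdf[idx - 1], self.sph_cdf[idx]
        t0, t1 = self.sph_theta_rad[idx - 1], self.sph_theta_rad[idx]
        frac = np.where(c1 > c0, (u - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
        return t0 + frac * (t1 - t0)


def _cdf_from_density(weights: np.ndarray) -> np.ndarray:
    c = np.cumsum(weights)
    if c[-1] <= 0:
        raise ValueError("phase function is identically zero")
    c /= c[-1]
    c[0] = 0.0 if weights.size > 1 else c[0]
    c[-1] = 1.0
    return c


@lru_cache(maxsize=8)
def _build_lookup_cached(key) -> ScatteringLookup:
    (sph_d, sph_n, cyl_d, cyl_n, wavelength_nm, medium_index,
     n_theta, n_zeta, n_Theta) = key
    lam_um = wavelength_nm / 1000.0 / medium_index  # wavelength in the medium
    m_sph = sph_n / medium_index
    m_cyl = cyl_n / medium_index
    x_sph = np.pi * sph_d / lam_um
    x_cyl = np.pi * cyl_d / lam_um

    theta = np.linspace(0.0, np.pi, n_theta)
    mm = mie_mueller(x_sph, m_sph, np.degrees(theta))
    m11 = mm[:, 0, 0]
    # CDF over theta with solid-angle weight sin(theta), trapezoid bins
    w = m11 * np.sin(theta)
    bin_w = 0.5 * (w[1:] + w[:-1])
    cdf = np.concatenate([[0.0], np.cumsum(bin_w)])
    cdf /= cdf[-1]
    sph_mm = np.empty((n_theta, 4))
    sph_mm[:, 0] = m11
    with np.errstate(divide="ignore", invalid="ignore"):
        sph_mm[:, 1] = np.where(m11 > 0, mm[:, 0, 1] / m11, 0.0)
        sph_mm[:, 2] = np.where(m11 > 0, mm[:, 2, 2] / m11, 0.0)
        sph_mm[:, 3] = np.where(m11 > 0, mm[:, 2, 3] / m11, 0.0)
    g = mie_asymmetry(x_sph, m_sph)

    zeta = np.deg2rad(np.linspace(90.0 / n_zeta, 90.0, n_zeta))
    Theta = np.linspace(0.0, 2.0 * np.pi, n_Theta, endpoint=False)
    cyl_mm = np.empty((n_zeta, n_Theta, 4, 4))
    cyl_m11 = np.empty((n_zeta, n_Theta))
    cyl_cdf = np.empty((n_zeta, n_Theta))
    cyl_row0_avg = np.empty((n_zeta, 3))
    for i, z in enumerate(zeta):
        J = cylinder_amplitudes(x_cyl, m_cyl, np.degrees(z), np.degrees(Theta))
        M = amplitude_to_mueller(J)
        p = M[:, 0, 0].copy()
        cyl_m11[i] = p
        with np.errstate(divide="ignore", invalid="ignore"):
            cyl_mm[i] = np.where(p[:, None, None] > 0, M / p[:, None, None], 0.0)
        cyl_cdf[i] = _cdf_from_density(p)
        cyl_row0_avg[i] = M[:, 0, 1:4].mean(axis=0) / p.mean()
    return ScatteringLookup(
        wavelength_nm=wavelength_nm,
        medium_index=medium_index,
        sph_theta_rad=theta,
        sph_cdf=cdf,
        sph_mm=sph_mm,
        sph_g=g,
        cyl_zeta_rad=zeta,
        cyl_Theta_rad=Theta,
        cyl_cdf=cyl_cdf,
        cyl_mm=cyl_mm,
        cyl_m11=cyl_m11,
        cyl_row0_avg=cyl_row0_avg,
    )


def build_lookup(
    sphere: SpherePopulation,
    cylinder: CylinderPopulation,
    wavelength_nm: float = 632.0,
    medium_index: float = 1.33,
    *,
    n_theta: int = 1800,
    n_zeta: int = 180,
    n_Theta: int = 720,
) -> ScatteringLookup:
    """Build (or fetch cached) sampling tables for the given populations.

    Deterministic given the population/geometry parameters; cached in-memory
    keyed on them.
    """
    if sphere is None and cylinder is None:
        raise ValueError("at least one scatterer population is required")
    sphere = sphere or SpherePopulation()
    cylinder = cylinder or CylinderPopulation()
    key = (
        sphere.diameter_um, sphere.refractive_index,
        cylinder.diameter_um, cylinder.refractive_index,
        float(wavelength_nm), float(medium_index),
        int(n_theta), int(n_zeta), int(n_Theta),
    )
    return _build_lookup_cached(key)
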