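"""Numba transport kernel for the sphere-cylinder-birefringence Monte Carlo.

Per-photon state: position depth z, direction u, polarization reference
vector m (the local Stokes Q axis, kept perpendicular to u), and the 4×4
cumulative path matrix P.  Every optical interaction left-multiplies P:

* frame rotations R(phi) when re-referencing the Stokes basis,
* the m11-normalized single-scattering Mueller matrix of the sampled event
  (importance sampling from the unpolarized phase function makes P an
  unbiased estimate of the trajectory's polarization transfer),
* a linear retarder per propagation segment for the uniaxial birefringent
  interstitial medium.

The kernel is single-threaded and seeds NumPy's legacy RNG once, so runs
are bit-reproducible for a given configuration and seed.
"""

import numpy as np
from numba import njit

# outcome codes
DETECTED = 0
TOP_REJECT = 1
BOTTOM_EXIT = 2
TERMINATED = 3


@njit(cache=True)
def _apply_rotation(P, phi):
    """P <- R(phi) @ P; R rotates (Q, U) by 2*phi (frame re-reference)."""
    c = np.cos(2.0 * phi)
    s = np.sin(2.0 * phi)
    for j in range(4):
        q = P[1, j]
        u = P[2, j]
        P[1, j] = c * q + s * u
        P[2, j] = -s * q + c * u


@njit(cache=True)
def _apply_retarder(P, delta):
    """P <- Ret(delta, axis 0) @ P; rotates (U, V) by delta."""
    cd = np.cos(delta)
    sd = np.sin(delta)
    for j in range(4):
        u = P[2, j]
        v = P[3, j]
        P[2, j] = cd * u - sd * v
        P[3, j] = sd * u + cd * v


@njit(cache=True)
def _apply_sphere_block(P, r12, r33, r34):
    """P <- (M_mie / m11) @ P using the sphere block structure."""
    for j in range(4):
        i0 = P[0, j]
        q0 = P[1, j]
        P[0, j] = i0 + r12 * q0
        P[1, j] = r12 * i0 + q0
        u0 = P[2, j]
        v0 = P[3, j]
        P[2, j] = r33 * u0 + r34 * v0
        P[3, j] = -r34 * u0 + r33 * v0


@njit(cache=True)
def _apply_matrix(P, M, tmp):
    """P <- M @ P with a scratch buffer."""
    for i in range(4):
        for j in range(4):
            acc = 0.0
            for k in range(4):
                acc += M[i, k] * P[k, j]
            tmp[i, j] = acc
    for i in range(4):
        for j in range(4):
            P[i, j] = tmp[i, j]


@njit(cache=True)
def _apply_birefringence(P, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm):
    """Uniaxial retardance over a straight segment of length seg (cm).

    Effective birefringence dn*sin^2(psi) for angle psi between propagation
    and the optic axis; retarder axis is the optic-axis projection
    perpendicular to the direction of flight.
    """
    if dn <= 0.0 or seg <= 0.0:
        return
    cospsi = u[0] * axis_x + u[1] * axis_y + u[2] * axis_z
    sin2 = 1.0 - cospsi * cospsi
    if sin2 < 1e-12:
        return
    dneff = dn * sin2
    phi_r = 2.0 * np.pi * dneff * seg / lam_cm
    inv = 1.0 / np.sqrt(sin2)
    fx = (axis_x - cospsi * u[0]) * inv
    fy = (axis_y - cospsi * u[1]) * inv
    fz = (axis_z - cospsi * u[2]) * inv
    cosf = m[0] * fx + m[1] * fy + m[2] * fz
    sinf = n[0] * fx + n[1] * fy + n[2] * fz
    phi_f = np.arctan2(sinf, cosf)
    _apply_rotation(P, phi_f)
    _apply_retarder(P, phi_r)
    _apply_rotation(P, -phi_f)


@njit(cache=True)
def _cross_into(out, a, b):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True)
def _normalize3(v):
    s = 1.0 / np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    v[0] *= s
    v[1] *= s
    v[2] *= s


@njit(cache=True)
def _fresnel_unpolarized(cosi, n_med):
    """Unpolarized reflectance at the medium->air interface (n_med -> 1)."""
    sini = np.sqrt(max(0.0, 1.0 - cosi * cosi))
    sint = n_med * sini
    if sint >= 1.0:
        return 1.0
    cost = np.sqrt(1.0 - sint * sint)
    rs = (n_med * cosi - cost) / (n_med * cosi + cost)
    rp = (cosi - n_med * cost) / (cosi + n_med * cost)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _sample_sphere_theta(cdf, theta, r):
    idx = np.searchsorted(cdf, r)
    if idx < 1:
        idx = 1
    if idx > cdf.size - 1:
        idx = cdf.size - 1
    c0 = cdf[idx - 1]
    c1 = cdf[idx]
    frac = 0.0
    if c1 > c0:
        frac = (r - c0) / (c1 - c0)
    return theta[idx - 1] + frac * (theta[idx] - theta[idx - 1]), idx


@njit(cache=True)
def transport(
    n_photons,
    seed,
    # geometry
    u0x, u0z,            # launch direction (y component is 0)
    thickness,
    n_med,
    mus_total,
    p_sphere,
    cos_accept_internal,  # min |uz| inside the slab for detector acceptance
    # birefringence
    dn, axis_x, axis_y, axis_z, lam_cm,
    # cylinder axis distribution
    cyl_mean_axis, cyl_sigma,
    # sphere tables
    sph_theta, sph_cdf, sph_r12, sph_r33, sph_r34,
    # cylinder tables
    cyl_zeta, cyl_Theta, cyl_cdf, cyl_mm,
    # controls
    max_events,
    n_batches,
):
    """Trace photons through the slab; returns batch Mueller sums and a budget.

    Budget array: [detected, top_rejected, bottom_exit, terminated]; the four
    counts add up to n_photons exactly.
    """
    np.random.seed(seed)
    batch_sums = np.zeros((n_batches, 4, 4))
    batch_counts = np.zeros(n_batches, dtype=np.int64)
    budget = np.zeros(4, dtype=np.int64)

    P = np.empty((4, 4))
    tmp = np.empty((4, 4))
    u = np.empty(3)
    m = np.empty(3)
    n = np.empty(3)
    a = np.empty(3)
    bvec = np.empty(3)
    cvec = np.empty(3)
    pvec = np.empty(3)
    uold = np.empty(3)
    tdet = np.empty(3)

    nz_grid = cyl_zeta.size
    dzeta = cyl_zeta[1] - cyl_zeta[0]
    nt_grid = cyl_Theta.size
    dTheta = cyl_Theta[1] - cyl_Theta[0]

    for i in range(n_photons):
        # launch at the top surface, already refracted into the medium
        u[0] = u0x
        u[1] = 0.0
        u[2] = u0z
        # reference vector: p-direction of the incidence plane
        m[0] = u0z
        m[1] = 0.0
        m[2] = -u0x
        _cross_into(n, u, m)
        for r_ in range(4):
            for c_ in range(4):
                P[r_, c_] = 1.0 if r_ == c_ else 0.0
        z = 0.0
        events = 0
        outcome = -1

        while True:
            step = -np.log(np.random.random()) / mus_total
            znew = z + u[2] * step
            if znew < 0.0:
                seg = -z / u[2] if u[2] != 0.0 else 0.0
                _apply_birefringence(P, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm)
                z = 0.0
                cosi = -u[2]
                refl = _fresnel_unpolarized(cosi, n_med)
                if np.random.random() < refl:
                    # specular/total internal reflection at the top interface
                    u[2] = -u[2]
                    m[2] = -m[2]
                    _cross_into(n, u, m)
                    continue
                if cosi >= cos_accept_internal:
                    outcome = DETECTED
                else:
                    outcome = TOP_REJECT
                break
            elif znew > thickness:
                seg = (thickness - z) / u[2]
                _apply_birefringence(P, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm)
                outcome = BOTTOM_EXIT
                break
            else:
                _apply_birefringence(P, u, m, n, step, dn, axis_x, axis_y, axis_z, lam_cm)
                z = znew
                events += 1
                if events > max_events:
                    outcome = TERMINATED
                    break
                if np.random.random() < p_sphere:
                    # --- sphere event ---
                    phi = 2.0 * np.pi * np.random.random()
                    cph = np.cos(phi)
                    sph = np.sin(phi)
                    # scattering-plane direction
                    for k in range(3):
                        pvec[k] = cph * m[k] + sph * n[k]
                    _apply_rotation(P, phi)
                    th, idx = _sample_sphere_theta(sph_cdf, sph_theta, np.random.random())
                    # interpolate matrix entries linearly in theta
                    t0 = sph_theta[idx - 1]
                    t1 = sph_theta[idx]
                    w = 0.0
                    if t1 > t0:
                        w = (th - t0) / (t1 - t0)
                    r12 = sph_r12[idx - 1] * (1.0 - w) + sph_r12[idx] * w
                    r33 = sph_r33[idx - 1] * (1.0 - w) + sph_r33[idx] * w
                    r34 = sph_r34[idx - 1] * (1.0 - w) + sph_r34[idx] * w
                    _apply_sphere_block(P, r12, r33, r34)
                    ct = np.cos(th)
                    st = np.sin(th)
                    for k in range(3):
                        uold[k] = u[k]
                    for k in range(3):
                        u[k] = ct * uold[k] + st * pvec[k]
                        m[k] = ct * pvec[k] - st * uold[k]
                    _normalize3(u)
                    _normalize3(m)
                    _cross_into(n, u, m)
                else:
                    # --- cylinder event ---
                    cosZ = 1.0
                    for _try in range(64):
                        psi = cyl_mean_axis + cyl_sigma * np.random.standard_normal()
                        a[0] = np.cos(psi)
                        a[1] = np.sin(psi)
                        a[2] = 0.0
                        cosZ = u[0] * a[0] + u[1] * a[1]
                        if np.abs(cosZ) < 0.999999:
                            break
                    if np.abs(cosZ) >= 0.999999:
                        continue  # degenerate geometry; skip the event
                    if cosZ < 0.0:
                        a[0] = -a[0]
                        a[1] = -a[1]
                        cosZ = -cosZ
                    sinZ = np.sqrt(1.0 - cosZ * cosZ)
                    invs = 1.0 / sinZ
                    for k in range(3):
                        bvec[k] = (u[k] - cosZ * a[k]) * invs
                    _cross_into(cvec, a, bvec)
                    # incident parallel basis vector (in the u-axis plane)
                    for k in range(3):
                        pvec[k] = (a[k] - cosZ * u[k]) * invs
                    cosf = m[0] * pvec[0] + m[1] * pvec[1] + m[2] * pvec[2]
                    sinf = n[0] * pvec[0] + n[1] * pvec[1] + n[2] * pvec[2]
                    _apply_rotation(P, np.arctan2(sinf, cosf))
                    # tilt-angle table row
                    zeta = np.arccos(cosZ)
                    iz = int(np.floor(zeta / dzeta + 0.5)) - 1
                    if iz < 0:
                        iz = 0
                    if iz > nz_grid - 1:
                        iz = nz_grid - 1
                    # sample cone azimuth Theta from the per-tilt CDF
                    r = np.random.random()
                    row = cyl_cdf[iz]
                    jt = np.searchsorted(row, r)
                    if jt > nt_grid - 1:
                        jt = nt_grid - 1
                    Theta = cyl_Theta[jt] + (np.random.random() - 0.5) * dTheta
                    cT = np.cos(Theta)
                    sT = np.sin(Theta)
                    for k in range(3):
                        u[k] = cosZ * a[k] + sinZ * (cT * bvec[k] + sT * cvec[k])
                    _normalize3(u)
                    _apply_matrix(P, cyl_mm[iz, jt], tmp)
                    # outgoing parallel basis
                    for k in range(3):
                        m[k] = (a[k] - cosZ * u[k]) * invs
                    _normalize3(m)
                    _cross_into(n, u, m)

        budget[outcome] += 1
        if outcome == DETECTED:
            # re-reference the Stokes frame to the detector x-axis
            dotux = u[0]
            tdet[0] = 1.0 - dotux * u[0]
            tdet[1] = -dotux * u[1]
            tdet[2] = -dotux * u[2]
            _normalize3(tdet)
            cosf = m[0] * tdet[0] + m[1] * tdet[1] + m[2] * tdet[2]
            sinf = n[0] * tdet[0] + n[1] * tdet[1] + n[2] * tdet[2]
            _apply_rotation(P, np.arctan2(sinf, cosf))
            # lab-fixed detection convention: the backscattered Stokes vector
            # is referenced to the lab axes as for forward propagation, so a
            # specular-like return is the identity ("air" calibrates to
            # identity); flips U and V of the beam-referenced output
            for c_ in range(4):
                P[2, c_] = -P[2, c_]
                P[3, c_] = -P[3, c_]
            bi = i * n_batches // n_photons
            for r_ in range(4):
                for c_ in range(4):
                    batch_sums[bi, r_, c_] += P[r_, c_]
            batch_counts[bi] += 1

    return batch_sums, batch_counts, budget


# ---------------------------------------------------------------------------
# Stokes basis-state transport (default estimator)
# ---------------------------------------------------------------------------
#
# One photon carries a unit-intensity Stokes vector s = (1, q, u, v) and a
# scalar weight.  Scattering angles are drawn from the polarized intensity
# (rejection on top of the unpolarized tables), after which s is renormalized
# to unit intensity; detected contributions are therefore bounded
# (|q|, |u|, |v| <= 1), which is what lets small anisotropy signals such as
# the isotropy null be resolved.  The sample Mueller matrix is assembled
# from four input states (H, V, +45 deg, right-circular).


@njit(cache=True)
def _vec_rotate(s, phi):
    c = np.cos(2.0 * phi)
    sn = np.sin(2.0 * phi)
    q = s[1]
    u = s[2]
    s[1] = c * q + sn * u
    s[2] = -sn * q + c * u


@njit(cache=True)
def _vec_retard(s, delta):
    cd = np.cos(delta)
    sd = np.sin(delta)
    u = s[2]
    v = s[3]
    s[2] = cd * u - sd * v
    s[3] = sd * u + cd * v


@njit(cache=True)
def _vec_biref(s, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm):
    if dn <= 0.0 or seg <= 0.0:
        return
    cospsi = u[0] * axis_x + u[1] * axis_y + u[2] * axis_z
    sin2 = 1.0 - cospsi * cospsi
    if sin2 < 1e-12:
        return
    phi_r = 2.0 * np.pi * dn * sin2 * seg / lam_cm
    inv = 1.0 / np.sqrt(sin2)
    fx = (axis_x - cospsi * u[0]) * inv
    fy = (axis_y - cospsi * u[1]) * inv
    fz = (axis_z - cospsi * u[2]) * inv
    cosf = m[0] * fx + m[1] * fy + m[2] * fz
    sinf = n[0] * fx + n[1] * fy + n[2] * fz
    phi_f = np.arctan2(sinf, cosf)
    _vec_rotate(s, phi_f)
    _vec_retard(s, phi_r)
    _vec_rotate(s, -phi_f)


@njit(cache=True)
def transport_stokes(
    n_photons,            # photons per input state
    seed,
    s_in_q, s_in_u, s_in_v,  # input polarization (I = 1)
    u0x, u0z,
    thickness,
    n_med,
    mus_total,
    p_sphere,
    cos_accept_internal,
    dn, axis_x, axis_y, axis_z, lam_cm,
    cyl_mean_axis, cyl_sigma,
    sph_theta, sph_cdf, sph_r12, sph_r33, sph_r34,
    cyl_zeta, cyl_Theta, cyl_cdf, cyl_mm, cyl_row0_avg,
    max_events,
    n_batches,
):
    """Trace one input polarization state; returns batch Stokes sums + budget."""
    np.random.seed(seed)
    batch_sums = np.zeros((n_batches, 4))
    batch_counts = np.zeros(n_batches, dtype=np.int64)
    budget = np.zeros(4, dtype=np.int64)

    s = np.empty(4)
    snew = np.empty(4)
    u = np.empty(3)
    m = np.empty(3)
    n = np.empty(3)
    a = np.empty(3)
    bvec = np.empty(3)
    cvec = np.empty(3)
    pvec = np.empty(3)
    uold = np.empty(3)
    tdet = np.empty(3)

    nz_grid = cyl_zeta.size
    dzeta = cyl_zeta[1] - cyl_zeta[0]
    nt_grid = cyl_Theta.size
    dTheta = cyl_Theta[1] - cyl_Theta[0]

    for i in range(n_photons):
        u[0] = u0x
        u[1] = 0.0
        u[2] = u0z
        m[0] = u0z
        m[1] = 0.0
        m[2] = -u0x
        _cross_into(n, u, m)
        s[0] = 1.0
        s[1] = s_in_q
        s[2] = s_in_u
        s[3] = s_in_v
        w = 1.0
        z = 0.0
        events = 0
        outcome = -1

        while True:
            step = -np.log(np.random.random()) / mus_total
            znew = z + u[2] * step
            if znew < 0.0:
                seg = -z / u[2] if u[2] != 0.0 else 0.0
                _vec_biref(s, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm)
                z = 0.0
                cosi = -u[2]
                refl = _fresnel_unpolarized(cosi, n_med)
                if np.random.random() < refl:
                    u[2] = -u[2]
                    m[2] = -m[2]
                    _cross_into(n, u, m)
                    continue
                if cosi >= cos_accept_internal:
                    outcome = DETECTED
                else:
                    outcome = TOP_REJECT
                break
            elif znew > thickness:
                seg = (thickness - z) / u[2]
                _vec_biref(s, u, m, n, seg, dn, axis_x, axis_y, axis_z, lam_cm)
                outcome = BOTTOM_EXIT
                break
            else:
                _vec_biref(s, u, m, n, step, dn, axis_x, axis_y, axis_z, lam_cm)
                z = znew
                events += 1
                if events > max_events:
                    outcome = TERMINATED
                    break
                if np.random.random() < p_sphere:
                    # --- sphere event ---
                    th, idx = _sample_sphere_theta(sph_cdf, sph_theta, np.random.random())
                    t0 = sph_theta[idx - 1]
                    t1 = sph_theta[idx]
                    wgt = 0.0
                    if t1 > t0:
                        wgt = (th - t0) / (t1 - t0)
                    r12 = sph_r12[idx - 1] * (1.0 - wgt) + sph_r12[idx] * wgt
                    r33 = sph_r33[idx - 1] * (1.0 - wgt) + sph_r33[idx] * wgt
                    r34 = sph_r34[idx - 1] * (1.0 - wgt) + sph_r34[idx] * wgt
                    # conditional azimuth: density ∝ 1 + r12 (q cos2φ + u sin2φ)
                    rho = np.sqrt(s[1] * s[1] + s[2] * s[2])
                    env = 1.0 + np.abs(r12) * rho
                    phi = 0.0
                    for _rej in range(1000):
                        phi = 2.0 * np.pi * np.random.random()
                        c2 = np.cos(2.0 * phi)
                        s2 = np.sin(2.0 * phi)
                        gain = 1.0 + r12 * (s[1] * c2 + s[2] * s2)
                        if np.random.random() * env <= gain:
                            break
                    cph = np.cos(phi)
                    sph_ = np.sin(phi)
                    for k in range(3):
                        pvec[k] = cph * m[k] + sph_ * n[k]
                    _vec_rotate(s, phi)
                    # apply M/m11 and renormalize to unit intensity
                    gain = 1.0 + r12 * s[1]
                    snew[0] = 1.0
                    snew[1] = (r12 * s[0] + s[1]) / gain
                    snew[2] = (r33 * s[2] + r34 * s[3]) / gain
                    snew[3] = (-r34 * s[2] + r33 * s[3]) / gain
                    for k in range(4):
                        s[k] = snew[k]
                    ct = np.cos(th)
                    st = np.sin(th)
                    for k in range(3):
                        uold[k] = u[k]
                    for k in range(3):
                        u[k] = ct * uold[k] + st * pvec[k]
                        m[k] = ct * pvec[k] - st * uold[k]
                    _normalize3(u)
                    _normalize3(m)
                    _cross_into(n, u, m)
                else:
                    # --- cylinder event ---
                    cosZ = 1.0
                    for _try in range(64):
                        psi = cyl_mean_axis + cyl_sigma * np.random.standard_normal()
                        a[0] = np.cos(psi)
                        a[1] = np.sin(psi)
                        a[2] = 0.0
                        cosZ = u[0] * a[0] + u[1] * a[1]
                        if np.abs(cosZ) < 0.999999:
                            break
                    if np.abs(cosZ) >= 0.999999:
                        continue
                    if cosZ < 0.0:
                        a[0] = -a[0]
                        a[1] = -a[1]
                        cosZ = -cosZ
                    sinZ = np.sqrt(1.0 - cosZ * cosZ)
                    invs = 1.0 / sinZ
                    for k in range(3):
                        bvec[k] = (u[k] - cosZ * a[k]) * invs
                    _cross_into(cvec, a, bvec)
                    for k in range(3):
                        pvec[k] = (a[k] - cosZ * u[k]) * invs
                    cosf = m[0] * pvec[0] + m[1] * pvec[1] + m[2] * pvec[2]
                    sinf = n[0] * pvec[0] + n[1] * pvec[1] + n[2] * pvec[2]
                    _vec_rotate(s, np.arctan2(sinf, cosf))
                    zeta = np.arccos(cosZ)
                    iz = int(np.floor(zeta / dzeta + 0.5)) - 1
                    if iz < 0:
                        iz = 0
                    if iz > nz_grid - 1:
                        iz = nz_grid - 1
                    # conditional cone azimuth: accept ∝ polarized gain
                    jt = 0
                    gain = 1.0
                    for _rej in range(1000):
                        r = np.random.random()
                        row = cyl_cdf[iz]
                        jt = np.searchsorted(row, r)
                        if jt > nt_grid - 1:
                            jt = nt_grid - 1
                        gain = (
                            1.0
                            + cyl_mm[iz, jt, 0, 1] * s[1]
                            + cyl_mm[iz, jt, 0, 2] * s[2]
                            + cyl_mm[iz, jt, 0, 3] * s[3]
                        )
                        if np.random.random() * 2.0 <= gain:
                            break
                    # event-averaged polarized gain (ensemble diattenuation)
                    w *= (
                        1.0
                        + cyl_row0_avg[iz, 0] * s[1]
                        + cyl_row0_avg[iz, 1] * s[2]
                        + cyl_row0_avg[iz, 2] * s[3]
                    )
                    Theta = cyl_Theta[jt] + (np.random.random() - 0.5) * dTheta
                    cT = np.cos(Theta)
                    sT = np.sin(Theta)
                    for k in range(3):
                        u[k] = cosZ * a[k] + sinZ * (cT * bvec[k] + sT * cvec[k])
                    _normalize3(u)
                    snew[0] = 1.0
                    for r_ in range(1, 4):
                        acc = 0.0
                        for k in range(4):
                            acc += cyl_mm[iz, jt, r_, k] * s[k]
                        snew[r_] = acc / gain
                    for k in range(4):
                        s[k] = snew[k]
                    for k in range(3):
                        m[k] = (a[k] - cosZ * u[k]) * invs
                    _normalize3(m)
                    _cross_into(n, u, m)

        budget[outcome] += 1
        if outcome == DETECTED:
            dotux = u[0]
            tdet[0] = 1.0 - dotux * u[0]
            tdet[1] = -dotux * u[1]
            tdet[2] = -dotux * u[2]
            _normalize3(tdet)
            cosf = m[0] * tdet[0] + m[1] * tdet[1] + m[2] * tdet[2]
            sinf = n[0] * tdet[0] + n[1] * tdet[1] + n[2] * tdet[2]
            _vec_rotate(s, np.arctan2(sinf, cosf))
            # lab-fixed detection convention (see transport): flip U and V
            s[2] = -s[2]
            s[3] = -s[3]
            bi = i * n_batches // n_photons
            batch_sums[bi, 0] += w * s[0]
            batch_sums[bi, 1] += w * s[1]
            batch_sums[bi, 2] += w * s[2]
            batch_sums[bi, 3] += w * s[3]
            batch_counts[bi] += 1

    return batch_sums, batch_counts, budget
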