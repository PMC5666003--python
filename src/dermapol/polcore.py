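"""Stokes–Mueller algebra and the Mueller-matrix-transformation (MMT) parameters.

The Mueller matrix of a sample maps incident Stokes vectors ``(I, Q, U, V)``
to outgoing ones.  For fibrous tissue the four linear-polarization elements
``m22, m23, m32, m33`` carry most of the anisotropy signal; the MMT
parameters condense them into two rotation-insensitive scalars:

* ``A`` — degree of anisotropy in ``[0, 1]``; with
  ``b = (m22 + m33)/2`` and ``t = sqrt((m22 − m33)² + (m23 + m32)²)/2``,
  ``A = 2·b·t / (b² + t²)``.
* ``α`` — fibre-orientation angle, ``α = atan2(m23 + m32, m22 − m33)``
  wrapped into ``(−90°, 90°]``.  For a pure linear retarder with its axis at
  ``θ``, ``α = 4θ`` (wrapped); the fibre orientation is ``x = α/4``.

Conventions used throughout the package
---------------------------------------
* Stokes vectors are right-handed with ``V > 0`` meaning right-circular.
* The retarder sign convention is fixed by
  ``linear_retarder(90, 0) @ (1,0,0,1) == (1,0,-1,0)``.
* Frame rotation by ``phi`` acts on ``(Q, U)`` with angle ``2·phi``.

All functions accept stacked matrices with shape ``(..., 4, 4)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: element-wise tolerance for analytic identities
ANALYTIC_TOL = 1e-9
#: angular tolerance (degrees) for orientation identities
ANGLE_TOL_DEG = 1e-6

_CARDINAL_STOKES = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, -1.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0, -1.0],
    ]
)


class DegenerateMatrixError(ValueError):
    """Raised for Mueller matrices with non-positive total intensity gain."""


def stokes_rotation(phi_deg: float) -> np.ndarray:
    """Stokes frame-rotation matrix R(phi); acts on (Q, U) with angle 2*phi."""
    p = 2.0 * np.deg2rad(phi_deg)
    c, s = np.cos(p), np.sin(p)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def rotate_sample_frame(M: np.ndarray, phi_deg: float) -> np.ndarray:
    """Return R(−phi) · M · R(phi): the matrix of the same sample rotated by phi.

    A linear retarder with axis ``θ`` rotated by ``phi`` equals the retarder
    built directly at ``θ + phi``.
    """
    return stokes_rotation(-phi_deg) @ np.asarray(M) @ stokes_rotation(phi_deg)


def normalize_by_m11(M: np.ndarray) -> np.ndarray:
    """Divide all 16 elements by m11 so that the result has m11 = 1."""
    M = np.asarray(M, dtype=float)
    m11 = M[..., 0, 0]
    if np.any(m11 <= 0):
        raise DegenerateMatrixError("m11 must be positive to normalize")
    return M / m11[..., None, None]


def mmt_A(M: np.ndarray) -> np.ndarray | float:
    """Anisotropy parameter A ∈ [0, 1] from the m22/m23/m32/m33 block.

    Returns 0 by convention where both ``b`` and ``t`` vanish (isotropic
    pixel).  Input must be m11-normalized.
    """
    M = np.asarray(M, dtype=float)
    b = 0.5 * (M[..., 1, 1] + M[..., 2, 2])
    t = 0.5 * np.hypot(M[..., 1, 1] - M[..., 2, 2], M[..., 1, 2] + M[..., 2, 1])
    denom = b * b + t * t
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, 2.0 * np.abs(b) * t / np.where(denom > 0, denom, 1.0), 0.0)
    if A.ndim == 0:
        return float(A)
    return A


def wrap_alpha(alpha_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap an orientation angle (period 180°) into (−90°, 90°]."""
    w = np.mod(np.asarray(alpha_deg, dtype=float), 180.0)
    out = np.where(w > 90.0, w - 180.0, w)
    if out.ndim == 0:
        return float(out)
    return out


def mmt_alpha(M: np.ndarray, *, degenerate_tol: float = 0.0) -> np.ndarray | float:
    """Orientation parameter α = atan2(m23+m32, m22−m33) in (−90°, 90°].

    Pixels where both arguments are ≤ ``degenerate_tol`` in magnitude have no
    defined orientation and return NaN.
    """
    M = np.asarray(M, dtype=float)
    y = M[..., 1, 2] + M[..., 2, 1]
    x = M[..., 1, 1] - M[..., 2, 2]
    alpha = wrap_alpha(np.degrees(np.arctan2(y, x)))
    undefined = (np.abs(x) <= degenerate_tol) & (np.abs(y) <= degenerate_tol)
    alpha = np.where(undefined, np.nan, alpha)
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


def linear_retarder(retardance_deg: float, axis_deg: float = 0.0) -> np.ndarray:
    """Mueller matrix of a linear retarder (retardance δ, fast axis at θ).

    At θ = 0 the (U, V) block is ``[[cos δ, −sin δ], [sin δ, cos δ]]`` so that
    ``retarder(90, 0) @ (1,0,0,1) = (1,0,−1,0)``.
    """
    d = np.deg2rad(retardance_deg)
    M0 = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, np.cos(d), -np.sin(d)],
            [0.0, 0.0, np.sin(d), np.cos(d)],
        ]
    )
    if axis_deg == 0.0:
        return M0
    return rotate_sample_frame(M0, axis_deg)


def linear_diattenuator(diattenuation: float, axis_deg: float = 0.0) -> np.ndarray:
    """Normalized linear diattenuator (d ∈ [0, 1]); d = 1 is an ideal polarizer."""
    if not 0.0 <= diattenuation <= 1.0:
        raise ValueError(f"diattenuation must be in [0, 1], got {diattenuation}")
    d = diattenuation
    r = np.sqrt(max(1.0 - d * d, 0.0))
    M0 = np.array(
        [
            [1.0, d, 0.0, 0.0],
            [d, 1.0, 0.0, 0.0],
            [0.0, 0.0, r, 0.0],
            [0.0, 0.0, 0.0, r],
        ]
    )
    if axis_deg == 0.0:
        return M0
    return rotate_sample_frame(M0, axis_deg)


def isotropic_depolarizer(depolarization: float) -> np.ndarray:
    """diag(1, 1−d, 1−d, 1−d); d = 1 is a perfect depolarizer."""
    if not 0.0 <= depolarization <= 1.0:
        raise ValueError(f"depolarization must be in [0, 1], got {depolarization}")
    p = 1.0 - depolarization
    return np.diag([1.0, p, p, p])


def build_element(kind: str, **params) -> np.ndarray:
    """Build a canonical optical element by name.

    kinds: ``linear_retarder(retardance_deg, axis_deg)``,
    ``linear_diattenuator(diattenuation, axis_deg)``,
    ``isotropic_depolarizer(depolarization)``.
    """
    builders = {
        "linear_retarder": linear_retarder,
        "linear_diattenuator": linear_diattenuator,
        "isotropic_depolarizer": isotropic_depolarizer,
    }
    try:
        builder = builders[kind]
    except KeyError:
        raise ValueError(f"unknown element kind {kind!r}; choose from {sorted(builders)}")
    return builder(**params)


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_physical(M: np.ndarray, tol: float = ANALYTIC_TOL) -> ValidationReport:
    """Check basic physicality of a Mueller matrix.

    Verifies m11 > 0, |mij/m11| ≤ 1 + tol, and that the six cardinal
    fully-polarized states map to Stokes vectors with I ≥ |(Q,U,V)| − tol.
    """
    M = np.asarray(M, dtype=float)
    messages: list[str] = []
    m11 = M[0, 0]
    if not m11 > 0:
        return ValidationReport(False, [f"m11 = {m11} is not positive"])
    Mn = M / m11
    bad = np.argwhere(np.abs(Mn) > 1.0 + tol)
    for i, j in bad:
        messages.append(f"|m{i + 1}{j + 1}|/m11 = {abs(Mn[i, j]):.6g} exceeds 1")
    out = _CARDINAL_STOKES @ Mn.T
    dop_excess = np.linalg.norm(out[:, 1:], axis=1) - out[:, 0]
    for k in np.nonzero(dop_excess > tol)[0]:
        messages.append(
            f"cardinal state {k} over-polarized by {dop_excess[k]:.3g}"
        )
    return ValidationReport(len(messages) == 0, messages)
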