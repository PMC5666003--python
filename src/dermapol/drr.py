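"""Dual-rotating-retarder (DRR) polarimeter forward model and reconstruction.

The instrument is the classic backscattering DRR arrangement: unpolarized
source → horizontal polarizer P1 → rotating quarter-wave retarder R1 →
sample → rotating quarter-wave retarder R2 → horizontal polarizer P2 →
detector.  The two retarders advance at a fixed 5:1 rate ratio and thirty
intensity frames are recorded; the slow retarder steps by 6° per frame so
the schedule spans 180°.

Recovery of the 16 Mueller elements uses least squares on the 30×16 design
matrix whose k-th row is the outer product of the analyzer row vector and
the generator Stokes vector at step k.  This is exact for any full-rank
schedule and indifferent to which retarder is the fast one.  Half-wave
retarders make the design rank-deficient (rank 9) and are rejected with a
conditioning error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import polcore

_P_HORIZ = 0.5 * np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ]
)
_S_UNPOL = np.array([1.0, 0.0, 0.0, 0.0])


class ConditioningError(ValueError):
    """Raised when the DRR design matrix is rank-deficient."""


@dataclass(frozen=True)
class DRRConfig:
    """Measurement schedule of the dual-rotating-retarder polarimeter.

    ``rate_ratio = 5`` means the fast retarder advances five times the slow
    one per frame; ``fast_generator`` selects whether R1 (generator arm) or
    R2 (analyzer arm) is the fast one.  ``oblique_angle_deg`` is the
    incidence tilt used to reject specular reflection (metadata only).
    """

    n_steps: int = 30
    step_increment_deg: float = 6.0
    rate_ratio: int = 5
    retardance1_deg: float = 90.0
    retardance2_deg: float = 90.0
    fast_generator: bool = True
    oblique_angle_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.n_steps < 16:
            raise ValueError("need at least 16 steps to recover 16 elements")

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Retarder axis angles (theta1, theta2) in degrees for each frame."""
        k = np.arange(self.n_steps, dtype=float)
        slow = k * self.step_increment_deg
        fast = self.rate_ratio * slow
        return (fast, slow) if self.fast_generator else (slow, fast)


def generator_states(config: DRRConfig) -> np.ndarray:
    """Stokes vectors illuminating the sample at each step, shape (n, 4)."""
    th1, _ = config.angles()
    out = np.empty((config.n_steps, 4))
    for k in range(config.n_steps):
        R1 = polcore.linear_retarder(config.retardance1_deg, th1[k])
        out[k] = R1 @ _P_HORIZ @ _S_UNPOL
    return out


def analyzer_rows(config: DRRConfig) -> np.ndarray:
    """Detector projection row vectors at each step, shape (n, 4)."""
    _, th2 = config.angles()
    out = np.empty((config.n_steps, 4))
    for k in range(config.n_steps):
        R2 = polcore.linear_retarder(config.retardance2_deg, th2[k])
        out[k] = (_P_HORIZ @ R2)[0]
    return out


def design_matrix(config: DRRConfig) -> np.ndarray:
    """(n_steps, 16) matrix D with I = D @ M.ravel()."""
    g = generator_states(config)
    a = analyzer_rows(config)
    return np.einsum("ki,kj->kij", a, g).reshape(config.n_steps, 16)


def forward(M: np.ndarray, config: DRRConfig | None = None) -> np.ndarray:
    """Simulate the recorded intensity series for a sample Mueller matrix.

    ``M`` may be a single (4, 4) matrix or a stack (..., 4, 4); the result
    has shape (n_steps,) or (n_steps, ...) respectively.
    """
    config = config or DRRConfig()
    D = design_matrix(config)
    M = np.asarray(M, dtype=float)
    flat = M.reshape(M.shape[:-2] + (16,))
    return np.einsum("ke,...e->k...", D, flat)


def reconstruct(
    intensities: np.ndarray,
    config: DRRConfig | None = None,
    *,
    cond_limit: float = 1e8,
) -> np.ndarray:
    """Least-squares recovery of the sample Mueller matrix from intensities.

    Accepts a series of shape (n_steps,) or a stack (n_steps, ...), returning
    (4, 4) or (..., 4, 4).  Noiseless round trips are exact to ~1e−12.
    """
    config = config or DRRConfig()
    D = design_matrix(config)
    s = np.linalg.svd(D, compute_uv=False)
    cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    if cond > cond_limit:
        raise ConditioningError(
            f"DRR design matrix is ill-conditioned (condition number {cond:.3g}); "
            "half-wave retardances or a degenerate schedule cannot resolve all "
            "16 Mueller elements"
        )
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape[0] != config.n_steps:
        raise ValueError(
            f"expected {config.n_steps} frames, got {intensities.shape[0]}"
        )
    pinv = np.linalg.pinv(D)
    flat = np.einsum("ek,k...->...e", pinv, intensities)
    return flat.reshape(flat.shape[:-1] + (4, 4))


def calibration_error(M_measured: np.ndarray, M_reference: np.ndarray) -> float:
    """Maximum absolute element difference between two normalized matrices.

    This is the scalar used to validate the instrument against standard
    samples (air → identity, known retarders).
    """
    return float(np.max(np.abs(np.asarray(M_measured) - np.asarray(M_reference))))
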