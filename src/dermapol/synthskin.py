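"""Synthetic Mueller-image generator emulating staged skin measurements.

No public dataset exists for the live-animal measurements, so every
analysis stage is exercised on synthetic 400×400-pixel Mueller images whose
summary statistics match the reported per-stage ranges: healthy skin with
mean A ≈ 0.26–0.32 and α spread ≈ 21–38°, seriously photo-damaged skin
with mean A ≈ 0.20–0.23 and spread ≈ 45–54°, and self-repaired skin back
at healthy values.

Pixel construction inverts the MMT definition: each pixel gets an
orientation ``x`` drawn from a spatially correlated wrapped-normal field
(spread σ_α/4 so that α = 4x has spread σ_α) and an anisotropy target
``A``; the pixel matrix is a linear retarder at axis ``x`` whose
retardance is chosen so the retarder-block ratio reproduces ``A`` exactly,
composed with an isotropic partial depolarizer for realistic element
amplitudes (which leaves A and α unchanged).  Anisotropy is therefore
retarder-like, matching the birefringent-fibre origin of the tissue
signal.  Element-wise Gaussian noise emulates measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from . import drr as drr_mod
from . import polcore
from .muellerio import DEFAULT_PIXEL_SIZE_CM, MuellerImage

__all__ = [
    "StagePreset",
    "PRESETS",
    "generate_image",
    "generate_trajectory",
    "standard_trajectory",
    "generate_drr_frames",
]


@dataclass(frozen=True)
class StagePreset:
    """Target statistics for one measurement stage.

    ``alpha_spread_deg`` is the *measured* spread the image should
    reproduce — the peak-independent standard deviation of α recovered by
    the analysis — not the raw wrapped-normal parameter.  Because wrapping
    onto the 180° orientation circle compresses the linear standard
    deviation (a wrapped normal with σ = 51° measures ≈ 45°; the uniform
    limit is 180°/√12 ≈ 51.96°), the generator inverts that bias when
    drawing the orientation field.
    """

    name: str
    target_mean_A: float
    alpha_center_deg: float = 20.0
    alpha_spread_deg: float = 28.0
    correlation_px: float = 8.0
    noise_sigma: float = 0.005
    #: linear-block depolarization scale (m22-amplitude realism only)
    depol_linear: float = 0.5
    #: circular depolarization scale (m44 amplitude)
    depol_circular: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_mean_A <= 1.0:
            raise ValueError("target_mean_A must be in [0, 1]")
        if self.alpha_spread_deg < 0:
            raise ValueError("alpha_spread must be nonnegative")


PRESETS: dict[str, StagePreset] = {
    "healthy": StagePreset("healthy", target_mean_A=0.29, alpha_spread_deg=28.0),
    "damaged": StagePreset("damaged", target_mean_A=0.215, alpha_spread_deg=51.0),
    "repaired": StagePreset("repaired", target_mean_A=0.285, alpha_spread_deg=28.5),
}


#: linear std of the uniform orientation distribution (unreachable supremum
#: for wrapped normals)
_UNIFORM_STD = 180.0 / np.sqrt(12.0)


def _wrapped_recentred_std(sigma_deg: float) -> float:
    """Measured (recentred linear) std of a wrapped normal with parameter σ."""
    x = np.linspace(-90.0, 90.0, 2001)
    k = np.arange(-8, 9)[:, None]
    p = np.exp(-0.5 * ((x[None, :] + 180.0 * k) / sigma_deg) ** 2).sum(axis=0)
    p /= np.trapezoid(p, x)
    return float(np.sqrt(np.trapezoid(x * x * p, x)))


def generating_sigma(target_std_deg: float) -> float:
    """Wrapped-normal parameter whose measured spread equals the target.

    Bisects the monotone wrapping-bias map; targets at or beyond the
    uniform limit (≈ 51.96°) return a near-uniform field.
    """
    if target_std_deg <= 0:
        return 0.0
    if target_std_deg >= _UNIFORM_STD - 0.05:
        return 400.0  # effectively uniform
    lo, hi = target_std_deg * 0.9, 400.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _wrapped_recentred_std(mid) < target_std_deg:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _correlated_field(shape, correlation_px, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with the given
    correlation length (pixels); degenerates to white noise at 0."""
    w = rng.standard_normal(shape)
    if correlation_px <= 0:
        return w
    f = gaussian_filter(w, correlation_px, mode="wrap")
    return (f - f.mean()) / f.std()


def _pixel_matrices(alpha_deg, A, depol_linear, depol_circular) -> np.ndarray:
    """Vectorized depolarizer∘retarder matrices hitting (A, α) exactly."""
    A = np.clip(np.asarray(A, float), 1e-6, 1.0 - 1e-9)
    # invert A = 2r/(1+r^2) on the r <= 1 branch, r = t/b
    r = (1.0 - np.sqrt(1.0 - A * A)) / A
    cosd = (1.0 - r) / (1.0 + r)
    sind = np.sqrt(np.clip(1.0 - cosd**2, 0.0, None))
    x = np.deg2rad(np.asarray(alpha_deg, float) / 4.0)
    c2, s2 = np.cos(2 * x), np.sin(2 * x)

    shape = np.broadcast_shapes(A.shape, x.shape)
    M = np.zeros(shape + (4, 4))
    M[..., 0, 0] = 1.0
    # linear retarder at axis x (same convention as polcore.linear_retarder)
    M[..., 1, 1] = c2**2 + s2**2 * cosd
    M[..., 2, 2] = s2**2 + c2**2 * cosd
    M[..., 1, 2] = M[..., 2, 1] = c2 * s2 * (1.0 - cosd)
    M[..., 1, 3] = s2 * sind
    M[..., 3, 1] = -s2 * sind
    M[..., 2, 3] = -c2 * sind
    M[..., 3, 2] = c2 * sind
    M[..., 3, 3] = cosd
    # isotropic partial depolarizer (scales rows 2..4, leaves A and α fixed)
    M[..., 1, :] *= depol_linear
    M[..., 2, :] *= depol_linear
    M[..., 3, :] *= depol_circular
    return M


def generate_image(
    preset: StagePreset | str,
    size: tuple[int, int] = (400, 400),
    seed: int = 0,
    *,
    shared_fields: tuple[np.ndarray, np.ndarray] | None = None,
) -> MuellerImage:
    """Generate one synthetic m11-normalized Mueller image for a stage.

    ``shared_fields`` optionally supplies the (orientation, anisotropy)
    unit-variance texture fields so several timepoints of one trajectory
    share the same underlying tissue texture.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    if shared_fields is None:
        f_alpha = _correlated_field(size, preset.correlation_px, rng)
        f_A = _correlated_field(size, preset.correlation_px, rng)
    else:
        f_alpha, f_A = shared_fields
    sigma_gen = generating_sigma(preset.alpha_spread_deg)
    alpha = polcore.wrap_alpha(preset.alpha_center_deg + sigma_gen * f_alpha)
    A = np.clip(preset.target_mean_A + 0.02 * f_A, 0.02, 0.98)
    M = _pixel_matrices(alpha, A, preset.depol_linear, preset.depol_circular)
    metadata: dict = {"preset": preset.name, "seed": int(seed)}
    if preset.noise_sigma > 0:
        noise = rng.normal(0.0, preset.noise_sigma, M.shape)
        noise[..., 0, 0] = 0.0  # keep the m11-normalized convention
        M = M + noise
        if preset.noise_sigma > 0.1:
            metadata["warning"] = (
                "noise sigma large relative to the anisotropy signal; the "
                "target mean A may be unreachable"
            )
    return MuellerImage(
        M,
        pixel_size_cm=DEFAULT_PIXEL_SIZE_CM,
        normalized=True,
        stage_label=preset.name,
        metadata=metadata,
    )


def standard_trajectory(
    kind: str = "no_sunscreen",
    n_damage: int = 3,
    n_repair: int = 4,
) -> list[StagePreset]:
    """Preset sequence emulating a photo-damage / self-repair time course.

    Day 0 is the healthy baseline; A then dips (and the α spread rises)
    linearly to the most-damaged values over ``n_damage`` days and returns
    over ``n_repair`` days.  ``sunscreen`` uses the protected effect sizes
    (A dip 0.035, spread rise 10°); ``control`` stays flat.
    """
    healthy = PRESETS["healthy"]
    if kind == "no_sunscreen":
        damaged = PRESETS["damaged"]
    elif kind == "sunscreen":
        damaged = replace(
            healthy,
            name="damaged_sunscreen",
            target_mean_A=healthy.target_mean_A - 0.035,
            alpha_spread_deg=healthy.alpha_spread_deg + 10.0,
        )
    elif kind == "control":
        return [replace(healthy, name=f"control_day{d}") for d in range(n_damage + n_repair)]
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    out = [replace(healthy, name=f"{kind}_day0")]
    for d in range(1, n_damage + 1):
        f = d / n_damage
        out.append(_blend(healthy, damaged, f, f"{kind}_day{d}"))
    for d in range(1, n_repair + 1):
        f = 1.0 - d / n_repair
        out.append(_blend(healthy, damaged, f, f"{kind}_day{n_damage + d}"))
    return out


def _blend(a: StagePreset, b: StagePreset, f: float, name: str) -> StagePreset:
    return replace(
        a,
        name=name,
        target_mean_A=(1 - f) * a.target_mean_A + f * b.target_mean_A,
        alpha_spread_deg=(1 - f) * a.alpha_spread_deg + f * b.alpha_spread_deg,
    )


def generate_trajectory(
    stages: list[StagePreset],
    size: tuple[int, int] = (400, 400),
    seed: int = 0,
) -> list[MuellerImage]:
    """One image per stage preset with a shared tissue texture.

    The orientation/anisotropy texture fields are drawn once (same mouse
    imaged repeatedly); per-timepoint noise differs.
    """
    if len(stages) < 2:
        raise ValueError("a trajectory needs at least two stages")
    rng = np.random.default_rng(seed)
    f_alpha = _correlated_field(size, stages[0].correlation_px, rng)
    f_A = _correlated_field(size, stages[0].correlation_px, rng)
    return [
        generate_image(
            p, size, seed=int(seed + 1000 + k), shared_fields=(f_alpha, f_A)
        )
        for k, p in enumerate(stages)
    ]


def generate_drr_frames(
    image: MuellerImage,
    config: drr_mod.DRRConfig | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Forward-model the 30-frame intensity stack for a Mueller image.

    ``noise_sigma`` is the absolute standard deviation of zero-mean
    Gaussian intensity noise added to every frame pixel.
    """
    config = config or drr_mod.DRRConfig()
    frames = drr_mod.forward(image.elements, config)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    return frames
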