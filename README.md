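# dermapol

Backscattering Mueller-matrix polarimetry of skin: a polarized-light Monte
Carlo simulator for fibrous tissue (the sphere-cylinder birefringence
model), dual-rotating-retarder (DRR) Mueller-matrix reconstruction, and the
quantitative anisotropy statistics used to monitor skin photo-damage and
self-repair.

The package is for researchers in tissue polarimetry who want to (i)
simulate how microstructural changes — fibre loss and fibre disorder —
show up in backscattering Mueller matrices, (ii) model and invert the
30-frame DRR measurement, and (iii) turn per-pixel Mueller images into the
scalar indicators used for longitudinal skin monitoring.

## The model and the parameters

A 4×4 Mueller matrix `M` (normalized by `m11`) encodes everything linear
optics can say about a sample's polarization response.  For fibrous skin
the four linear elements `m22, m23, m32, m33` carry the anisotropy signal,
condensed by the Mueller-matrix transformation (MMT) into two
rotation-insensitive scalars:

    b = (m22 + m33)/2
    t = sqrt((m22 − m33)² + (m23 + m32)²)/2
    A = 2·b·t / (b² + t²)            ∈ [0, 1]   (degree of anisotropy)
    tan α = (m23 + m32)/(m22 − m33)              (fibre orientation; α = 4x)

`A` rises with the alignment of dermal collagen fibres; `α` tracks their
orientation (a pure linear retarder with axis θ gives α = 4θ).  Damage
analysis uses the mean of `A` over a 400×400-pixel region, the
frequency-distribution histogram (FDH) of `α` (400 bins over (−90°, 90°],
area normalized to 1), and the peak-independent standard deviation of `α`
(recentred at the circular mean of 2α; uniform disorder gives
180°/√12 ≈ 51.96°).

The Monte Carlo engine transports polarized photons through a slab
containing small spheres (organelles; Mie scattering, 0.2 µm) and
infinitely long in-plane cylinders (collagen fibres; oblique-incidence
cylinder scattering, 1.5 µm) in a uniaxially birefringent interstitial
medium (Δn = 1e−4), with total μs = 200 cm⁻¹, slab thickness 0.05 cm,
indices 1.4/1.33, λ = 632 nm and 15° oblique incidence.  Photo-damage is
modeled by shifting scattering weight from cylinders to spheres and
widening the cylinder orientation spread σ at constant μs.

## Worked example

Simulate the four no-sunscreen damage stages (sphere:cylinder shares
20:180 → 50:150 cm⁻¹, σ = 10° → 22°) and print the anisotropy:

```python
from dermapol import scbm

for row in scbm.damage_sweep("no_sunscreen", n_photons=200_000, seed=1):
    print(f"stage {row['stage']} ({row['ratio']}, sigma={row['sigma_deg']}deg): "
          f"A = {row['A']:.3f} +- {row['A_se']:.3f}")
```

```
stage 1 (20:180, sigma=10.0deg): A = 0.405 +- 0.007
stage 2 (30:170, sigma=14.0deg): A = 0.266 +- 0.009
stage 3 (40:160, sigma=18.0deg): A = 0.208 +- 0.015
stage 4 (50:150, sigma=22.0deg): A = 0.101 +- 0.016
```

`A` falls monotonically as fibres are lost and disordered — the simulated
signature of developing photo-damage; the matched sunscreen sweep
(20:180 → 35:165, σ = 10° → 16°) drops only about half as much
(0.405 → 0.254).

The full measurement chain on synthetic data — staged Mueller images →
DRR intensity frames → least-squares reconstruction → MMT maps → stage
statistics:

```bash
dermapol pipeline --size 200 --seed 0 --noise 0.001 --out demo/
```

```
day 0 (no_sunscreen_day0): mean A=0.2907 std alpha=28.42 deg
day 3 (no_sunscreen_day3): mean A=0.2164 std alpha=44.50 deg
day 7 (no_sunscreen_day7): mean A=0.2910 std alpha=28.45 deg
damaged=True recovered=True -> demo/pipeline_report.json
```

showing the dip-and-recovery of mean `A` (healthy ≈ 0.26–0.32 → damaged
≈ 0.20–0.23 → recovered) and the rise-and-return of the α spread
(≈ 28° → ≈ 45–51° → ≈ 28°).

Other subcommands: `dermapol simulate` (single stage or sweep, writes the
16-channel TIFF container + JSON diagnostics), `reconstruct`, `mmt`,
`analyze`, `fixtures`.

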