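# dgnrange

Patient-specific **normalized glandular dose (DgN) ranges** for screening
mammography.

## The problem

Mammographic dose reporting normalizes the mean dose to fibroglandular
(FG) tissue by the entrance air kerma:

```
DgN = Σ_E D_E W_E / Σ_E K_E W_E        [Gy per Gy, unitless]
```

with `D_E` the FG dose, `K_E` the entrance air kerma, and `W_E` the beam
weight per energy bin.  Conventional DgN coefficients assume a
homogeneous 50/50 adipose/glandular breast, but real FG tissue is
spatially concentrated — and a single projection image cannot tell
*where in depth* it sits.  Because the beam attenuates with depth, FG
tissue near the entrance (source) surface can receive several times the
dose of the same tissue near the detector, while the projection images
are essentially indistinguishable.  A single DgN number therefore hides
a large anatomical uncertainty.

This package computes, for a given projection + per-pixel glandular
fraction (GF) map, the *feasible range* `[DgN_min, DgN_max]` and a
most-likely DgN:

1. **Phantoms** — voxelized compressed breasts (half-elliptic prism,
   1 mm voxels, 1-voxel skin) with FG tissue in a depth slab at the
   top, center, or bottom (`dgnrange.phantom`).
2. **Projector** — exact Siddon ray tracing for primary-beam
   projections and GF maps, where `GF × compressed thickness` is the FG
   path length along each pixel's ray (`dgnrange.projector`).
3. **Transport** — a seeded photon Monte Carlo (photoelectric,
   Klein–Nishina Compton, Rayleigh; kerma approximation) scoring FG
   dose and tallying entrance-kerma photons through a 3 × 3 cm plane
   (`dgnrange.transport`), with embedded 10–30 keV cross sections
   (`dgnrange.materials`) and a modeled 30 kVp W/Al spectrum
   (`dgnrange.spectrum`).
4. **Reconstruction** — the core algorithm: back-project each pixel's
   FG path budget along its ray, flipping adipose voxels to FG
   source-first (maximum dose), detector-first (minimum dose), or
   center-out (most likely), then add skin (`dgnrange.reconstruct`).
   A 1-D two-slab closed form proves the ordering analytically
   (`dgnrange.dosimetry.two_slab_dose`).

## Worked example

```python
import dgnrange as dg

beam = dg.default_beam()                       # 30 kVp W/Al, 2 keV bins, 13-27 keV
spec = dg.BreastSpec(12.29, 4.29, 6.145, 0.20, "center")
phantom = dg.build_breast(spec)                # 123 x 62 x 43 voxels at 1 mm
res = dg.dgn_bounds_pipeline(phantom, beam,
                             config=dg.TransportConfig(100_000, 42))
r = res.dgn_range
print(f"DgN in [{r.dgn_min:.4f}, {r.dgn_max:.4f}], likely {r.dgn_likely:.4f}")
print(f"true DgN {res.dgn_true.dgn:.4f}, contained: {res.contained}")
```

prints (seed 42, 1e5 photons per energy bin, ~4 s):

```
DgN in [0.0944, 0.6412], likely 0.2440
true DgN 0.2428, contained: True
```

Read: for this 12.29 cm × 4.29 cm breast at 20% glandularity, any
depth arrangement of the FG tissue consistent with the projection
delivers between 0.094 and 0.64 Gy per Gy of entrance air kerma — a
6.8× spread resolved by no single image — while the phantom's actual
DgN (0.243) falls inside the bounds and is well approximated by the
center reconstruction.  The ± values attached to each bound
(`r.stderr_*`) are 1σ Monte Carlo errors, here below 0.2%.

The same stages are scriptable from a shell (`dgnrange phantom`,
`project`, `gfmap`, `reconstruct`, `transport`, `dgn-range`,
`reproduce --experiment {thickness,glandularity,reconstruction}`).

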