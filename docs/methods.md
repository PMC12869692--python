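# Methods

## Model overview

The package estimates bounds on the normalized glandular dose (DgN) of a
compressed breast from the only depth-blind observables a single
mammographic projection provides: the image itself and a per-pixel
glandular-fraction (GF) map.  The chain is: voxel phantom → Siddon
forward projection / GF map → constrained back-projection into
minimum-, center- and maximum-dose volumes → photon Monte Carlo dose →
DgN = Σ D_E W_E / Σ K_E W_E.

## Phantoms

The compressed breast is a **half-elliptic prism**: a half-ellipse
footprint (lateral semi-axis = diameter/2, chest-wall-to-nipple extent
as the other semi-axis, flat at the chest-wall plane y = 0) extruded at
uniform compressed thickness — the shape consistent with compression
paddles and with defining per-pixel GF against one global thickness.  A
rounded half-ellipsoid profile is available via
`build_breast(..., shape="half_ellipsoid")` for sensitivity checks.
Voxels are 1 mm³ by default; grids round dimensions up to whole voxels
(e.g. 3.29 cm → 33 slices), which slightly rounds the effective
thickness.

Skin is the outermost voxel layer of the support (1.45 mm rounded to
the nearest voxel multiple — one voxel at 1 mm pitch), on all faces
except the chest wall.  Fibroglandular tissue fills a depth-contiguous
slab of interior voxels: hugging the top skin, the bottom skin, or
centered on mid-depth.  Whole depth slices are filled and the boundary
slice is topped up partially in fixed raster order, so the achieved
volume GF matches the request to well under 1%.  The partial slice is
the one deliberate departure from lateral uniformity; it leaves a
one-voxel FG difference on rays grazing its edge (~2% of interior
pixels differ by up to ~2% in signal between placements).  Top and
bottom placements are exact mirror images through mid-depth.

The baseline study set (`table1_presets`) is four sizes —
11.29 × 3.29, 12.29 × 4.29, 13.29 × 5.29 and 14.29 × 6.29 cm (diameter
× thickness, skin included; chest-wall-to-nipple = diameter/2) — at
20% GF, plus the 12.29 cm size at 30% and 50%, each in the three
placements: 18 cases.

## Beam model

The default spectrum is a 30 kVp tungsten-anode beam behind 0.7 mm Al:
Kramers' thick-target law in the photon-count convention,
N(E) ∝ (kVp − E)/E, times aluminum transmission, discretized on a
0.5 keV grid and rebinned onto eight 2 keV bins centered at
13, 15, …, 27 keV (weight outside the band is discarded and the rest
renormalized).  Tungsten characteristic lines lie far above these
voltages.  Any measured spectrum can be substituted via CSV; DgN is a
per-energy-normalized ratio, so moderate spectral differences perturb
it only mildly.

## Cross sections

No photon cross-section library is part of the supported environment,
so the five material tables (air, adipose, fibroglandular — Hammerstein-
type compositions, skin, CsI; densities 1.205e-3 / 0.95 / 1.02 / 1.09 /
4.51 g/cm³) are generated by `scripts/build_material_tables.py` from a
small elemental model: Klein–Nishina incoherent scattering with an
empirical binding suppression, and per-element power-law photoelectric
and coherent components anchored at 20 keV to standard reference
values.  Mixture totals agree with NIST-style tables to a few percent
across 10–30 keV (air μ_en/ρ at 20 keV: 0.534 here vs 0.539 cm²/g
published); the tables are internally exact (total ≡ sum of components,
μ_en ≤ μ).  Interpolation is log–log linear.  A few-percent coefficient
shift moves absolute DgN by a similar amount but barely touches the
ratios and orderings this package reports.

## Transport

Photons are transported one energy bin at a time through the label grid
under the **kerma approximation** (sub-30 keV electron ranges in tissue
are < 0.02 mm ≪ 1 mm voxels, so recoil/photoelectron energy deposits at
the interaction site).  Photoelectric events absorb; Compton events
deposit the Klein–Nishina-sampled recoil energy and continue; Rayleigh
events redirect with a Thomson angular law (form factors neglected) and
deposit nothing.  Photons falling below 10 keV are absorbed locally
(mean free path ~3 mm, photoelectric-dominated).  The beam is
collimated to the detector rectangle from a point source 35.46 cm above
the phantom's top surface over the chest-wall edge.

Entrance air kerma uses the photon-count tally through a 3 × 3 cm
region at the entrance plane on the beam axis:
`K_E = 1.602e-10 · E · 1e-3 · (μ_en/ρ)_air(E) · N / 9 cm²`
(dimensionally: fluence × E × 1.602e-16 J/keV × cm²/g × 1000 g/kg
gives Gy).  Only the phantom is transported — no compression paddles,
water bath, beam-shaping block, or anti-scatter grid.  This is the
largest simplification relative to full Monte Carlo systems
(Geant4-class) and is deliberate: it keeps the engine desk-scale.
Its main consequence (below) is that the scatter bath irradiating the
deep breast is underestimated, so top/bottom DgN *ratios* come out
larger than published values, while orderings, containment, and
matched-pair comparisons — which this package exists to compute — are
unaffected in sign and structure.

Runs are single-threaded and seeded (bin *i* uses seed + *i*); results
are bit-reproducible.  Standard errors come from 10 interleaved photon
batches.  The default 1e5 photons/bin (vs ~1e8 in production-scale
studies) gives sub-percent DgN standard errors in seconds per phantom;
all tests and the acceptance script run at this scale and quote
uncertainties with their comparisons.

A deterministic **primary-dose oracle** (Beer–Lambert-attenuated
fluence × E × (μ_en/μ)_FG accumulated along Siddon rays) validates the
Monte Carlo with scattering disabled to 3σ; an exact per-bin energy
ledger (deposited + escaped = emitted) guards bookkeeping.

## Reconstruction

For each solidly shadowed pixel the FG path budget is
`GF × compressed thickness`.  Rays are Siddon-traced from the detector
toward the source; traversed voxels start as adipose and are flipped to
FG in mode order — source-first (max dose), detector-first (min dose),
or center-out from the mid-depth plane, stepping whole equal-z runs of
the traversal so bands align across oblique rays — until the cumulative
intersection length reaches the budget.  The final voxel is kept only
if that reduces the absolute error (half-voxel rule).  Rays are
processed in raster order and voxels are never un-flipped; FG already
present on a ray counts toward its budget.  The outermost support layer
is then relabeled skin; if that debits more than 1% of the global FG
budget a single correction sweep tops the affected rays back up (rim
rays that cannot recover their loss are logged).

Two choices here were genuinely open:

* **Support definition.**  A pixel casts a reconstruction column only
  if its tissue chord reaches half the compressed thickness (the GF map
  records per-pixel chords).  Edge rays that merely clip the voxelized
  surface would otherwise seed full-thickness columns, inflating the
  volume and preventing the reconstruction from being a fixed point of
  its own GF map; their sub-percent FG budget is dropped and logged.
* **Ray overlap.**  Divergent rays share voxels.  With raster order and
  no un-flipping, a voxel flipped by a later ray can push an
  earlier-processed ray ~1 voxel over budget.  Reconstruction is
  therefore voxel-exactly idempotent where rays do not share voxels
  (verified under near-parallel geometry) and reproduces itself to
  better than 99.5% of voxels under the 35.46 cm divergent geometry;
  GF residuals stay within half a voxel for ≥95% of interior pixels
  (interior = solid shadow minus the two-pixel skin-dominated rim).

`dgn_bounds_pipeline` chains everything: given a ground-truth phantom
it generates the projection and GF map internally, reconstructs all
three modes, transports each, and reports the DgN range, the true DgN,
and a containment flag.

## The two-slab closed form

For an FG slab of thickness `t_fg` at depth `d` under adipose,
monoenergetic normal incidence, the mean FG collision kerma is
`∝ exp(−μ_ad d) · (1 − exp(−μ_fg t_fg)) · (μ_en/μ)_fg / t_fg`, strictly
decreasing in `d` (log-derivative −μ_ad).  Dose is hence maximized with
FG at the entrance surface and minimized at the exit surface; the sign
agrees with the 3-D Monte Carlo orderings at every breast size, making
the closed form an analytic oracle for the reconstruction modes.

## What the synthetic conditions do and do not show

The generator produces idealized phantoms: geometric shapes, uniform
depth slabs, a perfect GF map from the package's own projector, no
noise, no scatter in the projector, no detector response.  Passing
tests therefore demonstrate the *internal consistency and the physics
of the placement effect* — ordering, range narrowing with glandularity,
containment of the true DgN, matched-pair agreement — not performance
on clinical images, where GF-map estimation error, anatomical texture,
and scatter would widen the bounds.  Absolute DgN values depend on the
tissue compositions and the idealized geometry and should be read as
model values, not clinical coefficients.

Known quantitative consequences of the simplifications, measured at
1e5 photons/bin:

* Top/bottom DgN ratios are **larger** than published full-geometry
  values (≈4.5 at 3.29 cm and ≈13 at 6.29 cm here, vs ≈1.8 and ≈3.0
  with a full system geometry): without the paddle/bath/grid scatter
  environment, the deep breast receives far less scattered dose, so the
  extremes spread further apart.  The monotone growth of the ratio with
  thickness, and every ordering, are preserved.
* Containment holds 18/18 and the worst matched-configuration deviation
  is ≈8% (largest thick-breast top case), dominated by voxelization and
  the simplified skin at the reconstruction rim.

## Numerical choices

Log–log interpolation everywhere on cross sections; 0.1 keV transport
lookup grid with linear interpolation; Siddon traversal with a 1e-9
relative entry-probe and half-voxel stopping rule; Compton sampling by
rejection against envelope 2 (exact at these energies); kerma region
3 × 3 cm at the entrance plane, chest-wall centered; seeds derived as
`base + 100 × case_index` (+1..3 for reconstruction modes), all well
below 2³¹.  Degenerate inputs fail loudly: zero FG mass, zero weighted
kerma, out-of-band energies, infeasible slab depths, and inconsistent
map/thickness pairings raise typed errors.

## Limitations

No electron transport, fluorescence, Doppler broadening, or coherent
form factors; no detector blur/noise; no paddle/bath/grid scatter (see
above); no anatomically textured FG distributions; single-view only.
The divergent-beam GF-map volume integral overestimates shallow FG by
the cone magnification ((SID+T)/(SID+z))², inherent to defining the map
on detector pixels.
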