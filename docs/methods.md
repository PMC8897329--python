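# Methods

`j45dose` is a desk-scale re-implementation of the survivor organ-dosimetry
pipeline used for the atomic-bomb survivor cohort: angle/energy-binned
free-field fluences are converted into Monte Carlo phase-space source terms,
transported onto an anthropomorphic phantom, and reduced to nine-component
organ absorbed doses with the comparison arithmetic used in cohort risk
work.  This note records the model, the parameters that matter, the places
where the design was genuinely open, and what the synthetic stand-ins do and
do not emulate.

## Angular quadrature

Fluences are indexed by a customized S-8 level-symmetric quadrature for
R-Z geometry: 48 directions over 2π, eight of which are zero-weight
"starting directions" (one per polar level, placed at
`mu = -sqrt(1 - eta^2)` in the `beta = 0` plane), the standard device for
stabilizing discrete-ordinates sweeps in curvilinear geometry.  The numeric
ordinates of the original system are not public, so the package ships the
classical LQ8 ordinate set (0.2182179, 0.5773503, 0.7867958, 0.9511897 with
octant point weights 0.1209877/0.0907407/0.0925926) in an editable CSV;
weights are renormalized on load so contributing bins sum to exactly 1.

Polar refinement splits each direction into `factor` children (default 5),
spaced `span/factor` apart in polar angle and centred on the parent so that
`factor = 1` is an exact identity; children preserve the parent azimuth and
carry `weight/factor`.  Mirroring across `beta = 0` unfolds the symmetric
240-direction set (200 contributing) into the asymmetric 480-direction set
(400 contributing), halving each weight.  Invariants asserted in tests:
exact counts, weight conservation to 1e-12, unit-norm directions, and the
vanishing of odd angular moments by symmetry.

## Synthetic fluences

The real fluence database is proprietary, so `synthesize_fluence` generates
stand-ins for the 20 generalized scenarios (2 cities x {1000, 1500} m x
{in-open, light/heavy 9-parameter house, light/heavy GLOBE}).  Each scenario
carries six components — prompt/delayed gamma, prompt/delayed neutron, and
two secondary shielded neutron-gamma components — on 21/21/37/23/21/21
energy groups (144 total).  Group boundaries default to logarithmic spans
(gammas 0.01–10 MeV, prompt neutrons 1e-9–20 MeV, delayed neutrons
1e-9–5 MeV) stored in editable CSVs; every algorithm is boundary-agnostic.

Features emulated, with generator defaults:

* **angular anisotropy** — intensity `exp(kappa * d_x)` with `kappa = 2.5`,
  forward-peaked toward directions leaving the hypocenter; shielded
  scenarios add a lateral skew `(1 + 0.3 * d_y)`;
* **spectra** — gammas fall as `E^-0.7 exp(-E/2.5 MeV)`; neutrons combine a
  300 K Maxwellian hump, a 1/E epithermal span and an evaporation-like fast
  tail (25/45/30 % in the open; shielding shifts weight toward thermal);
* **magnitudes** — totals of order 1e10–1e11 cm^-2 at the 1000 m reference,
  falling with distance as `1/r^2` times relaxation lengths of 450 m
  (gamma) and 200 m (neutron); Nagasaki carries a strongly reduced neutron
  component; a 2 % lognormal bin jitter adds texture.

These choices reproduce the *structure* real data would exercise (angular
concentration, three-part neutron spectra, city/distance/shielding trends);
they do not reproduce actual free-field magnitudes or spectral detail, so
absolute organ doses computed here are internally consistent but not
comparable to published survivor doses.  The shielded-air-KERMA scalar is
formed from the component totals with fixed per-particle KERMA coefficients
(2e-8 / 5e-9 mGy cm^2 for gammas/neutrons).

## Phase-space sampling

Angle bins are selected with probability (bin fluence x bin weight) /
total weighted fluence — zero-weight starting directions can never fire —
then an energy group by its share of the bin's spectrum.  Within a group,
gammas are uniform in energy; neutrons below the thermal cutoff (default
1e-6 MeV) follow a Maxwell–Boltzmann energy density `sqrt(E) exp(-E/kT)`
(a Gamma(3/2, kT) law, sampled exactly by inverse regularized incomplete
gamma, truncated to the group) at a configurable temperature (default
300 K, kT = 2.585e-8 MeV); neutrons above the cutoff are log-uniform (1/E).

Positions are uniform on a disc whose normal equals the bin direction
(rotation about x by the angle from `eta`, then about z by the angle from
`mu`), translated one radius upstream, so `position . direction = -R`
exactly; the expansion radius is 40/70/100 cm by phantom age class.  The
space between disc and phantom is vacuum, so free-field interactions are
not double counted.  ASCII records are written at full double precision
(byte-identical under a fixed seed); the MCPL binary dialect stores single
precision with in-place reciprocal packing of the largest direction
component, giving ~1e-7 relative round-trip agreement.

## Phantom

The stylized adult is a quadric-surface reconstruction in the documented
legacy style: 160 cm standing height (the 1945 Japanese adult), cylindrical
neck containing thyroid and cervical spine, arms as conical frustums
separated from the trunk, arm/leg bones as single rods split into
upper/middle/lower thirds, exactly three media (soft tissue 1.00, skeleton
1.40, lung 0.296 g/cm^3), and explicit volume targets for lungs, pancreas,
thyroid and testes (provisional values — the original report's organ
volumes are not reprinted here).  All coefficients live in
`data/phantom_adult.yaml`; nothing is hard-coded.  The body frame is z-up
with +x anterior; the transport engine rotates world coordinates 180°
about z so the survivor faces the hypocenter.

Voxelization is by voxel-centre membership with a fixed claim priority —
skeleton > internal organs > skin > residual soft tissue (registered as the
`muscle` organ) — which makes organs pairwise disjoint by construction and
converges to the CSG volumes as spacing shrinks (verified against the
closed-form sphere volume at 1 % and by monotone error decay).  At 0.5 cm
all 28 registry organs, including the 0.6 cm eye lenses, receive positive
mass; the working resolution for transport tests is 1.0 cm.  Generic voxel
phantoms round-trip through a raw little-endian int16 array plus a YAML
sidecar.

The 25-bone-site registry and its active-marrow/endosteum distribution
fractions (legacy-style and modern-style tables, ages infant/child/adult)
are synthetic reconstructions normalized to sum to 1; the two styles differ
mainly in how much adult marrow is attributed to the long bones.

## Dose engine

The engine is analog, KERMA-approximation Monte Carlo on the voxel grid
(3-D DDA traversal; free paths from total interaction coefficients,
log-log interpolated from small editable tables whose magnitudes follow
standard tissue/bone compilations but are not evaluated data).

* Photons deposit `E * (muen/mu)` at a collision and terminate
  (deposit-and-kill default) or continue with survival weighting and
  isotropic redirection (optional, energy unchanged — simplified physics).
* Neutrons deposit the collision-estimator KERMA `k_f / (sigma/rho)`,
  clipped to the particle's remaining kinetic energy.  The clip discards
  capture Q-value energy (significant for thermal neutrons) in exchange
  for a strict run-level invariant: total deposited energy never exceeds
  emitted energy, where "emitted" counts source kinetic energy plus the
  energy of spawned secondaries.
* Each neutron collision spawns, with configurable yield (default 0.3), an
  isotropic 2.2 MeV pseudo-photon (hydrogen-capture-like) scored to the
  body neutron-gamma components.  This is calibration-ware standing in for
  in-body secondary-gamma production, not a physical capture model.
* Air-generated electrons use a stub continuous-slowing-down model:
  energy is deposited uniformly in mass depth along the entry direction
  over a Katz–Penfold CSDA range, so organs deeper than the maximum range
  receive exactly zero — reproducing the qualitative finding that internal
  organs see negligible air-electron dose.

Tallies are per-organ MeV/g per source particle with batch-based standard
errors (20 batches default).  Track-length fluences at the bone sites
(path length through site voxels / site volume, binned by energy group)
feed synthetic fluence-to-dose response functions (KERMA-shaped in energy
with a deterministic ±15 % per-site modifier) and the fraction-weighted
marrow/endosteum sums.

**Absolute dose.**  A tally per source particle is converted to dose per
unit fluence by the source-disc area (one particle uniform on a disc of
area A represents fluence 1/A), then multiplied by the component's total
weighted fluence and 1.602e-7 mGy per MeV/g.  The nine components are the
six source terms, the two body neutron-gamma terms, and the air-electron
term; category sums follow cohort practice (neutron = prompt + delayed
neutron absorbed dose; everything else, including neutron-induced gammas
and air electrons, reports under gamma).

Validation oracles: Beer–Lambert slab transmission within 3σ at 1e5
particles, 1/sqrt(n) error scaling, track-length vs collision estimator
agreement in a homogeneous region, and a brute-force triple-loop equality
(1e-12) for the marrow weighted sum.

## Comparison reporting

Percent difference is `(reference - new) / new x 100`, rounded half-even
to one decimal — the convention verified against the printed reference
pairs (3545.2 vs 3465.3 → −2.3 %; 4332.6 vs 4375.8 → 1.0 %; 3759.1 vs
3574.2 → −4.9 %).  RBE weighting multiplies only the neutron absorbed-dose
components (neutron-induced gammas configurable, unweighted by default);
factors of 10 and 80 bracket the values used in cohort risk analyses.
Surrogate evaluation covers the legacy pairs (extrathoracic→skin,
prostate→urinary bladder wall, gall bladder wall→pancreas,
esophagus→stomach wall) plus the shielded-air-KERMA skin surrogate, which
by construction is constant across phantom ages.  Scenario sweeps emit a
long-format organ x scenario x category table with quadrature-combined
errors and chart-ready nine-component stacks.

## Problem sizes and determinism

Default problem sizes are chosen for single-CPU runs: 1 cm voxels for
transport, 1e4–1e5 particles per statistical check, 1e6 draws for the
angle-sampling chi-square.  Every random stage takes an explicit seed
(generator, sampler, transport batches, acceptance script), and identical
seeds give byte-identical phase-space files and reports.

## Known limitations

* Deposit-and-kill photon transport has no buildup, so deep-organ doses
  are systematically lower than coupled transport would give; survival
  mode mitigates but keeps energy fixed at scatter.
* Thermal-neutron dose is deliberately throttled by the energy-conservation
  clip (capture Q excluded).
* The stylized phantom is a reconstruction, not the original coefficients;
  marrow fractions, response functions and interaction tables are synthetic
  or approximate and labelled as such in their files.
* Only standing, hypocenter-facing geometry is modelled; kneeling and
  factory shielding configurations are out of scope.
* The MCPL writer targets the public format's structure but has not been
  validated byte-for-byte against the reference C implementation.
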