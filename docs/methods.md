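# Methods

This note documents the models, parameter choices and numerical decisions in
pregdose, and what the synthetic test bed does and does not establish about
real patient dosimetry.

## Synthetic phantom

Organs are closed analytic solids (ellipsoids, capsules, boxes, spherical
shells) placed in a simplified trunk: a soft-tissue capsule envelope
(radius 175 mm) containing the maternal organs, a gravid uterus ellipsoid
with an amniotic sac, placenta and umbilical cord, and a fetus ellipsoid
holding 20+ fetal structures.  Placement coordinates live in one editable
layout file (`data/layout_reference_9mo.json`); they are package-invented
constants — the placenta/amniotic/cord arrangement in particular is
arbitrary, and organ shapes make no claim to anatomical realism.  Primitives
flagged `size_from_mass` are rescaled isotropically so volume equals
target mass / density; container organs (uterus, amniotic sac, fetus body)
keep fixed layout dimensions, and their bulk masses are emergent rather than
adjusted (the synthetic uterus wall is consequently much heavier than a real
near-term myometrium — a geometric artifact of wrapping an ellipsoid shell
around an off-center sac; it is excluded from mass-matching claims).

Masses: each organ carries the reference target mass of the structure it
stands in for.  Paired structures (kidneys, ovaries, lungs, eyes, adrenals,
salivary glands) split their roster mass equally.  The salivary glands are
absent from the reference mass table; 70 g total is a package default.
Fetal target masses sum to 3471.8 g, 0.8% below the 3500 g reference
newborn, matching the published fetal total.  Materials are ICRP-style
densities and 4–6-element compositions; fetal lungs carry a fluid-filled
density of 1.04 g/cm³ (fetal lungs are not aerated).

Scene validation is sampled: organ-interior points must fall inside the
envelope and inside the nesting parent's primitive.  Sibling organs are laid
out disjointly; residual boundary slivers are resolved deterministically by
paint order and corrected by mass adjustment.

## Voxelization and mass adjustment

A voxel takes label L iff its center lies inside L's primitive (boundary
points count as inside; the effect is measure-zero).  Children are painted
only where the parent's label is present, which enforces nesting on the
lattice; the deepest nesting level therefore wins in overlaps.  Walls are
peeled with 6-connectivity — one pass relabels every organ voxel adjacent to
a non-organ label, repeated n times — immediately after the owning organ is
painted, so interior organ boundaries never grow walls.  26-connectivity
would over-peel corners.

Mass adjustment: the target voxel count is round(target mass / voxel mass);
voxels are removed from the exterior layer (relabeled to the majority
non-organ neighbor) or added on surrounding-region voxels 6-adjacent to the
organ, in deterministic order (descending distance from the initial organ
centroid, ties lexicographic by index).  Contents organs grow into their
wall; walls grow into the organ's surroundings; adjustment runs contents
before walls so wall masses are finalized last.  The loop stops within half
a voxel mass, giving |mass − target| ≤ 1 voxel mass and idempotence.  At the
default grids (1 mm fetal, 2 mm maternal) the residuals are below 0.1%,
comfortably inside the 0.3% (fetal) and 1% (maternal) tolerances quoted for
the reference phantom.

## Biokinetics

The iodide-in-pregnancy model has 13 compartments: blood iodide exchanging
with an extracellular pool; competitive clearance to the thyroid and (via a
fast kidney transit) to urine; salivary and gastric secretion into the
stomach → small intestine → blood reabsorption loop; thyroid organification
with slow hormone release (T½ ≈ 80 d) to an organic pool exchanging with the
liver, deiodinating back to blood and losing a small biliary fraction to
feces; and transplacental exchange with a fetal pool feeding an avid fetal
thyroid.  Blood, ECF and the organic pool map onto the "remaining tissues"
source region.

Cumulated activities are the exact linear solve Ã = (λ_p I − K)⁻¹ A0
(columns of K sum to zero — every sink is explicit — so Σ Ã λ_p = 1: each
atom decays exactly once).  Adaptive ODE integration of the same system is
retained purely as an independent test oracle.

**Maximum thyroid uptake F.**  The blood→thyroid rate is not a constant: it
is solved (Brent root find) so that, with decay off and thyroid release
switched off, the asymptotic trapped fraction equals F.  This is the
operational definition of "maximum uptake" and accounts for recycling
through the gut and ECF.  The fetal thyroid is treated as a trap on the same
timescale.

**Rate constants.**  The published pregnancy model does not print its
transfer constants, so the bundle `data/iodide_rates.json` holds editable
package defaults at physiologically conventional values (renal iodide
clearance 3 d⁻¹, gastric + salivary secretion 7 d⁻¹ with complete
reabsorption, kidney transit ≈ 5 min, transplacental transfer 0.105 d⁻¹
against 1 d⁻¹ back-transfer, fetal thyroid trapping 2 d⁻¹).  They reproduce
the published trends across the seven uptake levels (maternal thyroid
rising, fetal thyroid / stomach / salivary falling, liver rising) and land
close to the published I-131 magnitudes at 25% uptake (thyroid 61.4 h vs
62.6 h; fetal thyroid 4.34 h vs 4.42 h; bladder 1.34 h vs 1.33 h); the
remaining-tissues residence runs ~40% above the printed value, an accepted
compromise of the simplified ECF/organic split.  No claim is made that
these are the original constants.

**Bladder.**  Urine inflow (the kidney→urine flux, evaluated from the eigen
decomposition of the system) accumulates in the bladder, decays physically
and empties on a fixed clock (default 3.5 h interval, first void 3.5 h — a
conventional adult assumption; the source publication does not state its
value).  The integral is computed per void interval with an adaptive ODE
solver (rtol 1e-10) over a 15-half-life horizon; the test oracle is
forward-Euler event stepping at dt = 1e-3 h.  Oral-vs-IV administration
delay is ignored (minutes against multi-hour kinetics).  Tc-99m has no
computed model; its cumulated activities come only from the transcribed
reference tables.

## Decay data

Per-nuclide line lists (CSV fixtures, sha256-guarded) carry nominal
energies/yields transcribed from standard ENSDF-derived compilations;
daughter ingrowth (I-131 → Xe-131m) is ignored.  Conditioning policies:
yields ≤ 0.1% dropped (applied per line; whether the original work cut per
line or per group is unstated), Auger groups collapsed to their
yield-weighted average energy, conversion subshells to the subshell-maximum
energy with total yield.  Beta branches use the allowed shape
p·W·(E_max−E)² times the nonrelativistic point-charge Coulomb factor
F = 2πη/(1−e^(−2πη)), η = ±Z α W/p — the minimal reading of "the Fermi
function"; the relativistic screened correction is a flagged extension.
Spectra are binned at 1 keV by default (sub-0.1% moment accuracy).  I-123's
β+ branch is negligible; positrons and annihilation photons are not
implemented.

## Transport

Analog photon Monte Carlo on the labeled lattice: exact DDA voxel
traversal, free paths from the local linear attenuation, photoelectric
absorption ends the history, incoherent scattering samples the
Klein–Nishina ratio by Kahn rejection on free electrons.  Coherent
scattering and pair production are omitted — a documented narrowing
relative to a general-purpose code, defensible for 18–723 keV tissue
transport.  Scoring is the track-length kerma estimator: a segment of
length t in material m adds t·E·(μ_en/ρ)_m·ρ_m, i.e. the expected energy
transferred along the segment, assuming secondary electrons deposit
locally.  Energy bookkeeping for the conservation audit is analog (photo
deposits E, Compton deposits E−E′, sub-cutoff photons are counted as
discarded, boundary crossings as escaped), so emitted = deposited + escaped
+ discarded holds to float precision per run; the kerma tally itself is an
estimator and is bounded by the emitted energy only in expectation.
Transport is fully analog — no weights, no Russian roulette; the 2 keV
default cutoff simply terminates histories.

Electrons default to local deposition: at the beta mean energies involved
(≤ ~0.4 MeV) the CSDA range in soft tissue is ≲1.3 mm, below or near one
voxel, so the self-organ dose is exactly E/m and cross-organ electron dose
is zero.  The `csda` mode spreads the energy uniformly in mass-thickness
along a straight line of length equal to the density-scaled Katz–Penfold
range, for sensitivity checks.  Bremsstrahlung is ignored (sub-percent
radiative yield at these energies).

Cross sections are generated from elemental compositions: exact
Klein–Nishina total and energy-transfer cross sections (the latter by
quadrature of the differential), plus a Born-type photoelectric term
1.25·4√2·σ_T·α⁴·Z⁵·(m_ec²/E)^3.5, on a shared 160-point log grid
(1 keV–2 MeV) with log-log interpolation.  These analytic tables keep the
package dependency-free at run time; they approximate evaluated libraries
to a few tens of percent in the photoelectric-dominated region, which
shifts absolute doses but none of the structural results (linearity,
trends, ratios, conservation).  K-edges are not modeled (all edges of the
constituent elements lie at or below the grid floor except calcium's
4 keV, which matters only for sub-5-keV transport in bone).

Randomness: one master seed; each history derives a splitmix64 substream
from (seed, history index), so results are bit-reproducible and independent
of execution order.  Relative errors are per-history sample standard errors.

## Dose assembly

S(T←s) sums per-particle specific energies over all lines weighted by
yield; beta branches run at their spectrum-mean energy (exact under local
electron deposition, where dose is linear in energy).  Organ doses apply
the exact unit constant 3600·10⁶·1.602176634e-10·10³ ≈ 576.78.  The
whole-fetus summary row is the mass-weighted mean of fetal-region doses
(equivalently total fetal energy over total fetal mass) — a definition this
package fixes explicitly, tested against the voxel-tally identity.  When a
cumulated-activity set lacks the fetal thyroid as a source (the stylized
reference sets), the fetus is treated as a single uniform source region;
activity in source regions absent from the phantom (colon segments, feces)
folds into residual tissue, and percent differences always name their base.

## Synthetic test bed: scope of the evidence

The generator reproduces the *structure* of the published study — organ
roster, reference masses, source regions, uptake levels, table schemas —
but not patient anatomy, organ shapes or inter-organ distances.  Passing
tests therefore establish correctness of the algorithms (classification,
peeling, adjustment, solvers, estimators, unit chains) and of in-table
arithmetic, and directional physics (self-absorption of the fetal thyroid,
uptake trends); they do not validate absolute organ doses for a real
patient, which require the MR-derived phantom, evaluated cross sections and
condensed-history electron transport.  Default problem sizes (1–4 mm grids,
10³–10⁵ histories) were chosen so the full suite exercises every code path
at interactive speed.

## Known limitations

- Uterus wall, amniotic fluid, cord and fetal soft tissue masses are
  emergent, not matched.
- Kidney cumulated activity is a model transit value, near but not exactly
  the tabulated 4.8 min at every uptake level.
- The decay fixtures are nominal transcriptions, not an ENSDF parse.
- Marrow/endosteal weighting uses a packaged active-marrow fraction table
  applied to skeletal-site doses; the synthetic skeleton has no
  microstructure.
- `csda` electron mode ignores scattering detours (straight-line range).
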