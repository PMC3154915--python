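# Methods

This note documents the model, the synthetic-data assumptions, the
numerical choices and the known limitations of `granuflux`.

## 1. Granule energetics model

### State and geometry

A single spherical granule (default radius 150 nm, specific capacitance
1 µF/cm², hence membrane area 0.283 µm², volume 1.41 × 10⁻²⁰ m³ and total
capacitance 2.83 fF) exchanges ions with a fixed cytosolic reservoir.  The
integrated state is the net transported charge (as mol of elementary
charge per granule volume), luminal pH, and luminal glutamate, Na⁺, K⁺ and
Cl⁻ in mM.  The membrane potential ψ (lumen minus cytosol) is derived
algebraically as Q/C at every evaluation, never integrated separately, so
the charge-conservation identity C·ψ(t) − C·ψ(0) = F·∫Σzᵢ Jᵢ dt holds by
construction and is additionally verified in the test suite against
independently integrated per-pathway mole counters.

Free luminal H⁺ is tied to pH; pumped protons change pH through a constant
buffering capacity β (default 40 mM/pH unit, a typical organellar value),
so d(pH)/dt = −(net H⁺ influx / volume)/β.

### Rate laws

Main-text-level descriptions of such transport systems give stoichiometries
and qualitative behaviour rather than kinetic detail, so each carrier uses
the minimal thermodynamically consistent saturating form

    J = Jmax · tanh(ΔG / 2RT),

which is exactly zero at the carrier's equilibrium, has the sign of its
driving force everywhere, and saturates at Jmax.  Any rate law with those
three properties produces the same qualitative scenario comparisons; no
kinetic constants are fitted to data.

* **V-ATPase** (forward-only): ΔG = −ΔG_ATP − n_H (Fψ + RT ln([H⁺]_L/[H⁺]_c)),
  clipped at zero beyond the stall point.  Defaults n_H = 2 H⁺/ATP and
  ΔG_ATP = −57 kJ/mol give a stall potential −ΔG_ATP/(n_H F) ≈ +295.4 mV at
  equal pH, consistent with a membrane that polarizes "to over +200 mV"
  when the pump is the only pathway.
* **VGLUT**: electrogenic glutamate⁻ uniport, ΔG = F(ψ − E_glu) with
  E_glu the glutamate Nernst potential, times a cytosolic saturation
  glu_c/(glu_c + Km), Km = 5 mM.
* **EAAT2** (fully reversible): one export cycle carries 1 glu⁻ + 3 Na⁺ +
  1 H⁺ lumen→cytosol and 1 K⁺ cytosol→lumen; the net charge leaving the
  lumen per cycle is 3 + 1 − 1 − 1 = +2, so the electrical term in the
  cycle free energy is −2Fψ.  Species fluxes are returned per cycle
  exactly as (glu, Na, H, K) = (−v, −3v, −v, +v) into the lumen.
* **Optional Cl⁻ channel / cation leak**: linear conductance g·(ψ − E),
  both disabled by default so the three canonical scenarios contain only
  the pump and the two glutamate carriers.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| granule radius | 150 nm | mid-range dense-core granule profile (250–350 nm diameters) |
| specific capacitance | 1 µF/cm² | standard biological membrane value |
| β (buffering) | 40 mM/pH | typical organellar buffering capacity |
| T | 310.15 K | body temperature |
| ΔG_ATP | −57 kJ/mol | cellular phosphorylation potential |
| n_H per ATP | 2 | gives the ≈ +295 mV stall consistent with the > +200 mV plateau |
| cytosol pH / glu / Na / K / Cl | 7.2 / 3 / 15 / 140 / 40 mM | standard cytosolic composition; 3 mM glutamate anchored to the calibrated low-millimolar estimate |
| initial lumen pH / glu / Na / K / Cl | 7.2 / 0.01 / 70 / 30 / 40 mM | unenergized granule; luminal Na⁺ set high (granules are Na⁺-rich) so the EAAT2 export cycle is exergonic once the pump has polarized/acidified the granule — a tested property, not an assumption |
| pump/VGLUT/EAAT2 Jmax | 2×10⁻²⁰ / 1.5×10⁻²¹ / 1×10⁻²⁰ mol/s | see below |

The maximal rates correspond to ~12 000 H⁺/s, ~900 glu/s and ~6 000
cycles/s per granule — plausible for tens of pump complexes and a handful
to tens of transporter copies at single-carrier turnovers of 10²–10³ s⁻¹.
Within the 300-s simulation window the VGLUT rate also keeps the
cumulative 3-Na⁺-per-glutamate cost of EAAT2 export within the finite
luminal Na⁺ pool: the model has no Na⁺ replenishment pathway, so a much
faster VGLUT would exhaust luminal Na⁺ mid-run and stall the export limb —
a regime outside what the model is meant to represent.  The scenario
orderings are robust to ±50 % one-at-a-time changes of each Jmax (tested).

### Numerical choices

* LSODA (stiff-capable, adaptive) with rtol 10⁻⁸; absolute tolerance
  10⁻¹⁰ for the physical states and 10⁻²⁸ for the cumulative mole
  counters, which live on the 10⁻²⁰ mol scale.
* Default horizon 300 s with 1 001 output points.  The ATPase-only
  scenario converges in ~1 s of model time; the VGLUT-containing scenarios
  still drift slowly at 300 s (their true equilibrium is an unphysically
  acidic lumen that the kinetics approach only over hours), so the
  steady-state summary is defined as the mean over the final 10 % of the
  run, with an explicit convergence flag rather than a silent assumption.
* A concentration floor of 10⁻³ mM inside logarithmic terms keeps Nernst
  and cycle free energies finite when a luminal pool empties.  In
  addition, each *efflux* limb of a reversible carrier is multiplied by a
  smooth availability factor c/(c + floor) for the species it drains; this
  prevents integration below zero, preserves the sign and equilibrium-zero
  properties of each flux law, and leaves steady states above the floor
  unaffected.  Free [H⁺] is exempt (it is buffered and represented by pH).
* t_end = 0 returns the initial state; non-finite fluxes raise immediately
  with a state dump; a failed integration raises naming the last state.

## 2. Synthetic immunogold sections

### What is emulated

One "section" is a 2-D cell profile (irregular smooth outline, default
25 µm² for rat cells, 12 µm² for the smaller mouse design) containing
non-overlapping circular organelle profiles: secretory granules (diameters
250–350 nm; limiting-membrane band ±30 nm around the outer radius), SLMVs
(35–45 nm), and mitochondria (500–700 nm), plus the plasma-membrane band
and cytosol, in a rectangle of empty resin.  Packing enforces ≥ 80 nm
edge-to-edge clearance so bands and halos never overlap and every point
has exactly one compartment.

Gold labelling is simulated as independent homogeneous Poisson processes:
one per compartment at its *net* intensity (particles/µm²), plus one
uniform background process over the entire section.  For each antigen
class the generating region equals the region the counting rule measures —
granule profile for soluble antigens, the halo-inclusive disc for SLMVs,
60-nm bands for membrane antigens — which is exactly the condition under
which the density estimator is unbiased.  Every particle keeps a
provenance tag naming its generating process, used only by oracle tests.

### Study-condition presets

| preset | granule | cytosol | SLMV | background | design |
|---|---|---|---|---|---|
| rat_alpha | 33.6 | 21.1 | 100* | 1.7 (resin) | 5 cells × 30 granules |
| rat_beta | 19.7 | 30.2 | 100* | 1.7 | 5 cells × 30 granules |
| mouse_wt | 9.0 | 12.2 | 60* | 1.7 | 4 animals × 5 cells × 9 granules |
| mouse_ko | 17.7 | 10.5 | 60* | 1.7 | 4 animals × 5 cells × 9 granules |

Granule/cytosol values are the published net glutamate densities for these
conditions; the mouse design gives ≈ 45 granules per animal, the scale of
the published 119-/179-granule samples.  Values marked * are not printed
anywhere (SLMV densities are reported only as "much higher" than the
rest); they are fixed defaults chosen once to realize that ordering, and
nothing quantitative is asserted about them.  Membrane-antigen presets
(EAAT2/VGLUT3) expose the published background constants (3.7/1.3 over
mitochondrial outer membranes, 4.9/2.7 over matrix) but generate a single
uniform background stream.

What the generator does **not** emulate: biological cell-to-cell variation
(the published SDs include it; synthetic replicate scatter is Poisson
only), particle clustering or antibody-efficiency gradients, irregular
organelle shapes, section-thickness effects, and any pixel-level imaging
or detection step.  Passing recovery tests therefore show that the
*pipeline arithmetic* is unbiased under its own sampling assumptions, not
that those assumptions hold on real micrographs.

### Calibration test sections

Test sections with known glutamate concentrations are simulated as areas
whose expected density is intercept + slope·concentration with Poisson
counts — the "close to linear" regime of amino-acid test sections.
Calibration fits are ordinary least squares; the intercept is dropped
(through-origin fit) when it is within 2 SE of zero, and both fits can be
forced.  Inverse prediction propagates slope/intercept uncertainty by the
delta method and refuses densities below the intercept of a
through-origin fit.

## 3. Quantification pipeline

* **Assignment**: SLMV halo (≤ 30 nm from the outer border, boundary
  inclusive) > membrane bands (± 30 nm) > granule core > mitochondrion >
  cytosol; outside the cell is resin.  The precedence of the SLMV halo
  over membrane bands is a documented choice (the published counting is
  halo-inclusive but silent on precedence) isolated in one classifier.
  Soluble antigens use profile containment for granules and mitochondria;
  membrane antigens use the band rule.
* **Areas**: regular point grid (default 20 nm spacing; half-spacing
  offset) classified with the same rule; area = hits × spacing².  Analytic
  areas are exposed as the oracle; membrane-band areas equal trace length
  × 60 nm up to curvature terms.
* **Densities**: raw = count/area; net = raw − background, with the
  background stream selected by compartment class (resin for amino acids;
  mitochondrial outer membrane for membrane compartments and matrix for
  interior compartments of protein labellings).  Negative nets are
  preserved and flagged — clipping would bias recovery upward.
* **Ratios/statistics**: per-cell granule/cytosol and SLMV/cytosol ratios
  (cells with non-positive cytosol net excluded with a warning); group
  mean ± SD and SEM; two-tailed Mann–Whitney U, exact permutation null for
  group sizes ≤ 20 without cross-group ties, normal approximation
  otherwise.  Mouse comparisons pool counts and areas within each animal
  before subtraction and test across the 4 animals, matching the published
  per-animal design.  Because mean-of-per-cell-ratios ≠
  ratio-of-pooled-means, both statistics are reported side by side.

## 4. Problem sizes used in checks

The recovery checks rerun each preset's complete study design 50 times
with independent seeds and compare the mean recovered granule net density
against its generating value on the SEM-across-replicates scale; with the
default designs this is ~250 rat cells or ~1 000 mouse cells per preset
and runs in a few minutes.  The 20-nm default grid keeps area noise well
below Poisson counting noise; the 10-nm grid used in the area-accuracy
check reaches < 2 % error on a 300-nm-radius profile.  Scenario checks use
the full 300-s horizon; conservation identities are verified on a 120-s
three-transporter run sampled at 601 points.

## 5. Known limitations

* No kinetic detail of transporter conformational cycles; tanh rate laws
  are a declared stand-in for unavailable kinetic forms.
* No osmotic volume dynamics, no Donnan binding to the dense core, no Na⁺
  replenishment pathway; the cytosol is an infinite reservoir.
* Whether the canonical runs should include a Cl⁻ conductance alongside
  VGLUT is left off by default (the pathway is implemented and can be
  enabled per scenario).
* Planar densities only — no 3-D stereological corrections, matching the
  per-µm² reporting convention of the source measurements.
* The simulated durations of the scenario comparisons are a package
  default (300 s); conclusions are drawn from steady-state summaries and
  orderings, not from absolute time courses.
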