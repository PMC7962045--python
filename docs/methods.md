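# Methods

## Thermal model

The package solves the steady Pennes bioheat equation

∇·(k ∇T) + ρ_b C_p,b ω_b (T_b − T) + Q_met = 0

on a voxelized slab. Dropping the time derivative is deliberate: the
quantity of interest is the stationary temperature contrast between a
lesioned and a healthy foot under fixed ambient conditions, not gait-cycle
transients. Radiation, sweating and counter-current vascular effects are
not modeled.

**Geometry.** The anatomical foot is replaced by a rectangular slab: the
layer stack and the lesion depth, not the foot outline, drive the
plantar-surface physics. The z axis points downward from the deep muscle
face through muscle (25 mm), fat (5 mm), reticular dermis (1.67 mm),
papillary dermis (1.67 mm) and epidermis (0.46 mm) to the plantar skin,
then through the insole (1 mm polyurethane, 0.36 mm kapton, 18 µm copper,
3 mm polyurethane) and a 15 mm rubber sole to the floor. Grid lines sit
exactly on every layer interface.

**Foot–insole contact patch.** A full-contact slab cannot reproduce the
reported field structure of the original device study: with cooling only
through the floor path, at most ~23 % of the 37 → 20 °C drop can occur
below the insole top surface, which pins that surface near 35 °C — while
the reference field shows the insole surface an order of magnitude closer
to ambient (~24 °C). The physical reason is that a real insole extends
beyond the foot and its uncovered surface exchanges heat with the ambient
air. The default configuration therefore restricts the tissue stack to a
rectangular contact patch of 0.215 m × 0.052 m ≈ 112 cm² — a typical
adult static plantar contact area — centered on the 0.26 m × 0.09 m
insole footprint; insole and sole span the full footprint. The uncovered
insole top and the foot's side walls receive the same Robin condition as
the floor (h = 5 W/m²/K, 20 °C). Setting `contact_patch: null` recovers
the plain full-contact slab. With the patch, the healthy baseline puts the
muscle region at 36.4 °C and the insole-surface average at 28.3 °C
(covered region ~31 °C, exposed region ~24 °C); the rectangular-patch
idealization is the main reason the surface average sits a few degrees
above the anatomical-model reference, since a real contact patch feathers
out toward the arch and toes.

**Boundary conditions and the sock.** Floor: Robin, h = 5 W/m²/K at
20 °C. Deep tissue face: adiabatic — the perfusion sink anchors deep
muscle near T_b + Q_met/(ρ_b C_p,b ω_b) ≈ 37.07 °C without imposing it.
Slab side walls: adiabatic. The sock is an area-specific contact
resistance R = 0.02 m²·K/W inserted in the face conductance across the
skin–insole interface. The source prints this value in conductivity units
(W/m/K) while calling it a thermal resistance; we read it as m²·K/W, the
magnitude of a thin worn sock. Blood properties are not part of the
published tissue tables; the standard 1050 kg/m³ and 3617 J/kg/K are used
and configurable — the muscle equilibrium offset depends directly on them
(684.2/(1050·3617·0.0027) ≈ 0.067 °C above T_b).

**Lesion.** The reported lesion is "irregular" with height 0.25 cm and
volume 1.5 cm³; those two printed constraints define an oblate ellipsoid
with c = 1.25 mm and a = b ≈ 16.9 mm, embedded by reassigning tissue
cells whose centers fall inside it (clipped to the tissue sub-domain),
laterally centered under sensor S4. All 26 sweep cases share one grid, so
lesion-vs-healthy ΔT is free of discretization-difference noise; a control
"lesion" made of the surrounding tissue changes nothing, exactly.

**Discretization and solver.** Cell-centered finite volumes with
harmonic-mean (series-resistance) face conductances handle the 4
orders-of-magnitude conductivity contrast (copper vs polyurethane)
robustly. The linear system is symmetric positive definite; it is solved
by sparse LU up to ~300 k unknowns and diagonally preconditioned CG above
(relative residual 1e-10). Each solve records boundary fluxes per face
group, an energy-balance audit (|outflow − sources| over the larger of
|sources| and gross throughflow; ≤1e-9 in practice) and a discrete
maximum-principle check against the coldest/hottest anchors
(environment temperatures, blood temperatures, perfused equilibria).

**Default resolution.** Lateral 4 mm in the packaged study configuration
(2 mm in the generic geometry default); vertical 0.5 mm over the 12 mm
depth band containing all lesion positions, 2.5 mm elsewhere, minimum 3
cells per layer (epidermis cells ≈ 0.15 mm). A refinement study
(dx 4→3 mm, dz_fine 0.5→0.25 mm) moves sensor ΔT by < 0.01 °C, so the
categorical detectability outcomes below are grid-converged; the 26-case
sweep then takes a few minutes and < 1 GiB. Against the closed-form 1-D
oracle on the laterally uniform stack the 3-D solver is within 0.01 °C at
default vertical resolution, with second-order error decay under
z-refinement.

## 1-D analytic oracle

Within each layer the steady equation has the closed form
T = T_eq + A e^{−m t} + B e^{−m(L−t)} (perfused; m = √(ρ_b C_p,b ω_b/k),
T_eq = T_b + Q_met/(ρ_b C_p,b ω_b)) or a quadratic (non-perfused).
Coefficients come from interface continuity of temperature and flux (with
a contact-resistance jump at the sock plane) plus the outer boundary
conditions. The decaying-exponential basis keeps all basis values in
(0, 1] regardless of m·L, so thick strongly perfused layers cannot
overflow. The interface system mixes O(1) temperature rows with O(k/L)
flux rows; row equilibration plus two iterative-refinement steps restore
interface continuity to ~1e-12 relative. The oracle is cross-checked
against an independent 10⁴-node finite-volume solve (< 1e-4 °C).

## Sensor readout and detectability

Sensors are read in the first insole cell below the skin–insole interface
at the cell center nearest each sensor (x, y) (first-minimum tie rule).
The sensing pad is taken to be thermally shorted to the insole contact
surface through its conductive-paste via; reading at the kapton plane
instead would differ by the drop across the upper polyurethane layer.
Detectability is |ΔT| ≥ 0.1 °C, boundary inclusive, with ΔT always taken
against the baseline with the same sock setting.

The default 8-sensor layout follows the usual plantar pattern (hallux,
three metatarsal heads, midfoot, heel), scales linearly with foot length
(supported range 0.20–0.32 m) and is fully user-overridable; exact
coordinates are schematic. S3 and S5 are the two nearest neighbors of S4,
which the depth sweep exploits.

## What the model finds — and its limits

With the published tissue/lesion parameter set the simulation reproduces
the qualitative inflammation picture: ΔT is positive, decays
monotonically with depth, is maximal at the nearest sensor (S4) with
S3/S5 next in every case, and the sock damps the signal at the detecting
sensors. Two findings differ from the original report and are properties
of the parameter set in this geometry, not numerical artifacts (they
survive grid refinement):

* Inflammation at 9.7 mm is detectable without a sock (+0.13 °C at S4)
  but falls just short of the 0.1 °C threshold with one (+0.09 °C).
* An ischemic lesion is *more* visible at muscle depth (−0.22 °C at S4)
  than in the fat layer (−0.13 °C): in fat its properties are nearly
  those of fat (ω 4.05e-4 vs 0.8e-4 1/s, Q_met 342 vs 368 W/m³, k 0.1 vs
  0.185 W/m/K), while in muscle it removes a strong perfusion anchor
  (ω 2.7e-3, T_b 37 °C) and blankets it with insulation, so ischemic
  detectability is non-monotone in depth and not confined to the
  reticular/fat band. The sock can also slightly *increase* |ΔT| at far,
  sub-threshold sensors by redistributing the signal laterally.

## Synthetic bench data

The bench measurements behind the sensor characterizations are not
deposited, so the calibration modules are validated on synthetic data with
known ground truth:

* **Charge–force**: Q = d33·F + ε, d33 = 4.5 pC/N, Gaussian ε
  (σ = 0.5 pC) over the quasi-static 0–4 N range.
* **Voltammetry**: triangular sweeps per the bench protocol (start
  +0.5 V, high +1.0 V, low −1.2 V, 4 scans, 0.1 V/s), a Gaussian anodic
  peak at +0.72 V (σ = 0.03 V) on a sloping linear baseline, current
  noise σ = 0.02 µA, and gain 2.5 µA/mM through a saturating response
  that is linear to 6 mM, flat from 6 to 10 mM and linear again to
  24 mM — mirroring the reported calibration structure. Peak currents are
  read on the final anodic scan (conditioning sweeps discarded) with a
  linear baseline through the window edges, which makes extraction
  exactly invariant to any global linear baseline; a window ≥ 6 peak
  widths (default 0.24 V) recovers the peak height within 2 %.
* **Blanks**: replicate zero-concentration traces; the LOD uses the
  standard deviation of ≥ 10 blank peak extractions (closest to the
  blank-based IUPAC definition) rather than fit-residual σ, with the
  multiplier fixed at 3.3 (configurable).
* **Tissue perturbations**: each positive parameter scaled by an
  independent uniform factor in [1−f, 1+f]; exact zeros (epidermis
  perfusion) are preserved.

All generators are deterministic under a fixed seed. What passing these
tests shows is that the *pipeline* recovers known structure at realistic
noise levels; it says nothing about the accuracy of any particular bench
instrument, and the published bench figures (LOD 3.27 µM, 21 µA/mM·cm²)
are context, not reproduction targets — the raw data and electrode area
behind them are unpublished. "Normalized current peak" responses are
normalized by the maximum in-series peak when requested; the original
normalization is unspecified.

## Numerical conventions

Temperatures are °C throughout (the equation is affine in T, so no Kelvin
conversion is needed); lengths SI, with an mm option in config files.
OLS fits estimate the intercept rather than forcing zero, so baseline
offsets in synthetic QA are visible. Linear-range detection grows windows
(≥ 4 points) greedily from the low-concentration end and restarts after
each accepted window or failed start; flat or duplicate-concentration
windows score r² = 0. CSV reports round temperatures to 3 decimals and
embed the configuration fingerprint; writes are temp-then-rename atomic.
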