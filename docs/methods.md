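# Methods

`ventilam` simulates the chain of events by which positive-pressure
mechanical ventilation provokes an innate immune response in airway
tissue: a ventilator waveform drives air through a bifurcating airway
tree, the resulting lumen pressures stretch the layered airway wall, the
wall strain activates immune cells in a stochastic cellular model, and
the scar tissue (fibrosis) that the episode leaves behind stiffens the
wall material, closing the loop. The three stages are deliberately
decoupled — each is a self-contained model exchanging scalar boundary
data with the next — so any stage can be replaced or run standalone.

## Organ stage: lumped ventilation model

The conducting tree is a symmetric Weibel-type cascade, generations 0-7,
with `2^g` identical parallel branches per generation. Geometry defaults
(lumen radius 9.0 mm at the trachea down to 1.15 mm at generation 7,
lengths 120 mm down to 7.6 mm) are stored in a versioned CSV fixture and
are freely overridable; wall-layer thicknesses are fixed fractions of
the lumen radius (epithelium 5 %, connective tissue 10 %, smooth muscle
15 %), chosen as representative of bronchiolar wall architecture.

The ventilator delivers a tidal volume V_T = 420 ml with inspiration
time T_in = 0.4 s and expiration time T_ex = 2.0 s. Inspiratory flow is
a rising exponential

    Q(t) = A (1 − e^(−t/τ)),  τ = T_in / 5,

with A fixed in closed form so the inhaled volume is exactly V_T.
Expiration is the passive profile Q(s) = (Q_end − B s/τ_ex) e^(−s/τ_ex)
with τ_ex = T_ex / 5, continuous with the inspiratory flow at the
transition, and B fixed in closed form so the expired volume equals V_T
exactly. Volume is therefore conserved over every cycle by construction
(verified to 10⁻⁶ relative tolerance by quadrature in the tests).

Each branch is a Poiseuille resistance ΔP = 8 μ L q / (π r⁴) with air
viscosity μ = 1.79×10⁻⁵ kg/(m·s); flow splits evenly at every
bifurcation, and node pressures accumulate from the distal outlet
boundary (gauge 0 by default) upward. The network is linear in the
inlet flow, and pressure decreases monotonically with generation
whenever flow is inspiratory. This is a deliberate desk-scale
replacement for a resolved 3D fluid–structure computation: it drops
inertial and turbulent losses, so absolute pressures are underestimates
of clinical airway pressures, but the generation-wise pressure drop —
the quantity the downstream stages consume — is reproduced. With the
default breath, peak lumen pressures run from ≈11.6 Pa at the trachea
to ≈1.0 Pa at generation 7.

## Tissue stage: layered hyperelastic annulus

The airway wall cross-section is an axisymmetric three-layer annulus
(epithelium, connective tissue, airway smooth muscle) in plane strain,
loaded by lumen pressure on the inner boundary and tethered by an
elastic foundation (traction −k·u, k = 600) on the outer boundary. At
desk-scale pressures the tether's influence is negligible, but it is
retained because it sets the correct boundary physics for stiffer
loading regimes.

The two inner layers are compressible Neo-Hookean,
W = (μ/2)(Ī₁ − 3) + (1/d)(J − 1)², with epithelium μ = 5 MPa, the
connective layer ten-fold softer (the stiffness ratio is exposed in
config, since the direction of the ratio is a modelling choice — we take
the epithelium-plus-basement-membrane side as the stiffer one), and the
volumetric parameter d = 2/K set for near-incompressibility (effective
Poisson ratio 0.49). The "shear viscosity" naming sometimes attached to
μ in the hyperelasticity literature is interpreted here as the
shear-modulus-like material constant of the strain-energy function; no
rate dependence is modelled. The smooth-muscle layer is linear elastic
with E = 99 MPa, ν = 0.45.

Inertia is dropped and the wall solved quasi-statically at the
peak-of-cycle pressure: breathing frequencies (≲1 Hz) are far below any
wall resonance, and the cellular stage consumes only a per-breath
strain scale. The solver minimises total potential energy (strain
energy, foundation energy, and an exact follower-pressure potential
−P·π[(a+u_a)² − a²]) over nodal radial displacements with linear 1D
finite elements (200 nodes by default, interface-conforming mesh,
two-point Gauss quadrature) and full Newton iteration with an analytic
tangent. Convergence is declared at a relative residual of 10⁻¹⁰ or at
the floating-point floor — the residual is a difference of terms of
order μ while its converged value is of order P, so for P/μ ≈ 10⁻⁶ the
achievable relative residual is bounded by machine precision times μ/P;
the solver detects this via increment stagnation rather than iterating
fruitlessly. Zero load returns the zero solution bit-exactly.

Verification: against the closed-form layered Lamé solution with
spring-modified outer boundary the solver agrees to well under 1 %, with
second-order grid convergence; stored energy matches the path integral
∫P dV of the ramped follower pressure to 1 %.

The scalar passed downstream is the thickness-averaged hoop strain of
the epithelial layer. Under the default breath this is 6.2×10⁻⁷ at
generation 4, 2.7×10⁻⁷ at generation 6 and 0.9×10⁻⁷ at generation 7.
These magnitudes inherit the deliberately low Poiseuille pressures; the
cellular stage's activation threshold is calibrated on the same scale,
so only the ratios between airways carry physiological meaning.

Feedback: after a cellular run, the fibrotic fraction f of the
epithelial population multiplies the Neo-Hookean constants of both
inner layers by (1 + α f). The gain α is not constrained by any
measurement we model; it defaults to 5 and is exposed in config. Since
μ′ ≥ μ, post-episode strain can only decrease.

## Cellular stage: stochastic automata

A bounded (non-toroidal) 100×100 lattice of epithelial cells — states
alive, dead, fibrosis — hosts 50 macrophages and 50 fibroblasts
performing chemotaxis-biased random walks, and two cytokine fields (TNF,
pro-inflammatory; TGF, pro-healing) obeying the explicit reaction-
diffusion update dC/dt = D∇²C − K·C with a five-point Laplacian and
zero-flux boundaries (D·dt/dx² = 0.1, comfortably inside the 0.25
stability bound; total mass decays exactly geometrically when nothing is
released). One step applies, in fixed order: agent movement (both kinds
climb the TNF field, sampling {stay, 4 neighbours} with weights
∝ e^(βC)), cytokine release (unit bolus; macrophage TNF release is
strain-gated and TGF-suppressed, fibroblast TGF release saturates in
TNF), diffusion–decay of both fields, and synchronous epithelial
transitions. All "probability determined by concentration" rules are
saturating Michaelis–Menten forms, which keep probabilities bounded and
monotone in the driving signal. Time is abstract ("steps"); no mapping
to wall-clock time is asserted.

The strain gate is a cubic smoothstep from ε_act = 1.9×10⁻⁷ to
ε_sat = 6.0×10⁻⁷: generation 7's strain sits below the threshold
(probability-1 quiescence — with no release possible and no initial
cytokines, the dead count is identically zero forever), generation 6
activates weakly (gate ≈ 0.10) and generation 4 saturates the gate.

Dead cells heal under TGF; cells continuously dead for τ_fib = 20 steps
while local TGF exceeds θ_fib = 0.002 convert to fibrosis with
probability 0.3 per step. Fibrosis is absorbing (scar): it neither
damages nor heals, and its terminal fraction is the bridge back to the
tissue stage. The fibrosis entry rule populates the model's third
epithelial state; its specific form (duration + TGF context) is a
design choice of this package.

Resolution mechanism: TNF is short-lived (K = 0.06 per step) while TGF
is nearly conserved (K = 2×10⁻⁵), so TGF acts as a long-lived
anti-inflammatory memory. Once the early TNF burst has driven
fibroblast TGF production, the accumulated TGF both suppresses further
macrophage release (half-saturation 0.001, i.e. strong suppression) and
heals quickly (p_heal = 0.8, half-saturation 0.03). This is what lets a
high-strain episode resolve permanently even though the strain stimulus
never goes away; without the lifetime separation the system settles
into a smouldering steady state instead.

Parameter defaults are a calibration, not a measurement: with the wall
strains the default pipeline produces, the high-strain ensemble (20
replicates) peaks at roughly 120-130 dead cells around step 35-40,
declines in the mean, and returns to zero well before step 10000;
the generation-6 ensemble peaks about five-fold lower; replicate-to-
replicate variability of the peak is low (CV < 0.25). The calibrated
values are plain dataclass defaults, all overridable.

Randomness: one `numpy.random.Generator` per run; a fixed seed
reproduces a run bit for bit. Ensembles derive replicate seeds from
`SeedSequence((master_seed, replicate))`, so replicates are independent
and the ensemble reproducible.

## What the defaults do and do not show

The synthetic study conditions emulate a ventilated adult lung's
conducting-airway geometry, a volume-controlled breath, and a tissue
section's innate immune response with a two-cytokine abstraction. They
do not include turbulent or inertial pressure drops, patient-specific
or asymmetric geometry, airway-wall buckling or viscoelasticity,
neutrophils or the wider cytokine network, spontaneous-breathing
(negative-pressure) ventilation, or any coupling of the CA back to the
breath within an episode. Passing tests therefore demonstrate internal
consistency of the multi-scale coupling and the qualitative
physiological orderings — not quantitative prediction for real
patients.

## Problem sizes

Default runs use a 100×100 lattice for 10 000 steps; ensembles use 20
replicates for standalone cellular studies and 5 replicates per airway
inside the case study. The wall solver uses 200 radial nodes; the
breath is sampled at 200 time points. These sizes were chosen so a full
case study completes in minutes on a single core while leaving the
ensemble statistics stable (peak-height CV well under 25 %).
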