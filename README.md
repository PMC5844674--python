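# ventilam

A desk-scale, multi-scale simulator of ventilation-induced airway
inflammation, for researchers studying ventilator-induced lung injury
and for modellers who want a transparent, fully scriptable alternative
to monolithic FEM/CFD pipelines.

Positive-pressure mechanical ventilation over-distends airway tissue;
the stretch activates innate immune cells, the resulting inflammation
kills epithelium and lays down fibrotic scar, and the scar stiffens the
tissue, changing its compliance. `ventilam` chains four components to
follow that cascade:

1. **organ_flow** — a ventilator waveform (tidal volume 420 ml,
   T_in = 0.4 s, T_ex = 2.0 s, exponential rise/decay) driving a
   symmetric Weibel-type airway tree (generations 0–7) modelled as a
   Poiseuille resistance network, ΔP = 8μLq/(πr⁴). Output: lumen
   pressure per generation over the breath.
2. **tissue_mech** — a plane-strain, three-layer annulus (Neo-Hookean
   epithelium with μ = 5 MPa and connective tissue, W = (μ/2)(Ī₁−3) +
   (1/d)(J−1)²; linear-elastic smooth muscle, E = 99 MPa) under lumen
   pressure with an elastic parenchymal tether on the outside, solved
   by 1D finite elements with Newton iteration. Output: mean epithelial
   hoop strain per airway.
3. **cell_ca** — a stochastic cellular-automata model on a 100×100
   lattice: strain-gated macrophages release TNF, fibroblasts answer
   with TGF, cytokines diffuse and decay (dC/dt = D∇²C − KC), epithelial
   cells die / heal / scar probabilistically, agents chemotax toward
   TNF. Output: the dead-epithelium count per step — the model's
   inflammation-severity readout — plus the terminal fibrosis fraction.
4. **pipeline** — couples the stages, runs the three-airway case study
   (G4-1, G6, G7), and feeds the fibrosis fraction back into the wall
   materials as stiffening, μ′ = μ(1 + αf).

## Worked example

```python
from ventilam import *
from ventilam.fixtures import default_morphology

morph = default_morphology()
tree = build_airway_tree(morph, max_gn=7)
profile = pressure_profile(tree, VentilatorWaveform())
print([round(float(p), 2) for p in profile.peak_pressures()])
# [11.56, 10.51, 9.53, 8.59, 7.22, 5.24, 3.1, 1.01]

sections = wall_sections(morph)
peaks = profile.peak_pressures()
strains = strain_for_airways({g: float(peaks[g]) for g in (4, 6, 7)}, sections)
print({g: f"{s:.2e}" for g, s in strains.items()})
# {4: '6.19e-07', 6: '2.66e-07', 7: '8.63e-08'}

ens = run_ensemble(StrainInput(level=strains[4]), CAParams(),
                   n_steps=10000, n_reps=20, seed=0)
m = ens.mean_dead
print(round(float(m.max()), 1), int(m.argmax()))
# 126.8 38
```

Reading: pressure falls monotonically down the tree (trachea 11.6 Pa to
generation 7 at 1.0 Pa, gauge, at peak inspiratory flow), so the
generation-4 airway is stretched most (hoop strain 6.2×10⁻⁷) while
generation 7 stays below the immune activation threshold. At the
generation-4 strain the 20-replicate ensemble-mean inflammation trace
peaks at ≈127 dead epithelial cells near step 38 and then resolves as
accumulated TGF suppresses further TNF release — the classic
rise-then-resolution course of an acute inflammatory episode. The
generation-6 strain produces a roughly five-fold smaller peak, and
generation 7 none at all.

The same case study, end to end with feedback and output files:

```
ventilam run --outdir out --seed 0
ventilam report --in out
```

A standalone cellular run at any strain:

```
ventilam ca --strain 6.2e-7 --steps 10000 --seed 42 --out trace.csv
```

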