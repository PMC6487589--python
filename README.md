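# canopydissect

Dissecting biomass accumulation of individual plants in **multi-genotype
canopies** into genetic and environmental components.

In heterogeneous canopies — phenotyping platforms, breeders' micro-plot
trials, variety mixtures — the classical Monteith decomposition of biomass
into radiation interception efficiency (RIE) and radiation use efficiency
(RUE) confounds a plant's genetics with the competition it happens to
experience, which collapses the heritability of both terms. This package
implements a per-plant revision of the Monteith equation:

```
ΔBM/Δt = R_i × RIE_plant × RUE / D
       = R_i × (LA × CI / CP) × (e^ε_RUE × e^(a·R_leaf + b)) / D
```

with, for plant *i* at density *D* (plants m⁻²) under incident flux *R_i*
(mol m⁻² d⁻¹):

* **RIE_plant = R_plant·D/R_i** — plant-level interception efficiency,
  computed with a voxel-grid Beer–Lambert light model over 3D plant meshes
  (0.2 × 0.2 × 0.1 m cells, 46-direction sky, clumping factor Ω = 0.8);
* **CP = LA_c/RIE_c** — *competition pressure*, an environmental index:
  mean leaf area over mean RIE in a 15-plant moving window centred on the
  plant; low at canopy borders, high inside a closed canopy;
* **CI = (RIE_plant/LA)/(RIE_c/LA_c)** — *competitiveness index*, the
  genetic part of interception: light captured per unit leaf area relative
  to the neighbourhood (1 = neutral competitor; taller plants score > 1);
* **ln RUE = a·R_leaf + b + ε_RUE** — RUE split into a panel-wide response
  to intercepted light per leaf area (*R_leaf*, µmol m⁻² s⁻¹) and a
  genotypic residual ε_RUE.

A synthetic-plant generator (parametric maize-like genotype panels), a
quantitative-genetics module (variance components, broad-sense heritability
H² = σ²_G/(σ²_G + σ²_e/r), trait correlations) and a virtual-field
simulator (single-genotype plots, 4-row micro-plots, row mixtures, random
mixtures) complete the pipeline, so the competitiveness *bias* that mixed
canopies introduce into genotype comparisons can be quantified in silico.

## Worked example

Simulate a random 9-genotype mixture, then dissect it:

```python
import canopydissect as cd
from canopydissect import fields
from canopydissect.light import LightEnvironment

panel = cd.generate_panel(9, variability={"final_leaf_area": 0.0}, seed=5)
lay = fields.layout("D", panel.genotype_ids, n_rows=12, plants_per_row=12,
                    row_spacing=0.2, plant_spacing=0.2, seed=5)
traj = fields.simulate(lay, panel, LightEnvironment(40.0), (-0.0025, 3.2),
                       t_range=(20, 50), step=10, replicate_noise=0.05, seed=5)
res = cd.CanopyDissection(traj.records, density=lay.density).fit()
print(res.summary())
```

```
Revised Monteith dissection
==========================================
plants: 144  genotypes: 9  days: 4
 RIE_plant (final day): mean   1.000  range [0.048, 3.767]
        CP (final day): mean   0.567  range [0.346, 1.182]
        CI (final day): mean   0.987  range [0.045, 3.747]
RUE response: ln RUE = -0.00248 * R_leaf + 3.226  (r2 = 0.899, n = 144)
eps_RUE range: [-0.0890, +0.0714]
```

Mean RIE_plant is 1 by construction in a closed mixture, but individual
plants range from 0.05 (overtopped) to 3.8 (dominant) — that spread is the
competition signal that CI captures (here mean 0.99, i.e. the panel is
balanced). The fitted light response recovers the coefficients the
simulation was driven with (a = −0.0025, b = 3.2), and the per-genotype
residuals expose the ε_RUE differences. `res.genotype_means()` returns the
per-genotype table; `fields.relative_biomass` and
`fields.competitiveness_bias` compare mixtures against single-genotype
reference canopies.

A thin CLI wraps the same pipeline:
`canopy-dissect layout|simulate|dissect|bias --config run.yml --out ...`.

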