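# thermosip

Quantitative analysis of soil microbial carbon use after a glucose amendment,
linking three views of the same incubation:

* **heat** — isothermal-calorimeter power traces are integrated to cumulative
  heats and converted to thermodynamic efficiency indices;
* **carbon** — ¹³C-labelled glucose lets a two-source isotope mixing model
  split respired CO₂ into glucose-derived, soil-organic-matter (SOM)-derived
  and primed pools;
* **community** — DNA stable-isotope-probing (SIP) fraction OTU tables are
  analysed for β-diversity (Bray–Curtis, PCoA, PERMANOVA), differential
  abundance between ¹³C-heavy and ¹³C-light fractions, and correlations of
  glucose-utilizing taxa with soil attributes.

It is written for soil microbial ecologists who run substrate-amendment
incubations combining calorimetry, gas/IRMS measurements and amplicon
sequencing, and who want the whole analysis reproducible from raw tables. A
synthetic-data generator with a known ground truth emulates a split-plot field
trial (conventional vs organic management × annual vs annual–perennial
cropping × 4 replicates × glucose/water amendment), so every stage is testable
end to end without laboratory data.

## The core quantities

With cumulative heats `Q_glucose` and `Q_control` (J g⁻¹ soil) over 48 h and
`ΔH_glucose` the energy added as glucose (18.05 J g⁻¹ soil at
500 µg glucose-C g⁻¹):

```
η_eff  = 1 − (Q_glucose − Q_control) / ΔH_glucose
η_CO₂  = ΔH_CO · n(CO₂-C from glucose) / ΔH_glucose ,   η_soil = 1 − η_CO₂
```

where `ΔH_CO` (default 467,200 J mol⁻¹ C = glucose combustion enthalpy / 6)
converts glucose-derived CO₂-C moles to heat. Respired CO₂ is partitioned by
the ¹³C mass balance

```
R_glucose = R_t · (x_sample − x_soil) / (x_glucose − x_soil)
R_SOM     = R_t − R_glucose
R_primed  = R_SOM − R_basal
```

with `x` denoting ¹³C atom fractions (labelled glucose 0.195; `x_soil` from
water-only controls) and `R_basal` the water-control respiration. The
calorespirometric ratio (mJ heat per µg CO₂-C) and the metabolic quotient
qCO₂ (basal respiration per unit fumigation-extraction microbial biomass C,
k_ec = 0.45) complete the index set.

## Worked example

```python
from thermosip import (ExperimentDesign, SyntheticTruth, simulate_experiment,
                       run_pipeline, treatment_summary)

design = ExperimentDesign(seed=42)
truth = SyntheticTruth(enriched_taxa={"CON": tuple(f"OTU{i:04d}" for i in range(1, 21))})
simulate_experiment(design, truth, out_dir="exp", n_taxa=300, depth=10_000)
res = run_pipeline("exp", n_permutations=199, seed=42)
print(treatment_summary(res["indices"], ["management", "crop"], ["eta_eff"]).round(3))
```

prints

```
management crop  n  eta_eff_mean  eta_eff_se
       CON  ANN  4         0.684         0.0
       CON  PER  4         0.675         0.0
       ORG  ANN  4         0.677         0.0
       ORG  PER  4         0.688         0.0
```

— the generator's default world dissipates 31–33 % of the added glucose
energy as extra heat, so the efficiency index sits near 0.68 in every
treatment; the standard errors are ~0 because the default power noise is tiny
relative to the 48-h heat integral. The same run partitions respiration
(pooled means: glucose-derived ≈ 173/168 µg CO₂-C g⁻¹ under conventional vs
organic management, with ~57 % of SOM-derived CO₂ primed in the organic
soils), finds the SIP fraction to be the dominant β-diversity term
(PERMANOVA pseudo-F = 4.2, p = 0.005), and flags the 20 planted
glucose-utilizer OTUs in the conventional-system heavy-vs-light contrast at
FDR < 0.01.

The same stages are scriptable from a shell:

```bash
thermosip simulate --out exp --seed 42
thermosip report --in exp --out report
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the summary-scale quantities of the source incubation (efficiency
indices from mean cumulative heats, the mass-balance partition identities,
and the pooled metabolic quotient) by running the package's operations on the
published treatment-mean inputs, and writes them as JSON.
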