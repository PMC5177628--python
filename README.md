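# nafkit

A toolkit for benchtop **non-aqueous fractionation (NAF)** experiments in
plant metabolomics: planning heptane–tetrachlorethylene density gradients,
and computing **relative and absolute subcellular metabolite distributions**
(plastid / cytosol / vacuole) from marker-enzyme activity profiles and
GC-MS metabolite profiles measured across the gradient fractions.

It is written for researchers who run NAF on lyophilized leaf material and
want the downstream arithmetic — gradient dilution volumes, the
hit-counting compartment assignment, replicate statistics, condition
comparison and clustering — as reproducible, scriptable code instead of a
spreadsheet.

## The method

**Gradient planning.** The gradient medium is an ideal binary mixture of
n-heptane (ρ = 0.68 g cm⁻³) and tetrachlorethylene (ρ = 1.60 g cm⁻³), so a
mixture density follows from mass balance,

    ρ_mix = Σᵢ ρᵢVᵢ / ΣᵢVᵢ ,

and the diluent volume that moves a supernatant of volume *V* and density
ρ to a target density ρ\* is *x* = V(ρ − ρ\*)/(ρ\* − ρ_d).

**Compartment assignment.** After fractionation, each analyte's values over
the *f* fractions are normalized to percent. For every pair of detected
fractions *i* < *j* the slope Δᵢⱼ = pct(j) − pct(i) of a metabolite is
compared to the slope of each compartment's marker enzyme
(alkaline pyrophosphatase → plastid, UGPase → cytosol, acid
phosphatase → vacuole):

    Ψ(comp, i, j) = | Δᵢⱼ^met − Δᵢⱼ^comp | .

On each pair the compartment with minimal Ψ scores a hit, and every
compartment whose excess Ψ − min(Ψ) stays below an uncertainty bound
(default 5, 7.5 and 10 percentage points, graded to reflect technical
error) scores additional hits. Hit totals over all pairs, normalized to
100 %, are the metabolite's relative subcellular distribution; replicates
are aggregated to mean ± SD, and multiplying by whole-tissue levels yields
absolute per-compartment amounts with propagated SD. A metabolite detected
in a single fraction is assigned to the compartment with the highest
marker percent in that fraction.

The package also ships condition comparison (one-way ANOVA, Tukey HSD for
more than two conditions, star/arrow annotation), z-score scaling with
Euclidean hierarchical clustering, and a synthetic-experiment generator
with known ground truth for validation.

## Worked example

```python
from nafkit import diluent_volume_for_target, solvent_ratio_for_density, run_assignment
from nafkit.synthetic import SyntheticConfig, generate_experiment

# Gradient arithmetic: dilute 1.05 mL of 1.55 g/cm3 supernatant to 1.45
print(round(diluent_volume_for_target(1.05, 1.55, 0.68, 1.45), 3))  # 0.136 mL
# Heptane:TCE ratio for the 1.3 g/cm3 suspension medium
print(round(solvent_ratio_for_density(1.3), 3))                     # 0.484

# Simulate a 3-metabolite, 3-replicate experiment and assign compartments
table, truth = generate_experiment(SyntheticConfig(n_metabolites=3, seed=42))
print(run_assignment(table)["relative"].round(1).to_string(index=False))
```

```
metabolite      condition compartment  mean_percent  sd_percent  n
   met_001 non_acclimated     plastid          29.3         1.4  3
   met_001 non_acclimated     cytosol          45.3         0.8  3
   met_001 non_acclimated     vacuole          25.4         0.8  3
   met_002 non_acclimated     plastid          12.1         2.4  3
   met_002 non_acclimated     cytosol          74.6         0.7  3
   met_002 non_acclimated     vacuole          13.3         1.8  3
   met_003 non_acclimated     plastid          11.1         0.0  3
   met_003 non_acclimated     cytosol           5.6         0.0  3
   met_003 non_acclimated     vacuole          83.3         0.0  3
```

Each row is the mean ± SD percent of a metabolite assigned to one
compartment across the three replicates. The simulated ground-truth mixing
weights were (0.30, 0.56, 0.14), (0.07, 0.88, 0.05) and (0.01, 0.03, 0.96):
the assignment recovers the dominant compartment of every metabolite, with
the graded-bound hit counting pulling strongly localized metabolites
(met_003) toward a crisp call and mixed ones (met_001) toward a blended
distribution.

The same workflow is available from a shell:

```sh
nafkit simulate --metabolites 10 --seed 42 --out sim/
nafkit assign --input sim/experiment.csv --bounds 5,7.5,10 --out results/
nafkit gradient --design design.yaml --out plan.csv
nafkit run --config run.yaml --out results/   # simulate → assign → stats
```

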