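# lacscape

Growth-feedback fitness landscape of the *E. coli* lac pathway: a
self-consistent cost model mapping regulatory genotype and inducer
environment to pathway phenotypes and Malthusian fitness, with tools for
locating fitness cliffs and expression barriers, simulating relaxation
dynamics and competition assays, and inferring the expression cost
coefficients from strain-panel measurements by maximum likelihood.

## The model

Expressing the lac operon costs growth. The cost of running the pathway at
production rate δ and total inducer transport rate T is

    cost(δ, T, λ) = c_δ·δ + c_T·T + c_C·T/λ²

in units of the growth rate λ₀ of a lac-deleted reference strain: a linear
cost of protein production, a direct cost of transport activity, and a
toxicity cost proportional to the steady-state concentration of the
co-transported protons (influx T diluted by growth λ in a cell volume ∝ λ).
The phenotypes themselves depend on the growth rate,

    δ = δ_max · η(λ) · (χ₀ + (1−χ₀)·h(E)),      T = (δ/λ) · τ̂(E),

with per-strain genotype summaries δ_max (maximal production rate at one
doubling per hour) and χ₀ (repressed/unrepressed ratio, the inverse
repression level), Hill induction h(E) by external IPTG, Michaelis per-pump
transport τ̂(E), growth-dependent expression η(λ), and permease copy number
δ/λ set by dilution. Fitness is therefore *self-consistent*:

    λ = G(λ) ≡ λ₀ − cost(δ(λ), T(λ), λ).

Because toxicity grows as transport outpaces dilution, G folds: above a
critical expression or inducer level the stable and unstable fixed points
coalesce (a saddle-node), producing a **fitness cliff** in
genotype–environment coordinates and an **expression barrier** in phenotype
coordinates. Populations pushed past it cannot sustain growth; populations
starting below the unstable branch dilute their proteins too slowly and go
extinct.

The package solves the fixed-point problem in both coordinate systems with
stability classification, locates the folds, integrates the relaxation
dynamics (damped iteration and the matching ODE), estimates (δ_max, χ₀) per
strain from concentration/fitness measurements with delta-method errors, and
fits (c_δ, c_T, c_C) by Gaussian maximum likelihood with nested model
comparison. A synthetic-data module reproduces the study design (operator
mutant panel plus ΔlacI, ΔlacY and reference controls at 0 and 1 mM IPTG,
12 fitness / 3 concentration replicates, CFU-level competition assays) so
the whole pipeline is testable end to end.

## Worked example

```python
import lacscape as L

p = L.ModelParams()                      # default cost coefficients
wt = L.Genotype(delta_max=1.0, chi0=1e-3, pump_factor=1.0)

for E in (0.0, 0.1, 1.0):
    s = L.solve_genotype_environment(wt, E, p)
    print(f"E={E:>4} mM: lambda={s.lambda_stable:.4f}  regime={s.regime}")

cliff = L.find_cliff(L.Genotype(1.0, 1.0, 1.0), p, "delta_max",
                     bracket=(0.1, 12.0), E=1.0)
print(f"fitness cliff at delta_max = {cliff:.4f} (1 mM IPTG)")
```

prints

```
E= 0.0 mM: lambda=0.9999  regime=single
E= 0.1 mM: lambda=0.9638  regime=two-branch
E= 1.0 mM: lambda=0.8990  regime=two-branch
fitness cliff at delta_max = 5.2818 (1 mM IPTG)
```

Uninduced, the wild type pays almost nothing (λ ≈ 1). With inducer the
landscape becomes double-valued (a stable branch the population sits on and
an unstable branch bounding its basin), and fully induced the wild type pays
a ~10% growth cost. A constitutive strain expressing ≈5.3× the wild-type
rate sits exactly at the cliff at 1 mM IPTG; anything above that cannot grow
at all. The same objects drive the command line:

```bash
lacscape run-all --seed 1 --out runs/demo     # simulate -> estimate -> fit -> landscape
lacscape landscape --mode phenotype --out runs/pheno
```

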