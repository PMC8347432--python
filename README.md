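# nmrbind

Solution thermodynamics of small aromatic drugs from routine NMR
observables: indefinite (isodesmic) self-association from dilution chemical
shifts, 1:1 drug–DNA binding constants from titration shifts and from
diffusion (DOSY) measurements, and aqueous degradation half-lives — plus
seeded synthetic-data generators so every fit can be validated by parameter
recovery without raw spectra.

## Who this is for

NMR and medicinal-chemistry groups characterizing planar, stacking-prone
compounds (camptothecin-family topoisomerase I inhibitors are the motivating
case) in water: how strongly does the compound self-associate, how tightly
does it bind a model DNA duplex such as d(GCGATCGC)₂, and how fast does it
degrade? All inputs are small CSV tables of chemical shifts, diffusion
coefficients, or intact fractions; all outputs are equilibrium or rate
constants with per-proton detail and pooled uncertainty.

## Models

**Self-association (isodesmic).** Every stacking step shares one constant
K_a (mM⁻¹). Under fast exchange a proton's shift displacement from the
monomer follows

    Δδ_obs = δ_mon − δ_obs = Δδ_max · K_a·L₀ · (2 / (1 + √(1 + 4·K_a·L₀)))²

which equals Δδ_max · K_a·[L] with [L] the free monomer. Fitting this per
proton over a dilution series (default design: 12 log-spaced points,
0.003–1.2 mM) gives K_a, δ_mon and Δδ_max; the pooled value is the mean ±
SD of the per-proton constants (a global shared-K_a mode is also offered).

**Titration binding (1:1).** With K_a = [DNA·L]/([DNA][L]), the shift
change of a ligand proton during a duplex titration is

    Δδ = δ_obs − δ_L = Δδ_DNA·L · K_a·[DNA] / (1 + K_a·[DNA])

where [DNA] is by default the equilibrium free duplex from the exact 1:1
quadratic (a total-concentration approximation is available). An optional
correction re-evaluates the free-ligand baseline δ_L from the isodesmic
model as ligand is withdrawn into the complex — the bias self-associating
protons otherwise show.

**DOSY binding.** Under fast exchange, observed diffusion coefficients are
population-weighted averages of free and bound species. Taking the complex
to diffuse like the duplex (D_complex ≅ D_obs,DNA), the free-ligand mole
fraction is a linear interpolation, the complex concentration follows from
the ligand mass balance, and K_a is closed-form — the exact algebraic
inverse of the forward model.

**Kinetics.** First-order decay f(t) = A₀·e^(−kt), t½ = ln 2/k, with a
zero-order variant for sensitivity.

## Worked example

Simulate a dilution series at the default study design (true K_a =
1.71 mM⁻¹, 6 protons, 0.002 ppm shift noise) and fit it:

```
$ nmrbind simulate dilution --seed 1 --out dilution.csv
$ nmrbind fit dilution dilution.csv --out report.csv
Ka_mean = 1.6906 +/- 0.0764 mM^-1 (6 protons, mode=per_proton_average)
```

The recovered mean is within 1.2% of the generating constant; the ± value
is the scatter of the six independent per-proton fits. `report.csv` holds
the per-proton detail:

```
proton,Ka_mM_inv,delta_mon_ppm,delta_max_ppm,rss
H11,1.5536505286445559,7.94762698887958,0.40605697527621054,5.76e-05
H12,1.7190300984113576,8.280457081453338,0.6481176710775511,1.62e-05
...
```

A diffusion record at a 1:3 ligand:duplex ratio inverts in closed form,
with a Monte-Carlo band from 2% relative noise on all D values:

```
$ nmrbind simulate dosy --seed 0 --out dosy.csv
$ nmrbind fit dosy dosy.csv --mc-sigma 0.02
mix1: MF_L = 0.203, [complex] = 0.2391 mM, Ka = 5.9436 mM^-1  (MC 68% band 5.33-6.66)
```

and a degradation time course fits to its half-life:

```
$ nmrbind simulate decay --seed 1 --out decay.csv
$ nmrbind fit decay decay.csv
k = 0.01372 / day, t_half = 50.52 days (order 1)
```

`nmrbind study run --outdir out` runs all four analyses end to end on
synthetic data and cross-checks the titration- and diffusion-derived
binding constants. The library surface (`import nmrbind`) exposes all of
this programmatically; see `docs/methods.md` for model assumptions,
parameter defaults and limitations.

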