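# Methods

## Scope and assumptions

All four analyses assume fast exchange on the NMR timescale: every
observable (chemical shift, diffusion coefficient) is a population-weighted
average over species, so equilibrium constants are inferred from how that
average moves with composition. Activities are replaced by concentrations
(mM throughout; the DNA duplex is counted as duplexes, not strands), and
temperature, pH and ionic strength are treated as fixed experimental
metadata, not model inputs.

## Isodesmic self-association

The indefinite-association model assigns one constant K_a (mM⁻¹) to every
stacking step, so n-mer concentrations form the geometric ladder
[Lₙ] = K_a^(n−1)·[L]ⁿ and the mass balance is L₀ = [L]/(1 − K_a[L])².
This inverts in closed form,

    [L] = L₀ · (2 / (1 + √(1 + 4·K_a·L₀)))²,

and the shift-displacement isotherm follows as
Δδ_obs = Δδ_max · K_a·[L]. Two published limits pin the algebra: Δδ_obs → 0
at infinite dilution and Δδ_obs → Δδ_max at full stacking; both hold for the
form above, and the identity Δδ_obs/Δδ_max = K_a·[L] is enforced as a
property test. (Printed versions of this isotherm are frequently mangled
typographically; the closed form here is derived from the mass balance, not
transcribed.)

Sign convention: Δδ_obs = δ_mon − δ_obs, so the usual upfield drift on
stacking gives positive Δδ_max. A proton pushed downfield by the stack
geometry (the 23-methyl in the default synthetic panel) is kept in the fit
with Δδ_max < 0 rather than discarded.

Fitting: per proton, unweighted nonlinear least squares over
(K_a, δ_mon, Δδ_max) via lmfit, with K_a bounded to [0, 10³] mM⁻¹ starting
at 1, δ_mon started at the most-dilute observed shift (the lowest measured
concentration is near, not at, infinite dilution, so δ_mon stays free), and
Δδ_max started at the observed swing. Three jittered restarts back up a
failed convergence; per-point 1/σ weights are optional. The pooled value is
the arithmetic mean ± sample SD of the per-proton constants — each proton
is an independent estimate of the same K_a — with a shared-K_a global mode
as the alternative. Protons whose total swing falls under a caller-set
noise floor carry no K_a information and are flagged out of the pooled
mean. Fits require ≥ 4 points spanning ≥ one decade of concentration;
narrower designs cannot separate K_a from Δδ_max.

## Titration binding

Binding of ligand L to the duplex is fixed at 1:1 stoichiometry
(K_a = [DNA·L]/([DNA][L])); the two equivalent G·C duplex ends are not
modelled as separate sites. The free duplex is the positive root of

    K_a·d² + (1 + K_a·C_L − K_a·C_DNA)·d − C_DNA = 0,

evaluated on the cancellation-free branch d = 2·C_DNA/(b + √(b² + 4K_a·C_DNA)).
The isotherm Δδ = Δδ_DNA·L · K_a·[DNA]/(1 + K_a·[DNA]) is exposed under two
conventions, because published fits use both and rarely say which: the
exact equilibrium free duplex (`free_exact`, default) or the total duplex
(`total_approx`); the two agree to <1% once duplex exceeds the ligand
~20-fold with K_a·C_L ≤ 0.1. Titration sign convention follows the binding
literature, Δδ = δ_obs − δ_L (upfield complexation shifts are negative).

The baseline δ_L defaults to the observed shift at C_DNA = 0. For a
self-associating ligand that baseline is itself concentration dependent:
as duplex withdraws monomer into the complex, the remaining free pool
de-stacks and its average shift relaxes toward δ_mon, biasing fixed-δ_L
fits for strongly stacking protons. The optional correction takes the
isodesmic fit of the neat ligand and models the observed shift as
(1 − f_b)·δ_free(C_L − [DNA·L]) + f_b·(δ_mon + Δδ_DNA·L), with f_b the
bound-ligand fraction. The synthetic generator has a matching drift mode,
and the test suite demonstrates the bias and its removal.

Per-proton fits (K_a, Δδ_DNA·L) pool exactly as in the self-association
module; protons with |Δδ_DNA·L| under 3× the noise floor are excluded from
the mean, and a titration whose bound fraction never reaches 20% triggers a
"poorly constrained" warning rather than a silent, noise-dominated K_a.

## DOSY binding

With the duplex much larger than the ligand, the complex is assumed to
diffuse at the observed duplex rate (D_complex ≅ D_obs,DNA). The free
ligand mole fraction is then the linear interpolation
MF_L = (D_obs,L − D_complex)/(D_L − D_complex), the complex concentration
is (1 − MF_L)·C_L, and K_a follows from the mass-action quotient against
both totals. This closed form is the exact algebraic inverse of the
package's forward model, verified as a property test to 1e−8 relative —
the module's internal oracle.

Because a self-associating ligand's diffusion is concentration dependent,
the free-ligand reference D_L must be measured at a matched concentration;
the record carries it per sample rather than assuming a constant. MF_L
values straying past [0, 1] by more than 0.02 are treated as inconsistent
references (error), smaller excursions are clipped with a warning, and a
complex concentration at either total is reported as saturation (K_a
unbounded) instead of a number. The duplex-side mole-fraction route exists
for consistency checks when an independent D_complex is supplied, but does
not enter K_a by default — the D_complex ≅ D_obs,DNA convention collapses
it. A Monte-Carlo utility propagates relative noise on all four D values
to a K_a distribution; its median sits on the true constant for small
noise, quantifying the error the simplification can introduce.

## Degradation kinetics

The kinetic order of slow aqueous degradation is rarely established from a
single time course; first order (pseudo-unimolecular in water, appropriate
for a retro-Mannich elimination) is the default, f(t) = A₀·e^(−kt) with
t½ = ln 2/k, and a zero-order variant (f = A₀ − kt, t½ = A₀/2k) is provided
for sensitivity. The amplitude is pinned at 1 for data already normalized
to the t = 0 point (NMR integral ratios or HPLC area fractions both enter
this way) or fitted when normalization is in doubt. A fitted negative rate
is clipped to zero with a warning; a flat series is an error. A log-linear
regression of ln f on t serves as an independent oracle in the tests.

## Synthetic data

The generators produce data with exactly the statistical structure the
fits assume: forward-model means plus Gaussian observational noise —
additive in ppm for shifts (default σ = 0.002 ppm dilution, 0.003 ppm
titration, typical shift-reading error), relative for diffusion (σ = 2%),
additive for fractions (σ = 0.02, truncated to [0, 1]). Default designs
mirror the motivating experiments: 12 log-spaced concentrations from 0.003
to 1.2 mM for dilution; fixed ligand at 0.3 mM with duplex titrated 0 → 3×
ligand in 8 steps; a 1:3 ligand:duplex diffusion mixture with
D_L = 4.0×10⁻¹⁰ and D_DNA = 1.3×10⁻¹⁰ m² s⁻¹; 11 time points over 0–100
days at a 50-day half-life. The default proton panel carries six
heterogeneous limiting shifts (0.65 down to 0.10 ppm, aromatic protons
largest, one reversed methyl) so sign handling and pooling are exercised.

What passing recovery tests do **not** show: the generators contain no
peak overlap, no baseline or referencing drift, no exchange broadening, no
deviation from 1:1 stoichiometry or from isodesmic equality of stacking
constants, and (outside the explicit drift mode) no coupling between
equilibria. Recovery under these conditions validates the estimators
against their own model class, not against every pathology of real
spectra.

## Numerical choices

All equilibrium algebra is closed-form (no iterative root finding in the
model path); the quadratic uses the stable branch noted above. Noiseless
round trips are exact to better than 1e−6 relative for every fit and 1e−8
for the DOSY inversion. Optimizer: lmfit's `least_squares` (trust-region
reflective) with bounds [0, 10³] mM⁻¹ on equilibrium constants; ties and
degenerate inputs resolve to errors, not guesses (empty series, flat decay,
indistinguishable diffusion references, unsaturated titrations are all
reported explicitly). CSVs are written at %.17g and read with pandas'
round-trip float parser so write-then-read is bit-exact; every fit or
simulation emits a JSON manifest (command, inputs, config digest, seed,
version, timestamp) for reproducibility.

The replicate studies in the test suite (bias of recovered K_a and t½)
use 200 replicates, enough to bound bias at the few-percent level while
keeping the whole suite in seconds.

## Limitations

Dimerization-specific (K₂ ≠ K) or cooperative association, multi-site or
2-per-duplex binding, NOESY-derived geometry, raw gradient-attenuation
(Stejskal–Tanner) fitting, and spectral simulation are out of scope. The
DOSY route inherits the D_complex ≅ D_obs,DNA simplification: at low bound
fractions it is the dominant error source, which is why the Monte-Carlo
band is reported alongside the point estimate.
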