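# Methods

## The problem

Outer-membrane β-barrel proteins (OMPs) end in a conserved C-terminal
"β-signal" (Aro-Xaa-Aro) whose two interface residues — one side chain
facing the lipid, one facing the barrel interior — contribute to the
thermodynamic stability of the folded barrel. The standard way to
measure those contributions is an equilibrium chemical-denaturation
titration: a guest-residue library is built at the host position, each
variant is titrated over a guanidine-hydrochloride gradient in a
membrane mimetic (detergent micelle or lipid vesicle), an optical signal
(tryptophan fluorescence) is recorded, and each curve is fitted with the
linear extrapolation model (LEM) to obtain the zero-denaturant folding
free energy. Differencing those free energies against an alanine
reference yields a per-residue water-to-interface partitioning scale,
which can then be regressed against side-chain surface-area changes
(giving an atomic solvation parameter, ASP) and against published
hydrophobicity scales.

`foldscale` implements that entire pipeline as a reusable, tested
library with scikit-learn-style estimators for the fitting steps and a
synthetic-data module that stands in for the raw titrations, which are
not deposited with any publication of this kind.

## Models

**Linear extrapolation (stability convention).** ΔG(D) = ΔG⁰ − m·D with
ΔG⁰ ≥ 0 for a stable protein and m > 0. The unfolded fraction of a
two-state system is the logistic

    f_U(D) = exp(x) / (1 + exp(x)),  x = −(ΔG⁰ − m·D) / (RT)

computed through `scipy.special.expit` so it neither overflows nor loses
monotonicity for |x| up to ~700. The midpoint is Cm = ΔG⁰/m and is kept
exact by construction (`Cm` is a derived attribute, never a free
parameter). Printed forms of these equations sometimes carry the
exponent −(ΔG + m·D)/RT; that convention forces fitted m < 0 whenever
ΔG > 0, so the stability convention above is used internally and all
reported m values are positive. R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ and
T defaults to 298.15 K (samples equilibrated at 25 °C), overridable per
curve.

**Observed signal.** Each state contributes a linear baseline
(intercept + slope·D); the observed signal is the population-weighted
average of the baselines. Baseline-corrected fractions
(f_U = (y − B_F)/(B_U − B_F)) are deliberately *not* clipped to [0, 1]:
noise legitimately carries points outside and clipping would bias fits.

**Three-state systems.** An intermediate adds a third baseline and two
equilibrium constants, K₁ = exp(−(ΔG₁ − m₁D)/RT) between the folded
state and the intermediate, K₂ = exp(−(ΔG₂ − m₂D)/RT) between the
intermediate and the unfolded state. Populations are softmax-normalized
log-weights, so f_F + f_I + f_U = 1 to machine precision. The total
unfolding free energy ΔG₁ + ΔG₂ is a state function — invariant to how
the two transitions split it. U↔I / I↔N labels are assigned by midpoint
order (the higher-denaturant transition is U↔I), not by parameter index.

## Fitting

All estimation is nonlinear least squares (`scipy.optimize.least_squares`,
TRF, `x_scale="jac"` so results are invariant to affine rescaling of the
signal axis).

* **Initialization** (no publication states one): baselines from linear
  fits to the outer 20% of points at each end; midpoint from the
  half-transition point of the baseline-normalized, lightly smoothed
  signal; m from ln(81)·RT divided by the 10–90% transition width; a
  small multistart grid (midpoint ± 0.4 M, m × {0.5, 1, 2}) around that
  seed.
* **Two-state modes.** `direct` fits all six parameters against the raw
  signal. `two_stage` reproduces the classic protocol — estimate
  baselines, convert to fractions, fit (ΔG⁰, m) — but iterates the two
  stages to a joint fixed point, so on noiseless data the modes agree to
  better than 10⁻⁶ (on noisy data they differ slightly, as the protocols
  genuinely do). Default is `direct`.
* **Uncertainties** from the inverse Gauss–Newton curvature at the
  optimum scaled by the residual variance; the midpoint error by the
  delta method.
* **Failure taxonomy.** Flat curves or fitted m below a floor raise
  `NoTransition`; a fitted midpoint far outside the data range likewise.
  Three-state fits raise `IndistinguishableStates` when the intermediate
  never exceeds a population floor (default 0.10), when the folded or
  unfolded state never populates (the model collapsed to two states),
  when a transition connects spectroscopically identical baselines
  (baseline contrast < 2% of amplitude — a "phantom" transition that
  absorbs noise), or when a fitted m sits at the grid resolvability
  limit ln(81)·RT/(2·ΔD), i.e. a transition sharper than two grid steps.
  These guards are what keep 10-parameter three-state fits honest on
  data that are really two-state.
* **Model selection** is by corrected Akaike score on the raw-signal
  residuals plus an intermediate-population floor (default 0.20): the
  three-state model must improve AICc by a margin (default 10) *and*
  populate its intermediate. The original analyses chose by inspection;
  an explicit criterion makes the choice reproducible.
* **Global shared-m fits** share one m value across curves with
  per-curve free energies and baselines free, as appropriate for vesicle
  titrations where the ASA change is taken as uniform across point
  mutants. Mutants whose folding/unfolding arms show hysteresis
  (midpoint shift > 0.2 M or normalized-fraction gap > 0.1 by default)
  are flagged `apparent`: their ΔG values are path-dependent
  ΔG⁰_app, not equilibrium free energies.

## Identifiability of the three-state total

The three-state LEM with free baselines is weakly identified at
realistic noise. On the canonical test curve (ΔG₁ = 3, m₁ = 1.5,
ΔG₂ = 5, m₂ = 1.2; 60-point 0.7–6.6 M grid; distinct baselines) the
asymptotic standard error of the fitted total at Gaussian noise of 1% of
the signal amplitude is ≈ 2.0 kcal mol⁻¹ (26% of the true total) — the
free intermediate-baseline slope trades off against both m values along
a flat likelihood valley. Fixing the intermediate slope to the folded
one (`shared_slope=True`) reduces this to ≈ 0.6 kcal mol⁻¹ (7%).
Noiseless round trips recover all four thermodynamic parameters to
10⁻³ relative; at finite noise only the midpoints are sharply
determined, and the extrapolated free energies inherit the m-value
uncertainty. One acceptance check (recovery of the total to 1% at 1%
noise) sits an order of magnitude below this Cramér–Rao bound and is
kept failing by design as documentation of the information limit; it is
a property of the model class, not of the optimizer (measured replicate
scatter matches the bound).

## Partitioning scales and regressions

ΔΔG⁰_w,i(X) = ΔG⁰(reference) − ΔG⁰(X), reference alanine by default and
exactly zero in the scale. The `dg_selector` chooses which free energy
enters per residue: the state-function total, a single transition
(`U_to_I` / `I_to_N`, three-state fits only; requesting them from a
two-state fit is an error), or `auto` — total for two-state fits, U→I
for three-state fits, the convention appropriate when the U→I transition
is the better measure of global folding. The per-residue choice is
recorded in a provenance map so mixtures stay auditable.

Regressions are ordinary least squares (`scipy.stats.linregress`);
tests verify them against hand-written normal equations. Exclusion
lists are always explicit caller input — published analyses exclude
specific outliers (Cys, Ser, Trp…) per figure without an algorithmic
rule, so no automatic outlier rejection exists here. Deletion variants
(multi-character codes) are auto-excluded from ASA regressions only,
since a deleted residue has no defined side-chain ΔASA. For a
lipid-facing (φ) scale the ΔΔG–ΔASA(non-polar) relation is direct
(positive ASP); for a protein-facing (π) scale it is inverse.

Packaged reference tables (side-chain ASA; Wimley–White interface and
octanol scales; translocon scale) are transcriptions of the cited
literature with the citation in each file header; they are convenience
data, flagged for verification before quantitative use, and no test
depends on their values. Scales we could not transcribe with confidence
(Ez at 12 Å, dsTβL, Moon–Fleming) are not shipped; the loader accepts
any two-column TSV.

## Spectral observables

⟨λ⟩ = Σ I(λᵢ)λᵢ / Σ I(λᵢ) is the intensity-weighted average emission
wavelength; it is bounded by the acquisition window and invariant to
intensity scaling. Because ⟨λ⟩ weights species by brightness, a
quantum-yield ratio Q_R (unfolded/folded integrated intensity) is undone
by f = x/(x + Q_R(1 − x)) with x the linear normalization of ⟨λ⟩ between
folded and unfolded endpoints; for a two-species mixture this recovers
the true unfolded fraction exactly, and Q_R = 1 reduces to plain linear
normalization. The exact functional form of this correction is not
printed in the source literature; this two-species form is the package's
documented choice and Q_R is an explicit input (default 1).
⟨τ⟩ = Σ τᵢαᵢ with amplitudes normalized to 1. Mean-residue ellipticity
is [θ] = θ_mdeg·MRW/(10·l·c) with MRW configurable (default 110 Da);
per-variant values at a wavelength are normalized to the wild type.

## Synthetic data (what a green test does and does not establish)

Generators are pure functions of (parameters, seed): linear baselines,
LEM transitions, homoscedastic Gaussian signal noise expressed as a
fraction of the folded amplitude at zero denaturant. The stated world:
0.7–6.6 M grid at 0.1 M steps; tryptophan-like descending signal;
library free energies on a linear ΔΔG–ΔASA(non-polar) relation with
slope magnitude 0.043 kcal mol⁻¹ Å⁻²; φ libraries ΔG_ref = 11,
m = 2.5; π libraries ΔG_ref = 9, m = 3.0, chosen once so every
variant's midpoint stays inside the grid (two-state m values in micelles
span roughly 1–4 kcal mol⁻¹ M⁻¹). Three-state variants pin midpoints at
2.2 and 4.4 M and split the total 35/65 between the transitions,
preserving it exactly. Emission spectra are two Gaussian bands (folded
344 nm — the folded-state emission maximum of the emulated protein;
unfolded 352 nm and FWHM 25 nm are package defaults, not measured
values) with areas (1 − f_U) and Q_R·f_U.

The generator reproduces the *statistical* structure the analysis
assumes, nothing more: no photophysics (quenching, inner-filter),
no micelle/vesicle physics, no heteroscedasticity, no baseline
curvature, no inter-mutant m-value heterogeneity. A green end-to-end
test therefore establishes that the pipeline inverts its own forward
model at realistic noise — not that any laboratory's numbers are
reproduced. The synthetic ASA table used in tests is an explicitly
labelled stand-in spanning the realistic range; tests never read the
packaged literature tables for expected values.

## Numerical choices

Logistics through `expit`/`softmax` (no overflow, populations sum to 1
exactly); least-squares tolerances 10⁻¹⁴ so noiseless round trips reach
10⁻⁴–10⁻³ relative and affine-rescaling invariance holds to 10⁻⁸;
baseline degeneracy threshold 10⁻¹² on the folded–unfolded difference;
hysteresis gap by linear interpolation of each arm's own
baseline-normalized fractions on the overlap of the two ranges (so
baseline-only offsets between arms never register as hysteresis);
reports written with ≥ 8 significant digits so write→read round-trips
are lossless at the printed precision.

## Known limitations

* Three-state free energies at realistic noise carry the large
  identifiability-limited uncertainties described above; trust the
  midpoints, report the errors.
* The apparent-value flag requires both arms of a variant to be present;
  single-arm data cannot be diagnosed for hysteresis.
* The two-stage fit is a faithful re-implementation of the classic
  protocol, not a statistically efficient estimator; `direct` is the
  default for that reason.
* Packaged literature tables are transcriptions; verify against the
  originals before publishing numbers that depend on them.
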