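# Methods

## Scope and model structure

The package implements the quantitative analyses behind chaperone-driven
disassembly of DNA-bound Hsf1 trimers: equilibrium and kinetic
fluorescence-polarization models, a binomial trimer-composition model coupled
to a multi-rate global kinetic fit with model selection, HX-MS bimodal
envelope deconvolution, Hsp70 binding-site scanning, and thermal-transition
fitting, plus seeded generators that emulate each experimental design.

## Equilibrium binding (ligand depletion)

Because the labelled HSE probe is used at concentrations comparable to the
dissociation constant, the free-ligand approximation is invalid and the bound
complex is the quadratic root of the mass-action equation. The root is
evaluated in the numerically safe branch (subtracting the square root of a
discriminant that is analytically ≥ (L−R)² + K_D²) and clipped to
[0, min(L, R)] to absorb rounding. The titration model has three parameters
(K_D, free and bound signal levels); K_D is bounded positive and initialised
at the titrant concentration closest to half-saturation.

## Dissociation kinetics

Dissociation traces are fitted with a composite curve: flat at y_max until a
lag t₀, then a single exponential decaying to y₀ with rate k (min⁻¹). The lag
is a *fitted* parameter bounded to [0, 15] min, consistent with the observed
5–10 min delay before the exponential phase; it is a trace-level property
shared by all species within a trace. Traces with no net decrease beyond
3× the local noise estimate (from first differences) are flagged "no decay"
and returned as structured failures rather than exceptions.

## Binomial composition and the global mixture fit

Trimers assembled from an a:b mix of wild-type and site-deleted monomers have
binomially distributed composition with p = a/(a+b): fractions p³, 3p²(1−p),
3p(1−p)², (1−p)³ of trimers with 3, 2, 1, 0 accessible chaperone sites. The
kinetic model assigns each species its own delayed-exponential rate (k₃, k₂,
k₁) and fixes the 0-site rate at exactly zero, reflecting the complete loss
of dissociation for the site-deleted homotrimer. A trace is the
composition-weighted sum of species curves; at t ≤ t₀ it equals y_max for
every composition (amplitude conservation).

**Shared parameters.** Rates are global across traces. The amplitudes
(y_max, y₀) are also shared across traces by default: every mixing ratio is
measured at the same probe and total-protein concentrations, so the bound and
free polarization levels are common to the experiment. This choice matters
statistically — the undissociable 0:1 trace then anchors the plateau, which
is what makes the slowest rate identifiable within a finite observation
window; with per-trace amplitudes the single-site rate k₁ is essentially
unidentifiable at the default design (its asymptotic standard error exceeds
its value). Per-trace amplitudes remain available via
`global_fit_mixture(..., share_amplitudes=False)`. The lag t₀ is always per
trace.

**Initialisation.** Deterministic and seed-free: k₃ starts at the
single-exponential rate fitted to the trace richest in wild-type monomer,
with k₂ = k₃/2 and k₁ = k₃/10; amplitudes start at pooled head/tail means.
Rates whose species carry no composition weight anywhere in the design (e.g.
k₁, k₂ with only a pure-wild-type trace) are held fixed, reported with
infinite standard error, and listed as under-determined.

**Model selection.** Two null hypotheses are fitted to the same traces: a
single-site-sufficient null (every species with ≥ 1 site decays at one shared
rate, decaying amplitude 1 − f₀) and a three-sites-required null (only the
all-wild-type species decays, amplitude f₃). In the comparison the nulls fit
their shared rate freely so the AIC contest is fair; the separate
`null_prediction` helper draws the theoretical curves at a rate fixed from
the pure-wild-type fit, as used for overlaying predictions on data. AIC is
the default criterion — with ≥ 50 points per trace the small-sample
correction is immaterial — and AICc and BIC are reported alongside.

## HX-MS stage

Centroids are intensity-weighted mean masses of decharged stick spectra.
Back-exchange correction scales the centroid shift between undeuterated and
100 %-deuterated references to the peptide's maximum exchangeable amides,
counted as length − 2 − (internal prolines from position 3 on): the first
two residues back-exchange fully and proline has no amide hydrogen — the
field's standard bookkeeping. Condition differences are reported per peptide
(protection negative) with a conservative dual significance rule appropriate
for n = 3 replicates: Welch t-test at α = 0.05 **and** |ΔD| > 2× pooled SD.

Bimodal envelopes are fitted as A·[(1−p)·G(m; μ_low, σ_low) + p·G(m; μ_high,
σ_high)] evaluated at the stick masses, with μ_high = μ_low + δ, δ > 0
enforcing the mode order, independent widths bounded below by 0.3 Da (the
natural isotope-envelope width floor), and means initialised at the 25th/75th
intensity-weighted percentiles. Weights converging outside [0.02, 0.98] are
flagged "effectively unimodal"; when the two fitted modes collapse onto each
other (separation < half the larger width — the degenerate ridge a
single-mode envelope produces), the fit is repeated as a single Gaussian with
all weight assigned to the low mode so the reported split is well defined.
When reference centroids are supplied, each mode's mean is converted to a
per-subpopulation relative deuteration.

## Site scanning

Window geometry is fixed: 13 residues, offsets −6..+6, additive score
assigned to the center, no terminal padding (centers 7..L−6). The call
threshold treats "below −5" as score ≤ −5, the stricter of the two published
phrasings and the one printed with the counting procedure. Region counts are
per-center by default, with per-run (maximal-run) counts also available,
since the tallying convention for "segments" is ambiguous. Matrix values are
a required input with provenance fields; the package ships no matrix. All
coordinates are 1-based with inclusive ranges (explicitly not BED half-open).

## Thermal transitions

The temperature-induced monomer→trimer transition is summarised by a
four-parameter Boltzmann sigmoid on the trimer fraction with flat baselines —
the standard two-state description with the fewest assumptions, chosen
because only the transition midpoint Tm is compared between constructs. Tm is
bounded to the measured temperature range; steepness (1/°C) is positive.

## Synthetic data

Generators emulate the study designs: titrations with probe at 5 nM over a
log-spaced titrant grid; dissociation on a 0–100 min grid at 1-min spacing
with amplitudes 200/80 mP-like units and a 5-min lag; the five-ratio mixing
design (1:0, 2:1, 1:1, 1:2, 0:1) with rates (0.005, 0.02, 0.05) min⁻¹;
bimodal envelopes at ~1.00235 Da stick spacing; melts over 4, 20, 25, 30, 35,
39, 42 °C. Noise is additive homoscedastic Gaussian on the signal
(multiplicative on envelope intensities, clamped non-negative; melt fractions
clamped to [0, 1]) — plate-reader polarization noise is approximately
signal-independent at these amplitudes. Seeds are mandatory; a generator spec
maps deterministically to one dataset, and every dataset embeds its ground
truth.

What the generators do **not** emulate: correlated drift or photobleaching in
polarization traces, heteroscedastic or Poisson-like MS intensity noise,
charge-state and retention-time artefacts, peptide-level back-exchange
variability, or differences in DNA-binding affinity between heterotrimer
species (assumed identical). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness to
every artefact of real instruments.

## Numerical choices

All fits use bounded trust-region nonlinear least squares (lmfit over scipy's
`least_squares`) with tolerances 1e−12, and a seeded 5-start perturbation
fallback when the first start fails to converge. Data-quality failures (flat
titration, no decay, no thermal transition, unmatched peptides) return
structured results with a flag and message; exceptions are reserved for
violated preconditions (negative concentrations, too few points,
non-monotonic time). Problem sizes in the test-suite simulation studies
(50–200 seeds per quantity, 101-point traces) match the default designs and
keep the full suite under a minute of fitting time.

## Known limitations

* The mixture model treats the chaperone machinery implicitly: rates are
  fitted constants, not functions of Hsc70/DnaJB1/ATP concentrations.
* Heterotrimer species are assumed to bind DNA with identical affinity and
  signal amplitude.
* The bimodal fit assumes exactly two Gaussian subpopulations; three-state
  exchange would be mis-assigned.
* Envelope inputs are decharged sticks; no raw spectrum processing.
* With per-trace amplitudes the slowest mixture rate is unidentifiable on a
  100-min window — a property of the design, not the optimizer (see the
  shared-amplitude discussion above).
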