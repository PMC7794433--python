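# Methods

This note records the models implemented in `qscomm`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter for
reproducing results.

## The channel model

The communication channel is decomposed into two stages measured (and
fitted) independently, then composed.

**Encoder — signal production.** Signal concentration versus cell
density (OD650, arbitrary units) follows the allometric law
`SM(N) = a N^b` with `a` in nM·(a.u.)⁻ᵇ and `b` dimensionless. The
mechanistic route to `b = 2` assumed here is that each cell produces
signal at a rate proportional to the *population* growth rate, i.e. per
cell ∝ μ(t)·N(t). With dN/dt = μN this gives dSM/dt = c·μ·N², which
integrates in closed form to SM = (c/2)(N² − N₀²): a power law of
exponent 2 once N ≫ N₀, with `a = c/2`. No signal degradation is
modelled; the signal is treated as stable on the experimental timescale.
`fit_allometric` performs a Levenberg–Marquardt least-squares fit in
linear space (weights 1/SE² when replicate standard errors are present);
a log–log ordinary-least-squares variant is available because the choice
of fitting space is a genuine degree of freedom for power laws — on clean
data both agree, on multiplicative noise the log fit is the maximum-
likelihood choice, on additive noise the linear fit is. Rows flagged
below the detection limit are excluded from fitting but never dropped
from the table.

**Decoder — response to signal.** Target-gene output versus signal
follows the Hill law `W(SM) = Wmax·SMⁿ/(Kmⁿ + SMⁿ)`. The response is
assumed to equilibrate within the assay's incubation window, so
`HillParams` carry no time dependence. The fit reports standard errors
and the reduced χ²; multiple replicate tables can be fitted concatenated
(one parameter set across datasets). A shared-shape option freezes `n`
(used by the biosensor module where calibration and sample curves measure
the same sensor).

**Lower limit of response (LLR).** After subtracting the blank (mean
response of the zero-signal rows), the LLR is the smallest tabulated
concentration whose per-concentration t-based lower confidence bound
(95% two-sided by default) exceeds zero, scanning upward in
concentration. The t interval on technical replicates is used because
the emulated assay runs 8 replicates per dose.

**Growth.** Batch growth is logistic,
`N(t) = Nmax / (1 + ((Nmax−N0)/N0) e^(−rt))`, with specific growth rate
μ(t) = r(1 − N/Nmax). "Growth rate" is reported both as the natural-log
rate μ (h⁻¹) and as the slope of log₂(OD) versus time (doublings per
hour, i.e. μ/ln 2); the two accessors are explicit because the bare
phrase is ambiguous. Exponential-phase slopes are estimated on the OD
window (0.1, 0.7) a.u. where OD is a trustworthy density proxy, and
compared by the standard two-sample slope t-test with n₁+n₂−4 degrees of
freedom. The OD→cell-density conversion (1 a.u. ≈ 4×10⁸ cells/mL) is
exposed as a constant and never applied implicitly.

**Response dynamics.** Per-cell reporter signal is
`RM(t)/N(t) = RM0/N(t) + RM1(t)/N(t)`: an inherited stock RM0 that only
dilutes with division, plus synthesis at per-cell rate
`k · Ŵ(SM(t)) · μ(t)` where Ŵ = W/Wmax is the normalized decoder output
evaluated at the encoder-law signal. `k` is therefore the per-cell
response at full decoder output and unit specific growth rate; no
reporter maturation or degradation is modelled, mirroring the
no-degradation assumption for the signal. Because dN = μN dt, RM1 is a
quadrature over density, `RM1 = k ∫ Ŵ(a νᵇ) dν`, which makes the fitting
model *linear* in (k, RM0); `fit_dynamics` exploits this by integrating
Ŵ once on the observation grid (all other parameters fixed at their
independent fits, as the two-stage design intends) and reports SEs and
R².

**Switch sharpness.** Composing the stages gives
`Ŵ(N) = (aNᵇ)ⁿ/(Kmⁿ + (aNᵇ)ⁿ)`. n_gen is defined as the number of
population doublings spanned by the central response window — by default
25% → 75% of maximum: `n_gen = log₂(u(1−l)/(l(1−u)))/(b·n)`. The window
is configurable; the central-quartile default is adopted because the
product form makes the roles of `b` and `n` explicit and the resulting
anchors (0.66 for b = 2.09, n = 2.3; 1.38 for b = 1; 1.52 for n = 1)
round to the headline values this comparison is meant to exhibit. A
root-finding evaluation is kept alongside the closed form as an internal
oracle. Parameter uncertainty is propagated by Monte Carlo with
independent truncated-normal draws per parameter — independence is an
approximation forced by the absence of a published covariance; it
overstates the band width slightly where (a, b) are anticorrelated.

## Biosensor quantification

Calibration (known concentrations) and sample (unknown medium, serially
diluted in signal-free medium) curves are fitted as Hill sigmoids; the
undiluted sample concentration is the horizontal offset
`Km_cal / Km_sample` with the sample's Km in dilution units. The SEs of
both Km estimates combine in quadrature, so the reported error includes
both curves' random errors. The "linear part" of the sigmoid is
operationalized as responses in [20%, 80%] of the fitted calibration
maximum: estimates are refused when no sample dilution lands there, and
a saturation flag marks any dilution above the 80% line (saturated
readings underestimate concentration). A point-wise alternative
(`method="linear_interp"`) inverts the calibration curve at each usable
dilution and takes the median. The LOD is the concentration whose net
response equals 3×SD of the blank replicates (the calibration being
blank-subtracted); it is strictly increasing in blank scatter and
undefined (error) when the threshold exceeds the calibration maximum.

## Single-cell statistics

**Deconvolution.** The measured intensity of a tagged cell is marker +
autofluorescence, assumed independent, so the tagged distribution is a
convolution. The control (untagged) sample enters as its empirical
distribution — binned to ≤ 200 point masses — and the marker as a
candidate lognormal; the predicted tagged histogram is the exact mixture
`Σᵢ wᵢ [F((edge−cᵢ))]` over control atoms, compared to the observed
histogram by Pearson χ² on shared Freedman–Diaconis bins (bins with
expected count < 4 pooled out). Nelder–Mead minimizes over
(μ_log, log σ_log) from moment-based starts. The reduced χ² of the
converged fit doubles as the closure diagnostic (≈ 1 on data generated by
the model).

**Hyperproducers.** Iterative one-at-a-time Grubbs at α = 0.05 on
log-intensities (the population is lognormal, so logs are the
near-Gaussian scale); iteration stops at the first non-significant
extreme. Flagged cells above the median are reported with their fold
brightness. Per iteration the null false-positive rate is ≤ α by
construction; empirically ~95% of clean samples of 1000 flag nothing.

**Co-localization.** Observed Pearson r of tagged (YFP, CFP) pairs is
referenced to a simulated null: independently drawn lognormal marker
intensities added onto real control cells, per channel. The null thereby
inherits the autofluorescence correlation but no marker coupling; the
two-sided p-value is the (add-one) rank of the observed r in the null
draws.

**Microplate QC.** Modified Z-score `0.6745(x − median)/MAD` with the
standard 3.5 cutoff (the method's customary value; the cutoff was not
otherwise specified). At n = 8 the MAD denominator is noisy and the
per-value false-positive rate on clean Gaussian replicates is ≈ 2.2%
(simulated), not the asymptotic ~0.1% — worth knowing when interpreting
exclusion counts. MAD = 0 disables exclusion with a warning.

## ATP ledger

The shipped configuration (`src/qscomm/data/comx168.yaml`) costs one
molecule of the pherotype-168 signal peptide as: biosynthesis of the ten
mature residues (ADPITRQWGD) at standard aerobic ATP-equivalent values
(total 238), translation of the full 55-residue precursor (54 peptide
bonds × 4 ATP = 216; the cleaved propeptide residues are assumed
recycled, so only their translation is charged), and 30 ATP for the
geranyl modification (two isoprene units at ~15 ATP each): 484 ATP in
total. The convention — mature-residue biosynthesis, full-precursor
polymerization — is recorded in the YAML and is the one that reproduces
the published total; alternative conventions can be expressed by editing
the configuration. The ~8 ATP figure for a short acyl-homoserine lactone
is cited reference data, not recomputed.

## Synthetic data: what is and is not emulated

Generator defaults are the study's operating point: logistic growth from
OD 0.02 to a carrying capacity of 1.0 a.u.; encoder (9.6, 2.09); decoder
(Km 4 nM, n 2.3, responses normalized to Wmax = 1); dynamics (k 760
M.U., RM0 5.5 M.U.·a.u.). The fermenter growth rate default is r = 0.7
h⁻¹ so the culture approaches carrying capacity within the ~8 h
time course the trajectory generator samples (15 points); flask-culture
examples use slower rates. Noise is multiplicative lognormal
(mean-one) for strictly positive measurements — 10% CV for
concentrations, 5% for reporter responses, 3% for OD — with 8 technical
replicates summarized to mean ± SE where the emulated assay does so.
Dose–response replicates additionally receive an additive background
floor (SD 0.003·Wmax): a purely multiplicative model would make the
blank noiseless and the LLR rule degenerate, whereas the floor gives
near-blank scatter of the kind the t-interval rule is designed for; with
it, the simulated LLR falls in the 0.2–0.5 nM range. The dilution series
spans 200 nM down to ~0.2 nM (18 × 1.5-fold steps) so the LLR region is
actually sampled. Cell populations are lognormal autofluorescence plus
lognormal marker; channel coupling enters as a shared log-normal factor
with a correlation knob, and hyperproducers as a discrete class at
`fold × median` marker level (a scaled-tail alternative would let dim
spiked cells hide inside the bulk, which is not what a distinct bright
class means). The neutral competition emulation draws independent
binomial plating counts around a fixed 1:1 composition: the transfer
bottleneck in the emulated assay is large, so composition drift is
negligible relative to plating noise (a compounding drift model would
also violate the independent-error assumptions of the regression CI on
the selection coefficient).

Passing round-trip tests on these generators shows the estimators are
consistent and correctly scaled *under the stated noise model*; it does
not validate the model against effects the generators omit — reporter
maturation delays, plate position effects, OD nonlinearity at high
density, signal adsorption, or segmentation errors upstream of the
per-cell tables.

## Numerical choices

ODE integration uses adaptive RK45 with rtol 1e-8 / atol 1e-12,
validated against closed forms (the rate law's (c/2)(N²−N₀²); the n_gen
closed form against Brent root-finding to < 1e-6). Nonlinear fits go
through lmfit (Levenberg–Marquardt) with positivity bounds and
data-driven starts; the dynamics fit is linear in its two parameters, so
convergence is not start-sensitive. Hill evaluation uses the (SM/Km)ⁿ
form to avoid overflow at large Kmⁿ. All randomness flows through
numpy's `default_rng` seeded from a single integer per generator call;
identical seeds give bit-identical tables. Degenerate inputs are
rejected with typed errors (`DomainError`, `InsufficientDataError`,
`FitError`, `QuantificationError`) rather than silently coerced:
negative densities or concentrations, non-increasing time grids, fewer
than 4 usable power-law rows, fewer than 5 distinct Hill concentrations,
single-replicate LLR rows, LOD thresholds beyond the calibration range,
MAD = 0.

## Problem sizes

The recovery simulations run 100 seeds per stage (24-point SM series;
19-dose × 8-replicate plates; 15-point trajectories), 50 seeds for
deconvolution at 5000 + 5000 cells, 100 seeds for Grubbs at 1000 cells,
and 40 plate simulations for the LLR — sizes at which the medians under
test are stable to well inside the asserted tolerances.

## Known limitations

The decoder is a phenomenological Hill law: the phosphorelay between
receptor and promoter is collapsed into the assumption that active
regulator is proportional to signal. Oxygen enters only descriptively
(the OD–O₂ correlation); no mechanistic oxygen → signal-production model
is fitted. The Monte-Carlo band ignores parameter covariance. The ATP
ledger is bookkeeping, not flux analysis. Encoder exponents b > 2
(feedback-like regimes) are expressible but nothing beyond the power law
is modelled.
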