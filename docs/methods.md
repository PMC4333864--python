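# Methods

## Rate extraction from cumulative gas curves

The observable is the cumulative headspace amount of CH₄ or CO₂ per bottle
over an 81-day incubation. The quantity entering the temperature analysis is
the *maximal* production rate, which approximates the substrate-unlimited
rate near the activity peak. It is estimated as the maximum over all
contiguous windows of `window_points` observations of the OLS slope of amount
vs time within the window. The default `window_points = 3` tolerates
single-point noise while still resolving a rate peak on a 3-day sampling
grid; `window_points = 2` reduces to finite differences. Negative best slopes
are floored at zero with a flag. The lag is the time-axis intercept of the
tangent line through the best window (slope = maximal rate through the window
centroid), clamped to the observation span; it is undefined (a distinct
error) when the maximal rate is zero.

Replicate bottles are independent, so per-temperature rates are the mean of
per-replicate maxima with the standard error of that mean — not the maximum
of a pooled curve, which would be biased upward by between-bottle noise. A
caller who prefers rate extraction on mean curves can average the series
before calling.

## Arrhenius activation energies

Rates are transformed to (x, y) = (−1/(R·T_K), ln P) with T_K = T°C + 273.15
and R the Boltzmann constant, default 8.623 × 10⁻⁵ eV K⁻¹ as conventionally
printed in this literature (the CODATA value 8.617 × 10⁻⁵ changes fitted
energies by < 0.1 % over 10–35 °C; the constant is a parameter). The
activation energy E is the OLS slope of y on x. E is invariant to any
positive rescaling of rates — only the intercept M moves by ln c — so the
arbitrary rate units of a headspace time series never matter. Points with
non-positive rates are excluded with a warning rather than failing the fit.

**Two regimes.** A community shift with temperature produces two Arrhenius
regimes. `fit_segmented` enumerates every cut between consecutive distinct
temperatures leaving at least `min_points` (default 2, admitting a 2-point
cold segment on a 6-temperature ladder) on each side, fits two *independent*
OLS lines (no continuity constraint — the two regimes are different
communities, not one curve), and returns the cut with minimal pooled RSS.
Ties break toward the more balanced split, then the lower break temperature.
The search is exhaustive, so the minimal-RSS property is exact, and a
brute-force re-enumeration is kept as a test oracle.

**One vs two regimes.** `select_model` applies the extra-sum-of-squares
F-test, F = ((RSS₁ − RSS₂)/2)/(RSS₂/(n − 4)), choosing the segmented model
iff p < α (default 0.05). Degenerate cases: both RSS ≈ 0 → single (relative
tolerance 10⁻¹²); RSS₂ ≈ 0 < RSS₁ → segmented; n ≤ 4 → the test is undefined
and is signalled so callers report the single fit with a warning. Because the
cut is itself chosen to minimize RSS₂, the nominal F distribution is
anti-conservative for this selection: with 6 temperatures and 5 % rate noise
the empirical rejection rate of a true single regime is ~0.12–0.15 rather
than α = 0.05. The test is kept in its classical form because it is the
field's convention; users needing exact size should calibrate α by simulation
(the acceptance script measures the realized size).

**mcrA normalization.** To remove the enzyme-abundance factor, maximal rates
are divided by the *largest detected* mcrA copy number over the sampled days
at that temperature (units become rate per 10⁶ copies). Not-detected entries
are missing data, never zeros; a temperature whose whole column is
not-detected is an error. The alternative per-day pairing of rate and
abundance is deliberately not implemented: maximal rate and maximal abundance
need not coincide in time, and pairing them day-by-day would conflate growth
dynamics with temperature response.

## Isotope fractionation and pathway classification

α_app = (δ¹³C-CO₂ + 1000)/(δ¹³C-CH₄ + 1000), dimensionless, > 1 whenever CH₄
is ¹³C-depleted relative to CO₂. Hydrogenotrophic methanogenesis depletes
¹³C in CH₄ much more strongly than aceticlastic methanogenesis, so larger
α_app means a larger CO₂-reduction share. Classification takes the *median*
α_app per temperature over the active window (records at or after
`active_from_day`, default 20 — roughly when CH₄ production peaks in warm
treatments): < 1.03 → "aceticlastic-dominated", ≥ 1.04 →
"mixed/hydrogenotrophic-enriched", otherwise "indeterminate". Both thresholds
and the window are parameters; the median is used because early-incubation
transients and per-day noise should not flip a label. No quantitative
two-source apportionment of the hydrogenotrophic fraction is attempted — that
requires pathway-specific fractionation factors that a field study rarely
constrains.

## T-RFLP and clone-library statistics

Percent abundance of a peak is A_p = 100·height/Σheights. The minor-peak
filter keeps peaks with A_p strictly > 1 % and pools the removed mass into a
"Diverse" residual; retained percents are *not* renormalized, so retained +
Diverse = 100 exactly and profiles remain comparable across samples.

In silico fragment prediction reads the amplicon 5′→3′ from the fluorescently
labeled primer end — for a 5′-labeled reverse primer that means the reverse
complement of the deposited (sense) orientation — and cuts at the first exact
occurrence of the recognition site (TaqI: TCGA, cut offset 1 because the
labeled fragment ends after the T of T^CGA). Ambiguous bases never match; a
site-free sequence reports its full length with an "uncut" flag. Predicted
integer sizes are matched to electrophoretic peaks with ±1 bp tolerance,
since size-calling drifts by about a base against in silico lengths.
Ambiguous assignments (several taxa sharing a size, e.g. an aceticlastic
methanogen and a non-methanogenic crenarchaeote both at 185 bp) are returned
in full, never silently resolved. If an amplicon lacks the labeled primer
region entirely the measured fragment may be short by up to the primer
length; sequences here are assumed to start at the primer.

Good's coverage is (1 − n₁/N)·100 with n₁ the singleton-OTU count.
Rarefaction uses the analytic hypergeometric expectation
E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)), computed with log-gamma arithmetic; a
seeded resampling estimator is provided purely as an oracle. OTU clustering
itself is out of scope — counts are caller-supplied.

## The synthetic experiment generator

Defaults encode the reference study conditions: temperatures
{10, 15, 20, 25, 30, 35} °C, 81 days sampled every 3 days, triplicate
bottles, qPCR on days {3, 24, 49, 65, 81}, isotopes and clone libraries at
{15, 25, 35} °C, libraries of 100 clones at day 49.

* **CH₄**: modified Gompertz cumulative curve parameterized by (amplitude,
  maximal rate, lag), the standard microbial-kinetics sigmoid with an
  identifiable maximal slope; the maximal rate follows a two-regime Arrhenius
  law (E_low 3.9 eV ≤ 17.5 °C, E_high 1.1 eV above, continuous at the break,
  scaled to 11.884 units/day at 35 °C — the rate unit is a convention, see
  above). Lag(T) = 10·exp(−0.08·(T − 30)) days, so ~50 days at 10 °C and
  ~7 days at 35 °C, inside the observation window everywhere. Amplitude =
  20·rate, placing the inflection ~7 days after the lag.
* **CO₂**: lag-free linear accumulation with a single 0.6 eV regime.
* **mcrA**: logistic growth from 0.01×10⁶ copies toward a carrying capacity
  that blends a cold plateau (~0.9×10⁶, 0.006/°C) with a warm branch
  (60×10⁶ at 35 °C, 0.065/°C) across ~17.5 °C — the two-level shape observed
  in temperature-ladder qPCR tables — with growth rate 0.25·exp(0.05·(T−35))
  d⁻¹ and a 0.1×10⁶ detection limit; replicate means below the limit are
  emitted as the literal token "ND", never zero.
* **δ¹³C**: CH₄ is the two-endmember mixture f_h·(−80‰) + (1−f_h)·(−40‰)
  with the hydrogenotrophic fraction f_h = 0.5/(1 + exp(−(T − 20)/3)) —
  logistic in temperature, constant in time, rising from ~0.08 at 15 °C to
  ~0.5 at 35 °C; CO₂ starts at −18‰ with a +0.01‰/day drift. These choices
  put the cold treatment's α_app below 1.03 and the warm ones above 1.04, the
  qualitative pattern the classifier must resolve.
* **Community**: taxon weights grow exponentially at
  g(T) = g_ref·exp(b·(T − 25)) per day from initial fractions; hydrogenotrophs
  have larger g_ref and b than the aceticlastic Methanosarcinaceae, so the
  185-bp fragment dominates cold/early samples and the 91/392-bp fragments
  rise when warm. A 20-taxon rare tail (8 % initial mass) gives libraries
  singletons and profiles a realistic "Diverse" residual. T-RFLP heights and
  clone counts are multinomial draws (10 000 counts / 100 clones) from these
  fractions, with same-size fragments summed into one peak.
* **Noise**: multiplicative lognormal on gas (σ = 0.05) and per-replicate
  qPCR (σ = 0.2); additive Gaussian (1‰) on δ values — positive observables
  get multiplicative noise, signed per-mil values additive.
* **Synthetic amplicons**: `synthesize_amplicons` builds random 800-bp
  stand-ins for clone sequences whose only designed feature is the TaqI site
  position, so labeled-end digestion returns each taxon's fragment size
  exactly. They are stand-ins, not reconstructions of any deposited sequence.

What the generator does *not* emulate: substrate (acetate/propionate/H₂)
pool dynamics, carbonate equilibrium and pH control of headspace CO₂,
spatial soil structure, chimeras/sequencing error in clone libraries, or
electrophoretic size-calling drift. Tests passing on synthetic data therefore
certify the estimators' correctness under the stated generative model, not
robustness to those real-data artifacts.

## Numerical choices

Determinism: every stochastic step takes an integer seed; the dataset-level
simulator derives independent child streams per observable layer from one
seed via seed sequences. OLS is delegated to `scipy.stats.linregress`; the
2-point-window r² is defined as 1. RSS comparisons in model selection use a
10⁻¹² relative tolerance to classify "zero". Rarefaction binomials are
evaluated in log space. Monte-Carlo problem sizes — 200 replicates for
parameter recovery, 1000 for test size, 10⁴ resampling reps for the
rarefaction oracle — give binomial standard errors comfortably below the
decision margins they support.

## Known limitations

* The breakpoint search scores cuts only between distinct temperatures; with
  two temperatures per segment the CI on that segment's slope does not exist
  (n = 2), which is why calibration studies use all replicate points.
* The F-test's nominal size does not account for breakpoint selection (see
  above); its realized size is reported, not hidden.
* `classify_pathway` uses fixed thresholds on a continuous quantity;
  treatments straddling 1.03–1.04 are reported "indeterminate" rather than
  forced into a class.
* Rate extraction assumes the sampling grid resolves the activity peak; on a
  coarse grid the window slope underestimates the true maximal rate by a few
  percent (this discretization bias cancels almost entirely in E, which
  depends on rate *ratios* across temperatures).
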