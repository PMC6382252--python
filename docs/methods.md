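# Methods

## Generative model

Observed vectors are flattened F x T cochleagrams, y in R^D (D = F*T,
frequency-major).  Binary latents s in {0,1}^H follow an i.i.d.
Bernoulli(pi) prior; the observation density is isotropic Gaussian around a
superposition of the active non-negative fields W_h in R^D:

* **MCA** (primary model): mean = element-wise max over active fields; the
  max over an empty active set is the zero vector, so the all-zero state has
  a well-defined likelihood.
* **BSC** (control): mean = sum of active fields; W unconstrained in sign,
  with an optional projection of W onto the non-negative orthant after each
  M-step (`clamp_nonneg`), used to show that inhibitory STRF subfields do
  not require signed fields even in the linear model.

The max reflects the log-max rule: cochleagrams of concurrent sources
combine approximately by a point-wise maximum, because band energies are
sparse and the compressive non-linearity makes the louder source dominate
each cell.  That rule is itself demonstrated rather than assumed
(`demo_logmax`): it holds in the compressive regime of the front-end, so
sources are presented 60 dB above the knee of `10*log10(1+x^2)` (gain 1000
on peak-normalized waveforms).  At presentation levels near the knee the
non-linearity is quasi-linear and the sum composes better — a caveat worth
knowing when feeding very quiet material.

## Cochleagram front-end

Gammatone filterbank, g(t) = a t^(n-1) exp(-2 pi b t) cos(2 pi f_c t + phi),
order n = 4, phase 0, with 32 center frequencies equally spaced on the
ERB-rate scale between 1 kHz and 22.05 kHz (endpoints exact).  The bandwidth
parameter is b = 1.019 * ERB(f_c) with the Glasberg–Moore ERB
(24.7 + f_c/9.26449 Hz); `a` is set per channel for unit peak gain at f_c.
The default realization samples the impulse response directly (FIR) at
44.1 kHz, truncated at 20 envelope time constants — the 4th-order envelope
t^3 e^(-2 pi b t) peaks at 3 time constants and is still ~87% of peak at 4,
so a much longer kernel is needed before the tail is negligible (<~1e-5 of
peak at 20).  Slaney's all-pole IIR cascade is available as
`filter_impl="iir"` (coefficients from the classic second-order-section
factorization, gain normalized numerically at f_c).

Band envelopes: RMS over a 20 ms window with 10 ms step, frames left-aligned
at t=0, trailing partial frame dropped (a 160 ms snippet gives exactly 15
frames); compression `10*log10(1 + x^2)`; snippets of 160 ms cut with 32 ms
overlap (hop 128 ms), remainder dropped; each flattened cochleagram divided
by its L2 norm, all-zero cochleagrams dropped and counted.

Waveforms not at 44.1 kHz should be resampled by the caller; the synthetic
generator always produces 44.1 kHz.

## Expectation Truncation

The exact posterior over 2^H states is replaced, per datapoint, by the
posterior restricted to a candidate state set K_n:

* candidates: the H' units with the highest cosine similarity between their
  field and the datapoint (ties to the lower index; a zero-norm datapoint
  gets the first H' units, with a warning);
* states: all binary vectors supported on the candidates with |s| <= gamma,
  plus the all-zero state, plus the singleton state of *every* unit (so no
  unit is starved of posterior mass);
* weights: normalized with log-sum-exp.

With H' = H and gamma = H the posterior is exact; tests assert equality with
exhaustive enumeration at H = 8 to 1e-10.

**Annealing.**  The E-step noise variance is multiplied by a temperature
decreasing linearly from 10 to 1 over the first half of the iterations
(T = T_end thereafter); the M-step uses sigma at face value.  While T > 1 a
small seeded Gaussian perturbation (std `anneal_param_noise * sigma`,
shrinking linearly to zero at T = 1; default coefficient 0.1) is added to W
after each M-step, the usual second ingredient of deterministic annealing:
it lets fields merged by the flattened posterior separate again.  At T = 1
the updates are exactly the deterministic M-step, so exactness checks
against exhaustive EM are unaffected.  Stopping is by fixed iteration count
(70 at full scale; 40 on the bars benchmark; 20 at desk scale) — no
convergence tolerance.

**Restarts.**  EM over this model class has a characteristic local optimum:
a field can converge to the *union* (element-wise max) of two dictionary
elements, because the Bernoulli prior rewards explaining their
co-occurrences with a single unit, while the datapoints of the orphaned
element are then best explained by the all-zero state — so no gradient ever
pulls a field toward them.  Annealing alone does not reliably escape this
basin on exactly-complete dictionaries.  `fit_et(n_restarts=k)` therefore
repeats the fit from k differently seeded initializations and keeps the run
with the highest final truncated free energy; the selection uses the
training objective only.  The union solution's free energy is far below the
full solution's (it leaves one element's data unexplained), so the
selection is unambiguous.  The bars benchmark uses 5 restarts;
overcomplete fits (H well above the number of latent structures, as in the
full-scale and desk profiles) are much less prone to the trap and default
to a single run.

**M-step.**  W: ratio of A^rho-weighted data sums, where A^rho is the
derivative of the rho-softened max (rho = 20), computed in max-scaled form;
entries with (x/max)^(rho-1) below 1e-12 are exact zeros — since
A <= z^(rho-1), any z below (1e-12)^(1/(rho-1)) can be skipped, which is
what makes the compiled inner loop fast.  For singleton states the softened
max reduces to the field itself, so its derivative is exactly 1 in every
dimension, including cells currently at zero; this matters, because it is
the only route by which a field can regain support on cells the
non-negativity clamp has zeroed.  Updated W is floored at 0 (MCA).
pi: mean expected activity, clipped to [1/(10NH), 1-1e-6].  sigma: root
mean expected squared residual under the *exact* max.  Because states with
more than gamma active units are cut from K_n, the worst-explained
datapoints would bias sigma upward; following the standard ET procedure the
sigma update uses only the N_cut datapoints with the highest truncated
marginal likelihood, N_cut = N * P(|s| <= gamma) under the current pi.  The
correction vanishes without truncation.  Dead units (M-step denominator
below 1e-10*N) keep their previous column and are logged, not reseeded.
BSC: W solves the expected least-squares normal equations
(pseudo-inverse on singularity, with a warning); the truncated exact second
moments <s s^T> are used, not a factored approximation.

**Initialization.**  Each field = data mean + Gaussian noise with variance a
quarter of the data variance (clamped at 0 for MCA); sigma = data standard
deviation; pi = 30/H, clipped to at most 0.5 so small dictionaries (H < 60)
still start with a valid probability.

**Monitoring.**  Per iteration: truncated free energy of the incoming
parameters at T=1, pi, sigma, temperature, dead-unit count.  After the
annealing phase the free energy is non-decreasing up to small numerical
slack on the tested instances; with changing candidate sets it is not
guaranteed monotone in general.

## STRF estimation

Responses are truncated posterior means <s> at T = 1 (whether the original
analysis reused annealed training-time posteriors is unknowable from the
text; T=1 is the principled choice for a trained model).  The read-out is
the closed-form ridge solution; the implementation verifies the ridge
normal equations (1e-8 relative) and that the solution beats the zero
matrix on the regression objective, on every call.

**lambda.**  The default is the mid-range (arithmetic mean of min and max)
of the eigenvalues of the *sample covariance* (1/N) sum y y^T, so the ridge
term lambda*N*I sits mid-spectrum of the Gram matrix sum y y^T.  Reading
the rule on the unnormalized Gram instead would make the regularizer exceed
the data term by a factor ~N and shrink every STRF to ~0.  For the
explaining-away demonstration, whose 64-dimensional Gram is well
conditioned, 1% of the mid-range value is used — the rule exists to tame
near-singular spectra of large natural-sound covariances, and the
demonstration's qualitative pattern is robust across a 10x–100x range of
that choice.

Field usage = mean posterior activation; "frequently used" fields are those
covering 80% of the total activation mass.  The negative-energy fraction of
a filter (sum of squared negative entries over sum of all squared entries)
quantifies how strongly explaining away shapes it.

## STRF characterization

* **Modulation transfer**: 2D FFT of the raw F x T STRF (no windowing or
  mean removal).  Channels are treated as uniformly spaced in log-frequency
  at the mean octave spacing of the actual ERB centers (the ERB scale is
  near-logarithmic over 1–22 kHz); scale in cycles/octave, rate in Hz from
  the 10 ms step.  The amplitude spectrum is folded to scale >= 0 with
  signed rate; positive rate = upward sweep; argmax ties break to smallest
  |rate|, then smallest scale, then positive rate.
* **Histograms**: rate bins of 12 Hz (default) or 8 Hz (wide mode); scale
  bin 0.25 cycles/octave (not dictated by anything — configurable);
  out-of-range points are clipped into edge bins so counts are conserved.
* **chi-squared dissimilarity**: sum over cells with h1+h2>0 of
  (h1-h2)^2/(h1+h2).
* **Tuning widths**: rectify one polarity, square, sum over the other axis,
  threshold at 50% of the profile maximum; the span may be non-contiguous.
  Frequency width sums the octave widths of qualifying channels (the
  alternative "lowest-to-highest qualifying channel" reading is not
  implemented as the default; summed widths is the measure consistent with
  non-contiguous spans).  Temporal width = qualifying bins x 10 ms.
* **Zero-norm exclusion**: STRFs with exactly zero L2 norm (<= 1e-15) are
  dropped and counted before population analyses.
* **Localization**: a field is called localized when its half-max support
  (cells >= half the peak magnitude) occupies at most 25% of cells — the
  same half-height convention as the tuning widths.  Energy-mass-based
  alternatives (e.g. smallest cell set holding 90% of squared energy,
  reported as `concentration_fraction`) judge fields more diffuse, because
  log compression flattens filter-skirt leakage into a broad low-level
  pedestal; both numbers are reported by the acceptance script.

## Synthetic data

The generator replaces a natural-sound corpus: each waveform is a sparse
stream of acoustic *events* (~4 per second, Poisson) — tones at ERB channel
centers and linear chirps between channel frequencies by default, with
band-passed noise bursts available — each gated to a 0.1–0.8 s window with
5 ms cosine ramps, peak-normalized per component and presented at 60 dB
above the compressor knee.  The windows matter: with components running
unbroken through every snippet the learned fields could carry no temporal
structure at all, and indeed come out temporally diffuse.  Snippets that
fall entirely between events are silent and dropped by the pipeline; the
desk corpus is sized so that ~5000 cochleagrams remain.  What the corpus
emulates: sparse, mostly-disjoint spectro-temporal energy, tonal/sweeping
structure with onsets and offsets, realistic front-end statistics.  What it
does not: speech phonetics, harmonic stacks, temporal dependencies across
snippets, room acoustics, amplitude-modulation statistics.  Passing tests
therefore show the *machinery* behaves as specified under matched model
assumptions, not that cortical parameters would be recovered from real
recordings.

Generative sampling draws s ~ Bernoulli(pi) i.i.d., composes active fields
with the element-wise max (zero vector when none active) and adds
*untruncated* Gaussian noise — sampled observations may go slightly
negative, matching the model's own Gaussian assumption; non-negativity
tests use sigma = 0.

Field layouts: `bars` (one field per full grid row/column; any row/column
pair overlaps in exactly one cell), `blobs` (random smooth bumps with hard
zero support outside a radius), `overlapping_pairs` (a chain of bumps in
which consecutive fields share support, plus one field whose support is
disjoint from all others — the explaining-away construction).

## Problem sizes and defaults

| stage | full-scale default | desk profile |
|---|---|---|
| corpus | 3640 waveforms (~20 snippets each) | 287 waveforms (~5000 retained snippets) |
| dictionary | H = 1000 | H = 100 |
| truncation | H' = 10, gamma = 6 | H' = 8, gamma = 4 |
| EM | 70 iterations, anneal 10->1 over first half | 20 iterations, same schedule |
| rho | 20 | 20 |

The desk profile is the configuration the test suite and the acceptance
script run end to end (~3–4 minutes); the bars benchmark (D=25, H=10,
N=2000, 40 iterations) is the quantitative parameter-recovery check.  The
EM inner loop is compiled with numba; the first call in a fresh process
costs a few seconds of compilation.

## Known limitations

* The truncated free energy is not guaranteed monotone when candidate sets
  change between iterations; it is asserted only on controlled instances.
* sigma estimation relies on the N_cut coverage heuristic; for priors where
  P(|s| <= gamma) is badly mis-estimated early in training the noise scale
  can wobble before annealing ends.
* The modulation-tuning axis treats ERB spacing as uniform in octaves; below
  ~500 Hz that approximation would degrade (irrelevant for the 1–22 kHz
  default band).
* `run_pipeline` holds the N x D dataset and the N x H response matrix in
  memory; at the full-scale defaults this is ~1.1 GB.
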