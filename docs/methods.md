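# Methods

## Model

A single channel's epoched, baseline-corrected trials are collected in an
N×T matrix Y. Each trial is modeled as an amplitude-scaled common waveform
plus a scaled copy of the waveform's first temporal derivative,

y_i = a_i·(B b) + ρ_i·(D b) + ε_i,

where B (T×q) holds orthonormal polynomial basis functions on the sample
grid, D their exact analytic first derivatives in units of B per ms, b the
waveform coefficients, a_i the trial's dimensionless amplitude scale, and
ρ_i = a_i·τ_i the derivative coefficient. The derivative term is the
first-order Taylor expansion of a continuous latency shift: W(t−δ) ≈ W(t) −
δ·W′(t), so a trial whose response occurs δ ms *later* has ρ_i = −a_i·δ.
The reported latency shift is λ_i = −ρ_i/a_i, making positive λ mean
"later". The expansion is first-order, so λ estimates are accurate for
shifts small relative to the waveform's curvature scale (here, peak width);
larger shifts are recovered with a compressive bias but preserved rank
order. ε is treated as Gaussian; estimation is ordinary (unwhitened) least
squares throughout — no temporal noise covariance is modeled.

Trials with |a_i| below 5% of the median |a| (configurable, `amp_floor`)
have their latency reported as NaN and flagged: λ = −ρ/a is undefined as
a → 0.

## Basis

The basis is built by a Stieltjes three-term recurrence with full
re-orthogonalization, on the time variable rescaled to [−1, 1] (raw
monomials over hundreds of samples are numerically singular). Column j is a
polynomial of exact degree j; columns are orthonormal under the discrete
inner product over the sample grid to ~1e−14 up to at least T = 2048,
q = 32. Derivatives are propagated through the same recurrence — never
finite differences — and carry the 2/(t_max − t_min) chain-rule factor. Any
discretely orthonormal polynomial family is equivalent here; orthonormality
(not mere orthogonality) keeps the per-trial regressions well scaled.
The default q = 20.

## Estimation

Alternating exact least squares:

1. Initialize b by projecting the grand average onto the basis.
2. Trial step: given the waveform(s), each trial's (a, ρ) is the OLS
   solution of a regression on the evaluated waveform and its derivative.
   The design matrix is shared by all trials, so all N regressions are one
   matrix solve; with W waveforms the 2W regressors are fit jointly. If the
   two regressors are numerically collinear (e.g. a constant waveform, whose
   derivative vanishes), the fit falls back to amplitude-only with ρ = 0 and
   a warning.
3. Waveform step: given all (a_i, ρ_i), b solves the stacked (N·T)×q
   least-squares system whose per-trial design is Σ_w a_i^(w)·M_w B +
   ρ_i^(w)·M_w D (M_w the support masks), via accumulated normal equations;
   a normal matrix with condition number above 1e12 raises a numerical
   error rather than being silently regularized.
4. Stop when the relative RSS decrease over a full iteration falls below
   `rel_tol` (default 1e−8; the criterion for a "negligible" decrease),
   when RSS reaches numerical zero (1e−20 of the data energy — reached on
   noiseless model-generated data, where the RSS then fluctuates at
   roundoff level), or at `max_iter` (default 200).

Each half-step is an exact LS solve, so the RSS trace is non-increasing;
this is asserted in the test suite across noisy, noiseless, one- and
two-waveform fits. The model has a scale indeterminacy (b → c·b, a → a/c,
ρ → ρ/c); after each waveform step, and once more after the final trial
step, the fit is re-gauged so the grand mean amplitude is exactly 1, making
a_i interpretable as relative amplitude and stabilizing AIC comparisons.

On data generated by the model itself the alternating fit recovers (b, a,
ρ) to machine precision within a handful of iterations, and on a 5-trial
instance it reaches the same RSS as a generic nonlinear least-squares
optimizer over all parameters jointly (tested to 1e−6 relative). One known
slow regime: when all ρ_i are within a small fraction of a sample of zero,
the estimation valley along the collective time-shift direction is
second-order flat and convergence along it is slow — irrelevant at
physiological jitter scales.

## Multiple waveforms and model selection

A split model keeps ONE coefficient vector b: the waveforms are the single
underlying shape cut into masked pieces whose per-trial (a, ρ) move
independently. (Giving each piece free coefficients would also be severely
ill-posed: a degree-19 polynomial can be numerically zero on half the
support, driving the stacked normal matrix's condition number to ~1e17.)

The split search follows the fitted one-waveform model: candidate split
points are every sample strictly between two adjacent local extrema of the
average model inside the analyst's range (extrema on the sample grid,
strict inequality against both neighbors, plateaus counted at their
leftmost sample). Each candidate is scored with b frozen — only the
per-trial parameters are re-estimated, jointly across pieces — keeping the
scan linear-time; the minimum-RSS split is then refit by the full
alternating algorithm (a frozen-b variant is available via `refit=False`).
Greedy recursion handles W > 2: the component whose best split lowers the
AIC most is split, while the AIC strictly decreases.

Models are compared with the Gaussian least-squares AIC,
n·ln(RSS/n) + 2k, n = N·T, with k = q + 2·W·N: the shared waveform
coefficients plus an amplitude and a derivative coefficient per trial per
waveform. The split location itself is not counted as a parameter. The same
criterion, with k = q + 2N, selects the number of basis functions.

Known limitation: k is the *nominal* parameter count. Because the model is
bilinear and fitted by minimizing RSS over (b, a, ρ) jointly, its effective
degrees of freedom exceed k — on pure white noise each added basis function
removes roughly 4–5 noise-variance units of RSS rather than 1 — so the AIC
is biased toward complexity, and markedly so under temporally correlated
noise (see the over-selection rates below). Users comparing waveform counts
on strongly autocorrelated data should treat a small AIC preference for the
more complex model with suspicion; prewhitening is out of scope here.

## Single-trial peaks

Given a converged fit and an analyst-specified range [t_lo, t_hi] (closed,
in ms) with a polarity (max / min / absolute), each trial's modeled
contribution of the selected waveform, a_i·(B b) + ρ_i·(D b), is evaluated
on the sample grid restricted to the range and the waveform's support; the
argextremum's time is the trial's latency and its value the amplitude. Ties
break to the earliest sample; no sub-sample interpolation is performed;
extrema at a range endpoint are returned but flagged (`at_boundary`), since
an edge extremum usually signals a mis-specified range; trials whose range ∩
support is empty are flagged undefined.

The classical comparator, `peak_pick`, smooths each *raw* trial with a
normalized Gaussian kernel (standard deviation in ms by default — the
full-width-at-half-maximum convention is selectable — truncated at ±4 sd,
reflect-padded) and takes the windowed extremum directly.

## Synthetic-data generator

`simulate` emulates a two-component late-positive-complex scenario:

| parameter | default | meaning |
|---|---|---|
| epoch | 600 ms, 300 samples at 500 Hz | stimulus-locked window |
| peaks | Gaussian bumps at 250 and 400 ms, sd 40 ms, polarity +1, base amplitude 1 | two overlapping positive components |
| amplitude | lognormal(µ_log = 0, σ_log = 0.25), truncated to [0.5, 2] by rejection | per-trial scale |
| latency | N(0, sd), sd ∈ {0, 10, 20, 30} ms | per-trial shift, evaluated analytically at shifted times (never integer-sample rolls, so sub-sample jitter is representable) |
| condition | `fixed` / `free` | one draw shared by both peaks (one signal) vs independent draws per peak (two signals; worst case) |
| noise | AR(5), coefficients (0.35, 0.20, 0.10, 0.05, 0.02), ≥500-sample burn-in | temporally correlated background; white selectable |
| SNR | {0.5, 1, 2}, default 1 | RMS(clean)/RMS(noise) over the whole matrix; the realization is rescaled to hit the target exactly |

The epoch geometry keeps the default 20-function basis adequate for the
default signal: the degree-19 representation error of the two-bump shape is
0.7% (relative L2), far below the 2.7–18% bias that latency jitter imposes
on the grand average. On a longer epoch with the same 40 ms peaks (e.g.
1024 ms), q = 20 underfits its own default signal (18% error) and the
waveform comparison would measure basis truncation, not estimation quality.
SNR is an amplitude (RMS) ratio because the EEG literature uses both
amplitude and power conventions; the convention is stated rather than
assumed. `experiments.simulate_from_model` additionally generates
*correct-model* data (the latency effect is exactly the derivative term),
used to separate model-mismatch effects from noise effects in the
selection experiments.

What the generator does **not** emulate: multi-channel structure, trial-to-
trial waveform shape changes, non-Gaussian or nonstationary noise, artifact
contamination, and amplitude–latency correlations. Passing recovery tests
on these simulations therefore demonstrates correctness of the estimator
under its own assumptions plus Gaussian-bump/AR noise, not performance on
arbitrary recordings.

## Study results (computed by `scripts/acceptance.py` and the test suite)

Under the default conditions the experiments reproduce the method's
qualitative signature: recovery correlations degrade monotonically as SNR
drops and are worst in the low-SNR/low-jitter cell; at ≥20 ms jitter the
fitted waveform is closer to the true shape than the grand average in the
large majority of replicates; the free condition selects two waveforms
almost always while correct-model data with white noise essentially never
over-select; AR(5) noise drives the over-selection rate far above the
white-noise rate; winning splits fall between the true peak centers; and
smoothing peak-picking at its best kernel width does not beat model-based
extraction. Exact numbers for a given seed are written by the acceptance
script; replicate counts (5 datasets for recovery correlations, 50 for the
rate estimates) were chosen so the whole study runs in about a minute on
one CPU.

Numerical notes: all solves are dense (T ≤ a few thousand); least squares
via LAPACK-backed `lstsq`/`solve`; collinearity threshold 1e−10 on the
singular-value ratio; truncated-lognormal rejection sampling aborts if the
bounds reject >99% of draws; AR stationarity is checked via the
characteristic roots at construction.
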