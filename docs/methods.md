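# Methods

## The SAR synapse model

`sarsyn` implements a phenomenological model of a chemical synapse in which
two Ca²⁺-sensor pathways — one fast (synchronous), one slow (asynchronous) —
compete for a single readily-releasable vesicle pool. It extends the
Tsodyks–Markram short-term-plasticity (STP) description: when the
asynchronous pathway is switched off (`U_ar = 0`) the deterministic model
reduces exactly to classical STP, which the test suite asserts to machine
precision.

State variables and dynamics (time constants in ms):

* `u_sr(t)` — synchronous release probability. Each presynaptic spike jumps
  it by `U_sr·(1 − u_sr)`; between spikes it decays exponentially to 0 with
  `tau_sr`.
* `u_ar(t)` — asynchronous release probability **rate** (1/ms). Spikes jump
  it by `U_ar·(U_max − u_ar)`; it decays with `tau_ar` to the spontaneous
  floor `U0` (0 by default; a positive `U0` produces spontaneous miniature
  release without any spiking).
* `N(t)` — available vesicles, `0 ≤ N ≤ N_F` (stochastic mode), or the
  continuous transmitter amount `x(t) ∈ [0, X_F]`, `X_F = N_F·x0`
  (deterministic mean-field mode). `x0` is the quantum size, the transmitter
  content of a single vesicle.

Stochastic mode draws per bin of width `dt`: at a spike,
`n_sr ~ Binomial(N, u_sr(t+))` from the pre-spike pool; then
`n_ar ~ Binomial(N − n_sr, u_ar·dt)` from the remainder; and every bin
`r ~ Binomial(N_F − N, dt/tau_d)` replenished vesicles, with
`N ← N − n_sr − n_ar + r`. Released transmitter per bin is `x0·(n_sr + n_ar)`.
Drawing the asynchronous count after the synchronous one makes the overlap
correction exact at the bin level and guarantees `N ≥ 0` without rejection;
at `dt = 0.05` ms the ordering is numerically irrelevant. Replenishment is
drawn in every bin, including spike bins.

Numerical choices:

* Fixed time grid, default `dt = 0.05` ms (the sampling interval of the
  voltage-clamp recordings the inverse pipeline targets). Spike times are
  snapped to the nearest bin; a snap of more than `dt/2` is an error.
* Probability decays use exact exponential factors per bin, not Euler steps
  — unconditionally stable and bin-width independent, since the dynamics are
  linear between spikes.
* Deterministic resource update: `dx/dt = (X_F − x)/tau_d − x·u_ar` is
  integrated per bin with `u_ar` frozen at its bin value (exponential update
  with effective rate `1/tau_d + u_ar`). The reported per-bin asynchronous
  release uses the bin-start value `x·u_ar·dt`; the O(dt²) inconsistency
  with the exact update is ~10⁻⁵ relative at the default grid.
* The stochastic replenishment probability is `dt/tau_d` per bin while the
  deterministic update uses the exact exponential factor; the difference is
  O((dt/tau_d)²) and invisible against Monte-Carlo error at 500 trials.
* One seedable generator per simulation; multi-trial ensembles draw all
  trials jointly, bin by bin, from a single generator.

## Receptor model and current components

Under voltage clamp the IPSC is the release rate convolved with a single
exponential kernel `K(s) = A·e^(−s/tau_syn)` and delayed by the transmission
delay `D` (default 0.75 ms): the gain `A = w·(v − E_rev)` is constant, so
only the product `A·q` is observable. The convolution is computed with the
exact one-pole recursion (`scipy.signal.lfilter`), and the synchronous /
asynchronous current components are obtained by convolving each release
component separately; their sum equals the total current bin-wise by
linearity. All internal computation uses current magnitudes and a positive
gain; the negative-going IPSC sign is applied only at I/O. Receptor
saturation and multi-state kinetics are out of scope — the kernel is a pure
exponential.

## Inverse pipeline

1. **Leak subtraction** — the leak is the mean current in a baseline window
   before the train (≥ 20 samples). Because an inhibitory synaptic current is
   non-positive, any corrected sample above `−ε` is clamped to `−ε` with
   `ε = 0.2` pA, small against typical IPSC amplitudes.
2. **Kernel estimation** — `tau_syn` is fitted by least squares
   (`a·e^(−t/τ) + b`) to the falling phase of an isolated event (miniature
   IPSC or single-spike response); fits outside (0.1, 100) ms are flagged.
   A default of 5 ms is appropriate for fast-spiking→pyramidal GABA-A
   synapses.
3. **Sequential constrained deconvolution** — walking the trace bin by bin,
   the release for bin *i* is the non-negative value that matches the
   measured magnitude after subtracting the carried-over prediction, capped
   so that the predicted current's future exponential decay never exceeds
   the measured trace within a lookahead window (default `5·tau_syn`;
   beyond that the bound is vacuous against the ε floor, and the truncation
   keeps the cost O(N·W)). This is what makes the estimate causal,
   non-negative and ringing-free where sparse-event Fourier deconvolution
   fails. The output is the scaled rate `q̃ = A·q` (pA/ms) — absolute units
   are unidentifiable. On noiseless synthetic input the round trip
   (convolve → deconvolve) is exact to ~10⁻¹⁴ relative L2; the 1% figure
   quoted in the tests is a conservative bound.
4. **Delay estimation** — per spike, the lag of the `q̃` peak within 3 ms;
   the median over spikes estimates `D`.

## Period statistics and likelihood fit

Release is integrated over spike-keyed periods: a synchronous window per
spike (duration 1.1 ms; offset 0.3 ms after the spike for deconvolved
recordings, 0 for simulated release where the synchronous event sits in the
spike bin — both conventions are exposed via `sync_offset`) and the
asynchronous gap up to the next window. Per period the across-trial mean
`μ_r(k)` and **population** standard deviation `σ_r(k)` (divide by n, not
n−1) are computed; the population convention is deliberate and matters at
small trial counts. Degenerate `σ = 0` is floored at 1% of the grand-mean
integrated release so the Gaussian likelihood stays finite.

The fit maximises the independent Gaussian log-likelihood of the
deterministic model's period predictions against `(μ, σ)` over an exhaustive
Cartesian parameter grid. Predictions are computed at `X_F = 1` and rescaled
so their total matches the data total (the A-normalisation, pooled across
trials); `X_F`, `x0` and `A` are therefore not fitted. Ties are broken by
the first grid point in the canonical parameter order. Confidence intervals
scan each dimension on a finer grid with the others held at the estimate and
keep the region where the likelihood (not log-likelihood) stays above 90% of
its maximum; intervals touching the scan boundary are flagged open-ended.

**Two-stage scheme.** `U_sr` and `tau_d` shape the depressing synchronous
envelope and are well identified; the first stage searches all six
parameters, the second fixes those two at their stage-1 estimates and
re-searches the remaining four on finer grids. Stage-1 grid density is
anisotropic for exactly this reason: `U_sr` and `tau_d` get 9 points (their
quantization error would otherwise propagate into every stage-2 parameter
along the likelihood ridge between `tau_ar` and the asynchronous increment),
the weakly identified `tau_sr`, `tau_ar`, `U_ar`, `U_max` get 5 and are
refined in stage 2 (13/25/21/9 points; `U_ar` grids are geometric since it
acts multiplicatively and spans more than a decade).

`U_max` and `U_ar` are nearly redundant — both scale the spike-triggered
jump of `u_ar` — so only their product is identified at moderate rates and
train lengths. The fit accepts either a direct `U_ar` grid (bounded by its
physiological range; used in the recovery study) or a product grid
`c_ar = U_max·U_ar`; results report both, one backed out via `U_max`.
Fixing `U_max` (e.g. at 1/ms) and searching the remaining five is also
supported.

## Quantal-size estimation

Post-train release is purely asynchronous and, in short windows, close to a
homogeneous Poisson process, so the Fano factor of the binned release amount
`M(j)` across trials equals the quantal amplitude `x̃0 = A·x0`. `M(j)` is
accumulated in 3.9 ms bins; the across-trial variance (unbiased, n−1
denominator) is regressed against the mean, through the origin by default
(an intercept mode exists behind a flag). With 50 trials the estimator has
~8% sampling SD plus a small (few percent) downward bias from pool depletion
(binomial thinning gives Fano slightly below 1); the 15% tolerance used in
validation accommodates both.

## Synthetic data: what it emulates and what it does not

`make_fixture` emulates voltage-clamp IPSC recordings: stochastic SAR
release → delayed exponential kernel → negative-going current plus a
constant leak offset and i.i.d. Gaussian noise (defaults: 2 pA noise SD,
−15 pA leak, quantal amplitude 10 pA). It does **not** model leak drift,
reversal-potential drift during high-frequency trains, receptor saturation,
series-resistance artefacts, or correlated recording noise — so passing
round trips here bound algorithmic error only, not robustness to those
real-data confounds.

## Parameter-recovery study

The recovery experiment validates the fitting chain on simulated ground
truth: settings drawn uniformly from `tau_sr ∈ [4,10]`, `U_sr ∈ [0.1,0.5]`,
`tau_ar ∈ [8,20]`, `U_ar ∈ [0.004,0.02]`, `tau_d ∈ [20,80]`,
`U_max ∈ [0.2,1]` (ms-based units as above), `N_F = 271`; per setting, 50
stochastic trials of 25 spikes at 100 Hz; fits run on period summaries of
the simulated release directly — deconvolution accuracy is validated by its
own round trip, keeping the two error sources separate. Reported metrics:
squared Pearson correlation of estimated vs true values per parameter and
for the product `U_max·U_ar`, and the mean relative deviation between the
log-likelihood of the estimate and of the truth on the same summaries.

The default is 30 settings — a desk-scale size chosen so the whole study
runs in minutes; R² for the well-identified parameters is stable at that
size, while for the near-unidentified pair (`U_max`, `U_ar`) the R² is
dominated by sampling noise (SE of a null correlation ≈ 0.18 at n = 30) and
should be read as "low" rather than as a precise value. The seed-robust
finding is the ordering: `U_sr`, `tau_d`, `tau_ar` and the product are
recovered well; `tau_sr` moderately (it decays almost fully within the
inter-spike interval, so the data barely constrain it); `U_max` and `U_ar`
individually poorly — yet the likelihood of the estimate stays within ~0.1%
of the truth's, the central identifiability observation.

## Known limitations

* Single synapse, single kernel: no network coupling, no multi-exponential
  or saturating receptors, no Ca²⁺ microdomain modelling.
* The deconvolution assumes the kernel is known and stationary; kernel
  misestimation propagates multiplicatively into `q̃`.
* The Gaussian period likelihood ignores across-period correlations induced
  by the shared vesicle pool; this is the standard simplification and is
  what the recovery study validates end to end.
* Grid search scales exponentially in the number of free dimensions; the
  defaults keep one fit in the low seconds, but much finer grids call for
  the two-stage scheme or fixing `U_max`.
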